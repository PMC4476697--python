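"""mtDNA-unique region screening and 25-30 bp primer/probe design.

The screen finds stretches of the circular mitochondrial genome with no
near-identical nuclear copy (NUMT), so that primers placed inside them amplify
mitochondrial templates only. Alignment is exact k-mer seeding (default k=15)
followed by full-window ungapped identity at every seeded diagonal, on both
nuclear strands — dependency-free and directly checkable against a brute-force
all-windows scan.

Primer pairs are picked inside unique regions under hard constraints (length
25-30 nt, GC 0.30-0.70, Tm window, amplicon length, an 18-25 nt hydrolysis
probe strictly between the primers) and ranked by a Tm/GC penalty. Specificity
of a finished oligo is confirmed by exhaustive scanning of the nuclear contigs.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from .seq import encode, gc_fraction, kmer_codes, revcomp, revcomp_arr
from .synthetic import GenomePair


@dataclass(frozen=True)
class UniqueRegion:
    """A maximal mtDNA interval whose every window is below the nuclear-identity screen."""

    mito_start: int
    mito_end: int
    max_nuclear_identity: float

    def __post_init__(self) -> None:
        if self.mito_end <= self.mito_start:
            raise ValueError("mito_end must exceed mito_start")
        if not 0.0 <= self.max_nuclear_identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    def __len__(self) -> int:
        return self.mito_end - self.mito_start


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    probe_seq: str
    forward_start: int
    reverse_end: int
    amplicon_length: int
    tm_forward: float
    tm_reverse: float
    tm_probe: float
    gc_forward: float
    gc_reverse: float
    penalty: float


@dataclass(frozen=True)
class SpecificityReport:
    primer_id: str
    best_identity: float
    perfect_3prime_match: bool


# ---------------------------------------------------------------------------
# uniqueness screen


def _nuclear_targets(genomes: GenomePair, k: int):
    """Encoded nuclear arrays (both strands) with per-target k-mer position maps."""
    targets = []
    for name, seqstr in genomes.nuclear.items():
        if not seqstr:
            continue
        fwd = encode(seqstr)
        for arr in (fwd, revcomp_arr(fwd).copy()):
            if arr.size < k:
                continue
            codes = kmer_codes(arr, k)
            order = np.argsort(codes, kind="stable")
            sorted_codes = codes[order]
            targets.append((arr, sorted_codes, order))
    return targets


def window_best_identities(
    genomes: GenomePair,
    window: int = 100,
    step: int = 10,
    k: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Best nuclear identity of every circular mito window (seeded scan).

    Returns ``(starts, identities)`` for windows starting at 0, step, 2*step, ...
    Windows wrap around the circular origin. Identity of a window is the best
    full-window ungapped match against any nuclear position on either strand,
    found through shared exact k-mers; windows sharing no k-mer with the
    nuclear genome score 0 (their true background identity is irrelevant to
    the screen's threshold decision).
    """
    L = len(genomes.mito)
    if window > L:
        raise ValueError(f"window {window} exceeds mito length {L}")
    if window < 15:
        raise ValueError("window must be >= 15")
    if not 0 < k <= window:
        raise ValueError("require 0 < k <= window")

    marr = encode(genomes.mito + genomes.mito[: window - 1])
    mcodes = kmer_codes(marr, k)
    starts = np.arange(0, L, step)
    best = np.zeros(starts.size)
    targets = _nuclear_targets(genomes, k)
    if not targets:
        return starts, best

    for wi, s in enumerate(starts):
        win = marr[s : s + window]
        best_v = 0.0
        seen: set[tuple[int, int]] = set()
        for ti, (arr, sorted_codes, order) in enumerate(targets):
            for j in range(window - k + 1):
                code = mcodes[s + j]
                lo = np.searchsorted(sorted_codes, code, side="left")
                hi = np.searchsorted(sorted_codes, code, side="right")
                for p in order[lo:hi]:
                    q = int(p) - j  # nuclear start of the aligned window
                    key = (ti, q)
                    if key in seen:
                        continue
                    seen.add(key)
                    a0, a1 = max(q, 0), min(q + window, arr.size)
                    if a1 <= a0:
                        continue
                    matches = int(np.count_nonzero(arr[a0:a1] == win[a0 - q : a1 - q]))
                    best_v = max(best_v, matches / window)
        best[wi] = best_v
    return starts, best


def screen_unique_regions(
    genomes: GenomePair,
    window: int = 100,
    step: int = 10,
    identity_threshold: float = 0.80,
    min_region: int = 100,
    k: int = 15,
) -> list[UniqueRegion]:
    """Maximal mtDNA regions in which no window reaches the nuclear-identity threshold.

    With an empty nuclear genome the whole mitochondrial sequence is returned
    as a single region (documented behaviour, not an error). Regions that wrap
    the circular origin are split at position 0 so output coordinates never
    exceed the sequence length.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    L = len(genomes.mito)
    starts, idents = window_best_identities(genomes, window=window, step=step, k=k)
    sub = idents < identity_threshold
    n = starts.size

    if not sub.any():
        return []
    if sub.all():
        return [UniqueRegion(0, L, float(idents.max()))]

    # maximal runs of sub-threshold windows on the circular index
    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(n):
        if sub[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if len(runs) > 1 and sub[0] and sub[-1]:
        runs[0] = runs.pop() + runs[0]  # wrap merge

    regions: list[UniqueRegion] = []
    for run in runs:
        first, last = run[0], run[-1]
        start = int(starts[first])
        end = int(starts[last]) + window
        if last < first:  # wrapped run: end index precedes start index
            end += L
        length = end - start
        if length >= L:
            start, end, length = 0, L, L
        if length < min_region:
            continue
        ident = float(idents[run].max())
        if end <= L:
            regions.append(UniqueRegion(start, end, ident))
        else:  # split at the circular origin
            regions.append(UniqueRegion(start, L, ident))
            regions.append(UniqueRegion(0, end - L, ident))
    regions.sort(key=lambda r: r.mito_start)
    return regions


# ---------------------------------------------------------------------------
# melting temperature


@lru_cache(maxsize=200_000)
def melting_temperature(seq: str, na_mM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Uses the SantaLucia (1998) unified parameter set with the SantaLucia salt
    correction at the given monovalent-cation concentration and 25 nM of each
    strand (Biopython's ``Tm_NN`` defaults). Deterministic; symmetric under
    reverse complement.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence must be >= 8 nt")
    encode(seq)  # raises on non-ACGT
    return float(mt.Tm_NN(Seq(seq), nn_table=mt.DNA_NN3, Na=na_mM, saltcorr=5))


# ---------------------------------------------------------------------------
# primer pair design


@dataclass(frozen=True)
class PrimerConstraints:
    primer_len: tuple[int, int] = (25, 30)
    gc_range: tuple[float, float] = (0.30, 0.70)
    tm_range: tuple[float, float] = (50.0, 65.0)
    tm_target: float = 58.0
    amplicon: tuple[int, int] = (60, 200)
    probe_len: tuple[int, int] = (18, 25)
    na_mM: float = 50.0
    max_candidates_per_side: int = 800
    max_pairs: int = 50


@dataclass(frozen=True)
class _Oligo:
    start: int  # region-local
    length: int
    tm: float
    gc: float

    @property
    def end(self) -> int:
        return self.start + self.length


def _candidate_windows(rseq: str, len_range, gc_range, tm_range, na_mM) -> list[_Oligo]:
    out = []
    lo, hi = len_range
    arr = encode(rseq)
    gc_cum = np.concatenate(([0], np.cumsum((arr == 1) | (arr == 2))))
    for length in range(lo, hi + 1):
        for start in range(0, len(rseq) - length + 1):
            gc = (gc_cum[start + length] - gc_cum[start]) / length
            if not gc_range[0] <= gc <= gc_range[1]:
                continue
            tm = melting_temperature(rseq[start : start + length], na_mM)
            if tm_range is not None and not tm_range[0] <= tm <= tm_range[1]:
                continue
            out.append(_Oligo(start, length, tm, float(gc)))
    return out


def design_primer_pairs(
    mito_seq: str,
    region: UniqueRegion,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerPair]:
    """Ranked primer pairs (with hydrolysis probe) inside one unique region.

    Both primers satisfy the length/GC/Tm constraints; the reverse primer is the
    reverse complement of a downstream mito interval; the probe (18-25 nt,
    same GC bounds, Tm closest to the primer mean) lies strictly between the
    primers. Pairs are ranked by
    ``|Tm_f - Tm_r| + |Tm_f - target| + |Tm_r - target| + |GC_f - 0.5| + |GC_r - 0.5|``
    with ties broken on (forward_start, reverse_end). An empty list is a valid
    result.
    """
    L = len(mito_seq)
    c = constraints
    rlen = len(region)
    min_needed = c.amplicon[0] + 2 * c.primer_len[0]
    if rlen < min_needed:
        raise ValueError(
            f"region [{region.mito_start},{region.mito_end}) of length {rlen} is shorter "
            f"than the minimum workable span {min_needed}"
        )
    rseq = (mito_seq + mito_seq)[region.mito_start : region.mito_end]

    prims = _candidate_windows(rseq, c.primer_len, c.gc_range, c.tm_range, c.na_mM)
    if not prims:
        return []
    prims.sort(key=lambda o: (abs(o.tm - c.tm_target) + abs(o.gc - 0.5), o.start, o.length))
    prims = prims[: c.max_candidates_per_side]
    probes = _candidate_windows(rseq, c.probe_len, c.gc_range, None, c.na_mM)
    if not probes:
        return []

    scored: list[tuple[float, _Oligo, _Oligo]] = []
    for f in prims:
        for r in prims:
            amplicon = r.end - f.start
            if not c.amplicon[0] <= amplicon <= c.amplicon[1]:
                continue
            if r.start - f.end < c.probe_len[0]:
                continue
            penalty = (
                abs(f.tm - r.tm)
                + abs(f.tm - c.tm_target)
                + abs(r.tm - c.tm_target)
                + abs(f.gc - 0.5)
                + abs(r.gc - 0.5)
            )
            scored.append((penalty, f, r))
    scored.sort(key=lambda t: (t[0], t[1].start, t[2].end))

    pairs: list[PrimerPair] = []
    for penalty, f, r in scored:
        gap_probes = [p for p in probes if p.start >= f.end and p.end <= r.start]
        if not gap_probes:
            continue
        target_tm = (f.tm + r.tm) / 2.0
        probe = min(gap_probes, key=lambda p: (abs(p.tm - target_tm), p.start, p.length))
        fseq = rseq[f.start : f.end]
        rseq_primer = revcomp(rseq[r.start : r.end])
        pairs.append(
            PrimerPair(
                forward_seq=fseq,
                reverse_seq=rseq_primer,
                probe_seq=rseq[probe.start : probe.end],
                forward_start=(region.mito_start + f.start) % L,
                reverse_end=(region.mito_start + r.end - 1) % L + 1,
                amplicon_length=r.end - f.start,
                tm_forward=f.tm,
                tm_reverse=r.tm,
                tm_probe=probe.tm,
                gc_forward=f.gc,
                gc_reverse=r.gc,
                penalty=float(penalty),
            )
        )
        if len(pairs) >= c.max_pairs:
            break
    return pairs


# ---------------------------------------------------------------------------
# specificity


def _scan_best(primer_arr: np.ndarray, contig_arr: np.ndarray, anchor_len: int, anchor_identity: float):
    plen = primer_arr.size
    n_off = contig_arr.size - plen + 1
    if n_off <= 0:
        return 0.0, False
    matches = np.zeros(n_off, dtype=np.int32)
    for j in range(plen):
        matches += contig_arr[j : j + n_off] == primer_arr[j]
    best = float(matches.max() / plen)
    anchor_ok = np.ones(n_off, dtype=bool)
    for j in range(plen - anchor_len, plen):
        anchor_ok &= contig_arr[j : j + n_off] == primer_arr[j]
    threshold = int(np.ceil(anchor_identity * plen))
    flag = bool(np.any(anchor_ok & (matches >= threshold)))
    return best, flag


def check_specificity(
    pair: PrimerPair,
    genomes: GenomePair,
    anchor_len: int = 5,
    anchor_identity: float = 0.90,
) -> list[SpecificityReport]:
    """Exhaustive nuclear scan (both strands) for each oligo of a finished assay.

    Reports the best full-length identity anywhere in the nuclear genome and
    whether any site matches the oligo's 3'-terminal ``anchor_len`` bases
    exactly while reaching ``anchor_identity`` overall — the configuration most
    likely to prime off-target.
    """
    reports = []
    for pid, seqstr in (("forward", pair.forward_seq), ("reverse", pair.reverse_seq), ("probe", pair.probe_seq)):
        parr = encode(seqstr)
        best, flag = 0.0, False
        for contig in genomes.nuclear.values():
            if not contig:
                continue
            carr = encode(contig)
            for arr in (carr, revcomp_arr(carr).copy()):
                b, f = _scan_best(parr, arr, anchor_len, anchor_identity)
                best = max(best, b)
                flag = flag or f
        reports.append(SpecificityReport(primer_id=pid, best_identity=best, perfect_3prime_match=flag))
    return reports
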