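"""Independent reference implementations used only as test oracles.

Everything here is deliberately brute-force (full window scans, literal 2^n /
C(n, k) enumeration, naive parameter-table sums) and shares no code paths with
the package beyond the trivial base encoding.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

_ENC = {c: i for i, c in enumerate("ACGT")}
_COMP = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.uint8, count=len(seq))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_window_identities(mito: str, nuclear: dict[str, str], window: int, step: int) -> np.ndarray:
    """Best nuclear identity of every circular mito window by scanning ALL offsets."""
    ext = _encode(mito + mito[: window - 1])
    starts = range(0, len(mito), step)
    best = np.zeros(len(list(starts)))
    for contig in nuclear.values():
        for strand_seq in (contig, _revcomp(contig)):
            arr = _encode(strand_seq)
            if arr.size < window:
                continue
            view = np.lib.stride_tricks.sliding_window_view(arr, window)
            for wi, s in enumerate(range(0, len(mito), step)):
                win = ext[s : s + window]
                matches = (view == win).sum(axis=1)
                best[wi] = max(best[wi], matches.max() / window)
    return best


def wilcoxon_enumeration_p(diffs, zero_policy: str = "pratt") -> tuple[float, float]:
    """(W+, two-sided p) by literal enumeration of all 2^m sign assignments."""
    d = np.asarray(diffs, dtype=float)
    if zero_policy == "wilcox":
        d = d[d != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    nz = d != 0
    ranks, signs = ranks[nz], d[nz] > 0
    m = ranks.size
    w_obs = float(ranks[signs].sum())
    ws = np.array([sum(r for r, bit in zip(ranks, bits) if bit) for bits in itertools.product([0, 1], repeat=m)])
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(lo, hi))


def mannwhitney_enumeration_p(a, b) -> tuple[float, float]:
    """(U1, two-sided p) by enumerating all C(n1+n2, n1) group assignments."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    us = np.array([ranks[list(c)].sum() - offset for c in itertools.combinations(range(pooled.size), n1)])
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def pearson_permutation_p(x, y, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the Pearson r (permutes y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = abs(float(xs @ ys) / x.size)
    rng = np.random.default_rng(seed)
    perms = np.array([xs @ rng.permutation(ys) / x.size for _ in range(n_perm)])
    return float((np.sum(np.abs(perms) >= r_obs - 1e-12) + 1) / (n_perm + 1))


# nearest-neighbor duplex parameters (unified oligonucleotide set) for the Tm oracle
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def tm_nearest_neighbor_oracle(seq: str, na_mM: float = 50.0, dnac1: float = 25.0, dnac2: float = 25.0) -> float:
    """Hand-rolled NN melting temperature (deg C): duplex stack sum + terminal
    penalties + entropic salt correction + duplex-concentration term."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        h, s = _NN[dinuc] if dinuc in _NN else _NN[_revcomp(dinuc)]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


def regions_from_bools(starts: np.ndarray, sub: np.ndarray, window: int, length: int, min_region: int):
    """Derive maximal unique regions from a per-window sub-threshold mask
    (independent re-implementation of the circular run merging)."""
    n = sub.size
    if sub.all():
        return [(0, length)]
    if not sub.any():
        return []
    runs = []
    i = 0
    while i < n:
        if sub[i]:
            j = i
            while j < n and sub[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    if len(runs) > 1 and sub[0] and sub[-1]:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wrapped
    out = []
    for i0, i1 in runs:
        start = int(starts[i0])
        end = int(starts[i1]) + window
        if i1 < i0:
            end += length
        if end - start < min_region:
            continue
        if end <= length:
            out.append((start, end))
        else:
            out.append((start, length))
            out.append((0, end - length))
    return sorted(out)
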