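"""Truth-known synthetic inputs for every pipeline stage.

Four generators, one per stage:

* :func:`make_genome_pair` — a random circular mitochondrial genome plus nuclear
  contigs carrying planted, partially diverged mtDNA insertions (NUMTs).
* :func:`make_ct_dataset` — triplicate qPCR Ct tables (targets + nuclear 16S
  normalizer) with per-animal true relative copy numbers.
* :func:`make_suit_trace` — a closed-chamber oxygraph record following a
  substrate-uncoupler-inhibitor titration (SUIT) plan with known plateau fluxes.
* :func:`make_cohort` — paired (delta-RQ, sham-referenced delta-respiration)
  animals with a prescribed population correlation.

Every generator is a pure function of its seed and parameters; the ground truth
it returns is the oracle the test-suite checks the analysis modules against.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .respirometry import OxygraphTrace, PhaseFlux
from .seq import decode, encode, random_sequence, revcomp_arr
from .stats import CohortRecord

# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class NumtTruth:
    """A planted nuclear copy of a mitochondrial interval (substitutions only, no indels)."""

    contig_id: str
    start: int
    end: int
    mito_start: int
    mito_end: int
    divergence: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.end - self.start != self.mito_end - self.mito_start:
            raise ValueError("NUMT length must equal source interval length (no indels)")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class GenomePair:
    """A circular mitochondrial sequence plus one or more nuclear contigs."""

    mito: str
    nuclear: Mapping[str, str]


def make_genome_pair(
    seed: int,
    mito_length: int = 16_500,
    nuclear_length: int = 200_000,
    numt_specs: Sequence[tuple[int, float]] = (),
    contig_id: str = "nuc1",
    max_place_attempts: int = 1000,
) -> tuple[GenomePair, list[NumtTruth]]:
    """Random genome pair with NUMTs planted at non-overlapping nuclear loci.

    Each spec is ``(length, divergence)``: a random mitochondrial interval of that
    length is copied (either strand), exactly ``round(length * divergence)``
    positions are substituted to a different base, and the copy overwrites a
    random non-overlapping window of the nuclear contig. Infeasible packing
    raises instead of silently truncating.
    """
    specs = [(int(l), float(d)) for l, d in numt_specs]
    for length, div in specs:
        if length <= 0:
            raise ValueError("NUMT length must be positive")
        if not 0.0 <= div <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if length > mito_length:
            raise ValueError(f"NUMT length {length} exceeds mito length {mito_length}")
    if sum(l for l, _ in specs) > nuclear_length:
        raise ValueError("total NUMT length exceeds nuclear contig length")

    rng = np.random.default_rng(seed)
    mito_arr = rng.integers(0, 4, size=mito_length, dtype=np.uint8)
    nuc_arr = rng.integers(0, 4, size=nuclear_length, dtype=np.uint8)

    placed: list[tuple[int, int]] = []
    truths: list[NumtTruth] = []
    for length, div in specs:
        mito_start = int(rng.integers(0, mito_length - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        segment = mito_arr[mito_start : mito_start + length].copy()
        if strand == "-":
            segment = revcomp_arr(segment).copy()
        n_sub = round(length * div)
        if n_sub > 0:
            pos = rng.choice(length, size=n_sub, replace=False)
            # substitute to one of the three *other* bases
            shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
            segment[pos] = (segment[pos] + shift) % 4

        for attempt in range(max_place_attempts):
            start = int(rng.integers(0, nuclear_length - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise ValueError(
                f"could not place NUMT of length {length} without overlap "
                f"after {max_place_attempts} attempts"
            )
        placed.append((start, end))
        nuc_arr[start:end] = segment
        truths.append(
            NumtTruth(
                contig_id=contig_id,
                start=start,
                end=end,
                mito_start=mito_start,
                mito_end=mito_start + length,
                divergence=div,
                strand=strand,
            )
        )

    truths.sort(key=lambda t: (t.contig_id, t.start))
    pair = GenomePair(mito=decode(mito_arr), nuclear={contig_id: decode(nuc_arr)})
    return pair, truths


# ---------------------------------------------------------------------------
# qPCR Ct tables

DEFAULT_GENES = ("COI-1", "COI-1A", "ND4-1")
NORMALIZER_GENE = "16S"
CALIBRATOR_ID = "CAL"


@dataclass(frozen=True)
class CtGeneratorParams:
    """Parameters of the triplicate-Ct generator.

    ``group_fold_changes`` maps group name to either a single post-injury fold
    change (pre defaults to 1.0) or an explicit ``{"pre": f0, "post": f1}`` map;
    folds are true mean RQ levels relative to the calibrator level
    ``calibrator_rq``. ``animal_sd`` is the between-animal SD on the log2-RQ
    scale; ``replicate_sd`` is the within-triplicate Ct SD in cycles.
    """

    n_per_group: int
    group_fold_changes: Mapping[str, Mapping[str, float] | float]
    genes: tuple[str, ...] = DEFAULT_GENES
    calibrator_rq: float = 1.0
    replicate_sd: float = 0.15
    animal_sd: float = 0.25
    seed: int = 0
    normalizer_ct: float = 22.0
    base_delta_ct: float = -4.0  # target-minus-normalizer Ct at latent level 1

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.replicate_sd < 0 or self.animal_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.calibrator_rq <= 0:
            raise ValueError("calibrator_rq must be > 0")
        for group, fold in self.group_fold_changes.items():
            folds = fold.values() if isinstance(fold, Mapping) else (fold,)
            if any(f <= 0 for f in folds):
                raise ValueError(f"fold changes must be > 0 (group {group})")


def _fold(params: CtGeneratorParams, group: str, timepoint: str) -> float:
    fold = params.group_fold_changes[group]
    if isinstance(fold, Mapping):
        return float(fold[timepoint])
    return float(fold) if timepoint == "post" else 1.0


def make_ct_dataset(params: CtGeneratorParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate Ct table plus the true RQ of every sample x gene.

    Returns ``(ct_table, truth)`` where ``ct_table`` has columns
    ``animal_id, group, timepoint, gene, replicate, ct`` (three replicates per
    sample x gene for targets and for the 16S normalizer, plus a dedicated
    calibrator sample ``CAL``) and ``truth`` has one row per sample x target
    gene with the latent RQ the pipeline should recover.
    """
    rng = np.random.default_rng(params.seed)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []

    def emit_sample(animal: str, group: str, timepoint: str, latent: Mapping[str, float]) -> None:
        # one 16S triplicate per sample, shared by all target genes
        for rep in range(1, 4):
            noise = rng.normal(0.0, params.replicate_sd) if params.replicate_sd else 0.0
            rows.append((animal, group, timepoint, NORMALIZER_GENE, rep, params.normalizer_ct + noise))
        for gene, level in latent.items():
            delta_ct = params.base_delta_ct - math.log2(level)
            for rep in range(1, 4):
                noise = rng.normal(0.0, params.replicate_sd) if params.replicate_sd else 0.0
                rows.append((animal, group, timepoint, gene, rep, params.normalizer_ct + delta_ct + noise))

    # calibrator sample: latent level = calibrator_rq for every gene
    emit_sample(
        CALIBRATOR_ID,
        "calibrator",
        "pre",
        {g: params.calibrator_rq for g in params.genes},
    )

    for group in params.group_fold_changes:
        for i in range(params.n_per_group):
            animal = f"{group}-{i + 1:02d}"
            for timepoint in ("pre", "post"):
                mean_level = _fold(params, group, timepoint)
                latent = {}
                for gene in params.genes:
                    eps = rng.normal(0.0, params.animal_sd) if params.animal_sd else 0.0
                    level = mean_level * 2.0**eps
                    latent[gene] = level
                    truth_rows.append((animal, group, timepoint, gene, level / params.calibrator_rq))
                emit_sample(animal, group, timepoint, latent)

    table = pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "gene", "replicate", "ct"])
    truth = pd.DataFrame(truth_rows, columns=["animal_id", "group", "timepoint", "gene", "true_rq"])
    return table, truth


# ---------------------------------------------------------------------------
# SUIT oxygraph traces

#: Default SUIT plan: routine baseline, convergent CI+CII OXPHOS after succinate,
#: oligomycin-induced LEAK. Fluxes are desk-scale values in pmol O2 s^-1 mg^-1.
DEFAULT_SUIT_PLAN: tuple[tuple[str, float, float], ...] = (
    ("baseline", 15.0, 400.0),
    ("OXPHOS_CI+CII", 82.6, 600.0),
    ("LEAK_CI+CII", 14.0, 600.0),
)


@dataclass(frozen=True)
class SuitGeneratorParams:
    """Parameters of the oxygraph-trace generator.

    ``phase_plan`` is an ordered list of ``(state label, true flux, duration s)``.
    O2 declines piecewise-linearly at ``flux * sample_conc / 1000`` uM/s, with a
    decaying positive spike of ``artifact_magnitude`` uM at each titration and
    white Gaussian noise of ``noise_sd`` uM on every sample.
    """

    phase_plan: tuple[tuple[str, float, float], ...] = DEFAULT_SUIT_PLAN
    equilibration_s: float = 60.0
    artifact_magnitude: float = 2.0
    artifact_tau_s: float = 10.0
    noise_sd: float = 0.2
    sample_conc: float = 1.0
    o2_start: float = 190.0
    sample_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.equilibration_s < 0:
            raise ValueError("equilibration_s must be >= 0")
        if self.sample_conc <= 0:
            raise ValueError("sample_conc must be > 0")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for label, flux, duration in self.phase_plan:
            if flux < 0:
                raise ValueError(f"phase {label!r}: flux must be >= 0")
            if duration <= self.equilibration_s:
                raise ValueError(f"phase {label!r}: duration must exceed equilibration_s")


def make_suit_trace(params: SuitGeneratorParams) -> tuple[OxygraphTrace, list[PhaseFlux]]:
    """Synthesise one oxygraph record plus the true flux of every phase."""
    rng = np.random.default_rng(params.seed)
    dt = params.sample_interval_s

    # feasibility: piecewise O2 must stay positive (noise/artifact excluded)
    o2 = params.o2_start
    for label, flux, duration in params.phase_plan:
        o2 -= flux * params.sample_conc / 1000.0 * duration
        if o2 < 0:
            raise ValueError(f"O2 would fall below 0 during phase {label!r}")

    total = sum(d for _, _, d in params.phase_plan)
    time = np.arange(0.0, total, dt)
    slopes = np.zeros_like(time)
    events: list[tuple[float, str]] = []
    truths: list[PhaseFlux] = []
    t0 = 0.0
    for label, flux, duration in params.phase_plan:
        sel = (time >= t0) & (time < t0 + duration)
        slopes[sel] = -flux * params.sample_conc / 1000.0
        events.append((t0, label))
        truths.append(
            PhaseFlux(state=label, flux=flux, window=(t0 + params.equilibration_s, t0 + duration), stability=0.0)
        )
        t0 += duration

    o2_series = params.o2_start + np.concatenate(([0.0], np.cumsum(slopes[:-1] * np.diff(time))))
    if params.artifact_magnitude:
        for te, _ in events:
            tail = time >= te
            o2_series = o2_series + np.where(
                tail, params.artifact_magnitude * np.exp(-(time - te) / params.artifact_tau_s), 0.0
            )
    if params.noise_sd:
        o2_series = o2_series + rng.normal(0.0, params.noise_sd, size=time.size)

    trace = OxygraphTrace(
        time=time,
        o2=o2_series,
        events=tuple(events),
        sample_conc=params.sample_conc,
    )
    return trace, truths


# ---------------------------------------------------------------------------
# joint cohorts


@dataclass(frozen=True)
class CohortEffectScales:
    """Location/scale of the bivariate (delta-RQ, delta-respiration) population."""

    delta_rq_mean: float = 1.2
    delta_rq_sd: float = 0.5
    delta_resp_mean: float = 20.0
    delta_resp_sd: float = 8.0


def make_cohort(
    seed: int,
    n: int,
    true_r: float,
    sham_mean_flux: float,
    effect_scales: CohortEffectScales = CohortEffectScales(),
    group: str = "RNR-6h",
    endpoint: str = "OXPHOS_CI+CII",
) -> tuple[list[CohortRecord], dict]:
    """Cohort of paired biomarker/bioenergetic deltas with correlation ``true_r``.

    delta_resp is generated on the sham-referenced deficit scale
    (sham mean minus the animal's post-injury respiration); records store the
    implied ``post_resp`` so the analysis recomputes the deficit itself.
    """
    if not -1.0 <= true_r <= 1.0:
        raise ValueError("true_r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3 animals")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = true_r * x + math.sqrt(max(0.0, 1.0 - true_r**2)) * z

    delta_rq = effect_scales.delta_rq_mean + effect_scales.delta_rq_sd * x
    delta_resp = effect_scales.delta_resp_mean + effect_scales.delta_resp_sd * y
    records = [
        CohortRecord(
            animal_id=f"{group}-{i + 1:02d}",
            group=group,
            delta_rq=float(delta_rq[i]),
            post_resp=float(sham_mean_flux - delta_resp[i]),
            sham_mean=float(sham_mean_flux),
            endpoint=endpoint,
        )
        for i in range(n)
    ]
    truth = {"true_r": true_r, "delta_rq": delta_rq, "delta_resp": delta_resp}
    return records, truth
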