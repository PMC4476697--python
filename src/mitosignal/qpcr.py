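"""Comparative-Ct (ddCt) relative quantification of mtDNA copy number.

A triplicate Ct table (samples x genes, targets plus the nuclear 16S rRNA
normalizer) is collapsed to per-sample mean Cts and converted to relative
quantification ratios

    RQ = 2^-(ddCt),   ddCt = (Ct_target - Ct_16S)_sample - (Ct_target - Ct_16S)_calibrator

so RQ is proportional to mtDNA copies per cell and equals 1 for the calibrator
by construction. Amplification efficiency is fixed at perfect doubling
(base 2); an efficiency hook is exposed for sensitivity analyses but the
reported statistics assume 2. Outlying triplicates are flagged, never dropped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

NORMALIZER_GENE = "16S"
REQUIRED_COLUMNS = ("animal_id", "group", "timepoint", "gene", "replicate", "ct")
SAMPLE_KEY = ["animal_id", "group", "timepoint"]


@dataclass(frozen=True)
class CtRecord:
    animal_id: str
    group: str
    timepoint: str
    gene: str
    replicates: tuple[float, float, float]


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    flagged: bool


@dataclass(frozen=True)
class RQValue:
    animal_id: str
    group: str
    timepoint: str
    gene: str
    rq: float

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("rq must be > 0")


@dataclass(frozen=True)
class PooledStat:
    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0 or self.n < 1:
            raise ValueError("require sem >= 0 and n >= 1")


def collapse_replicates(values: Sequence[float] | CtRecord, sd_limit: float = 0.5) -> ReplicateSummary:
    """Mean and sample SD of one Ct triplicate; flags (never drops) noisy triples."""
    if isinstance(values, CtRecord):
        values = values.replicates
    arr = np.asarray(values, dtype=float)
    if arr.size != 3:
        raise ValueError(f"expected exactly 3 replicates, got {arr.size}")
    if not np.all((arr > 0) & (arr < 45)):
        raise ValueError("Ct values must lie in (0, 45)")
    sd = float(arr.std(ddof=1))
    return ReplicateSummary(mean=float(arr.mean()), sd=sd, flagged=sd > sd_limit)


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing required columns: {missing}")
    if table["ct"].isna().any():
        bad = table.index[table["ct"].isna()].tolist()[:5]
        raise ValueError(f"Ct table has missing ct values at rows {bad}")


def relative_quantification(
    table: pd.DataFrame,
    normalizer_gene: str = NORMALIZER_GENE,
    calibrator: str = "auto",
    sd_limit: float = 0.5,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per sample x gene relative quantification ratios from a triplicate Ct table.

    ``calibrator`` is either an ``animal_id`` whose sample sets the reference
    dCt per gene, or ``"auto"``: the mean dCt of all pre-injury samples (which
    centres pre-injury RQ near 1). Returns a DataFrame with columns
    ``animal_id, group, timepoint, gene, rq, ct_flagged``.
    """
    _validate_table(table)
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")

    grouped = table.groupby(SAMPLE_KEY + ["gene"], sort=False)["ct"]
    sizes = grouped.size()
    bad = sizes[sizes != 3]
    if not bad.empty:
        raise ValueError(f"samples without exactly 3 replicates: {bad.index.tolist()[:5]}")
    means = grouped.mean().rename("ct_mean")
    sds = grouped.std(ddof=1).rename("ct_sd")
    coll = pd.concat([means, sds], axis=1).reset_index()
    coll["ct_flagged"] = coll["ct_sd"] > sd_limit

    norm = coll[coll["gene"] == normalizer_gene].set_index(SAMPLE_KEY)["ct_mean"]
    targets = coll[coll["gene"] != normalizer_gene].copy()
    if targets.empty:
        raise ValueError("no target genes in table")
    sample_index = pd.MultiIndex.from_frame(targets[SAMPLE_KEY])
    have_norm = sample_index.isin(norm.index)
    if not have_norm.all():
        missing_samples = sorted(set(map(tuple, targets.loc[~have_norm, SAMPLE_KEY].values)))
        raise ValueError(f"samples missing {normalizer_gene} normalizer: {missing_samples[:5]}")
    targets["dct"] = targets["ct_mean"].to_numpy() - norm.loc[sample_index].to_numpy()

    if calibrator == "auto":
        pre = targets[targets["timepoint"] == "pre"]
        if pre.empty:
            raise ValueError("auto calibrator requires pre-injury samples")
        cal_dct = pre.groupby("gene")["dct"].mean()
    else:
        cal = targets[targets["animal_id"] == calibrator]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} not found")
        cal_dct = cal.groupby("gene")["dct"].mean()
    missing_cal = sorted(set(targets["gene"]) - set(cal_dct.index))
    if missing_cal:
        raise ValueError(f"calibrator lacks genes: {missing_cal}")

    ddct = targets["dct"].to_numpy() - cal_dct.loc[targets["gene"]].to_numpy()
    targets["rq"] = np.power(float(efficiency), -ddct)
    return targets[SAMPLE_KEY + ["gene", "rq", "ct_flagged"]].reset_index(drop=True)


def pool_rq(values: Sequence[float], label: str = "pooled") -> PooledStat:
    """Mean, SEM (sample SD / sqrt(n), 0 when n = 1) and n of pooled RQ values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty group {label!r}")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return PooledStat(label=label, mean=float(arr.mean()), sem=sem, n=int(arr.size))


def pooled_mean_of_group_means(means: Sequence[float], n_animals: Sequence[int]) -> float:
    """Pooled mean from printed per-gene group means weighted by group sizes.

    Each (group, gene) mean represents ``n_animals`` values, so the pooled mean
    over all gene x animal values is the n-weighted average of the means.
    """
    means = np.asarray(list(means), dtype=float)
    weights = np.asarray(list(n_animals), dtype=float)
    if means.size == 0 or means.size != weights.size:
        raise ValueError("means and n_animals must be equal-length and non-empty")
    return float(np.average(means, weights=weights))


def delta_rq(rq_table: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple]]:
    """Post-minus-pre RQ delta per matched animal x gene.

    Returns ``(deltas, unmatched)`` where deltas has columns
    ``animal_id, group, gene, delta`` and unmatched lists animal x gene keys
    present at only one timepoint. Raises when nothing matches.
    """
    needed = {"animal_id", "group", "timepoint", "gene", "rq"}
    if not needed <= set(rq_table.columns):
        raise ValueError(f"rq table missing columns {sorted(needed - set(rq_table.columns))}")
    wide = rq_table.pivot_table(
        index=["animal_id", "group", "gene"], columns="timepoint", values="rq", aggfunc="mean"
    )
    for tp in ("pre", "post"):
        if tp not in wide.columns:
            wide[tp] = np.nan
    matched = wide.dropna(subset=["pre", "post"])
    unmatched = [tuple(ix) for ix in wide.index[wide[["pre", "post"]].isna().any(axis=1)]]
    if matched.empty:
        raise ValueError("no animal x gene keys with both pre and post measurements")
    out = matched.reset_index()[["animal_id", "group", "gene"]]
    out["delta"] = (matched["post"] - matched["pre"]).to_numpy()
    return out, unmatched


def animal_delta_rq(rq_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-averaged per-animal RQ delta (the biomarker fed to the association analysis)."""
    deltas, _ = delta_rq(rq_table)
    return deltas.groupby(["animal_id", "group"], as_index=False)["delta"].mean()
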