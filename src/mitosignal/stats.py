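"""Small-sample statistics for the paired biomarker design.

Exact (full-null-distribution) Wilcoxon signed-rank and Mann-Whitney U tests,
one-way repeated-measures ANOVA across genes, Pearson correlation, and the
sham-referenced delta association linking peripheral delta-RQ to cerebral
bioenergetic deficits.

The exact tests compute the complete permutation null — all 2^m sign
assignments of the ranked |differences| (signed rank) and all C(n1+n2, n1)
group assignments (rank sum) — via dynamic programming, so they are identical
to literal enumeration at any feasible size. Two-sided p-values double the
smaller tail and are capped at 1. No multiple-testing correction is applied;
callers see raw p-values.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int | tuple[int, int]
    method: str
    df: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass(frozen=True)
class CohortRecord:
    """One animal's paired biomarker/bioenergetic observation.

    ``delta_rq`` is the gene-averaged post-minus-pre relative mtDNA copy
    number; ``delta_resp`` (a derived property, never stored) is the
    sham-referenced respiratory deficit ``sham_mean - post_resp``: positive
    means the animal respires below the sham average.
    """

    animal_id: str
    group: str
    delta_rq: float
    post_resp: float
    sham_mean: float
    endpoint: str = "OXPHOS_CI+CII"

    @property
    def delta_resp(self) -> float:
        return self.sham_mean - self.post_resp


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@lru_cache(maxsize=4096)
def _signed_rank_null(ranks2: tuple[int, ...]) -> np.ndarray:
    """PMF of W+ (on the doubled-rank integer scale) under random signs.

    Equivalent to enumerating all 2^m sign assignments: the DP convolves one
    Bernoulli(1/2) contribution per rank.
    """
    total = int(sum(ranks2))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts / counts.sum()


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    zero_policy: str = "pratt",
    mode: str = "auto",
) -> TestResult:
    """Paired Wilcoxon signed-rank test of post vs pre.

    ``zero_policy='pratt'`` ranks zero differences with the rest and then drops
    their contribution; ``'wilcox'`` discards zeros before ranking. ``mode``
    is ``'exact'`` (full null distribution), ``'approx'`` (normal with
    tie-aware variance and continuity correction) or ``'auto'`` (exact up to
    m = 25 informative pairs).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D sequences")
    d = post - pre
    if zero_policy == "wilcox":
        d = d[d != 0]
        ranks_all = sps.rankdata(np.abs(d)) if d.size else np.array([])
        nonzero = np.ones(d.size, dtype=bool)
    elif zero_policy == "pratt":
        ranks_all = sps.rankdata(np.abs(d)) if d.size else np.array([])
        nonzero = d != 0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    m = int(np.count_nonzero(nonzero))
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="degenerate")

    ranks = ranks_all[nonzero]
    signs_pos = d[nonzero] > 0
    w_plus = float(ranks[signs_pos].sum())

    if mode == "auto":
        mode = "exact" if m <= 25 else "approx"

    if mode == "exact":
        ranks2 = tuple(sorted(int(round(2 * r)) for r in ranks))
        pmf = _signed_rank_null(ranks2)
        w2 = int(round(2 * w_plus))
        lo = float(pmf[: w2 + 1].sum())
        hi = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(statistic=w_plus, p_value=p, n=m, method="exact")
    if mode == "approx":
        mu = ranks.sum() / 2.0
        sd = math.sqrt(float(np.sum(ranks**2)) / 4.0)
        if sd == 0:
            return TestResult(statistic=w_plus, p_value=1.0, n=m, method="normal-approx")
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sd
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        return TestResult(statistic=w_plus, p_value=p, n=m, method="normal-approx")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=1024)
def _rank_sum_null_no_ties(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets of {1..n1+n2} of size n1 by rank sum (exact, DP)."""
    n = n1 + n2
    max_sum = n1 * n + 10
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(min(i, n1), 0, -1):
            dp[j, i:] += dp[j - 1, : max_sum + 1 - i]
    return dp[n1]


def mann_whitney_u(a: Sequence[float], b: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sample Mann-Whitney U test (statistic = U of the first sample).

    Exact mode enumerates the full rank-assignment null: a ties-free DP when
    the pooled sample has no ties, literal combination enumeration over the
    midrank multiset otherwise (up to ~200k splits), and the tie-corrected
    normal approximation beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if mode == "auto":
        n = n1 + n2
        if not has_ties and n <= 25:
            mode = "exact"
        elif has_ties and math.comb(n, n1) <= 200_000:
            mode = "exact"
        else:
            mode = "approx"

    if mode == "exact":
        offset = n1 * (n1 + 1) / 2.0
        if not has_ties:
            counts = _rank_sum_null_no_ties(n1, n2)
            sums = np.arange(counts.size) - offset  # U values per rank sum
            weights = counts
        else:
            if math.comb(n1 + n2, n1) > 5_000_000:
                raise ValueError("tied exact Mann-Whitney infeasible at this size; use approx")
            u_vals = [
                sum(ranks[list(combo)]) - offset
                for combo in itertools.combinations(range(n1 + n2), n1)
            ]
            sums, weights = np.unique(np.round(np.asarray(u_vals) * 2) / 2, return_counts=True)
            weights = weights.astype(float)
        total = weights.sum()
        lo = weights[sums <= u1 + 1e-9].sum() / total
        hi = weights[sums >= u1 - 1e-9].sum() / total
        p = min(1.0, 2.0 * min(float(lo), float(hi)))
        return TestResult(statistic=float(u1), p_value=p, n=(n1, n2), method="exact")
    if mode == "approx":
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(statistic=float(u1), p_value=1.0, n=(n1, n2), method="normal-approx")
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        return TestResult(statistic=float(u1), p_value=p, n=(n1, n2), method="normal-approx")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA across genes


def rm_anova_genes(deltas) -> TestResult:
    """One-way repeated-measures ANOVA: gene as the within-subject factor.

    ``deltas`` is an animals x genes matrix (DataFrame or array) of per-animal
    per-gene values (e.g. post-minus-pre RQ deltas). F = MS_gene / MS_(gene x
    animal) with df (g-1, (g-1)(a-1)). Missing cells are an error; no
    imputation. Sphericity is taken at face value (no correction), matching
    plain RM-ANOVA reporting.
    """
    if isinstance(deltas, pd.DataFrame):
        X = deltas.to_numpy(dtype=float)
    else:
        X = np.asarray(deltas, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 animals and >= 2 genes")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells in the animal x gene matrix")
    a, g = X.shape
    grand = X.mean()
    ss_subject = g * float(np.sum((X.mean(axis=1) - grand) ** 2))
    ss_gene = a * float(np.sum((X.mean(axis=0) - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_error = max(0.0, ss_total - ss_subject - ss_gene)
    df1, df2 = g - 1, (g - 1) * (a - 1)
    ms_gene = ss_gene / df1
    ms_error = ss_error / df2
    if ms_error == 0.0:
        f = 0.0 if ms_gene == 0.0 else math.inf
        p = 1.0 if ms_gene == 0.0 else 0.0
    else:
        f = ms_gene / ms_error
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(statistic=f, p_value=p, n=a, method="rm-anova", df=(df1, df2))


# ---------------------------------------------------------------------------
# correlation


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    line = sps.linregress(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        slope=float(line.slope),
        intercept=float(line.intercept),
    )


def association_analysis(
    cohort: Sequence[CohortRecord],
    plot_path=None,
) -> dict[str, CorrelationResult]:
    """Per-group Pearson correlation of delta-RQ against the sham-referenced deficit.

    Sign convention (fixed by :class:`CohortRecord`): positive r means larger
    peripheral mtDNA increases accompany larger cerebral bioenergetic deficits.
    All records in one run must share a respiration endpoint; mixing OXPHOS
    with RCR is an error.
    """
    if not cohort:
        raise ValueError("empty cohort")
    endpoints = {rec.endpoint for rec in cohort}
    if len(endpoints) > 1:
        raise ValueError(f"mixed respiration endpoints in one run: {sorted(endpoints)}")
    groups: dict[str, list[CohortRecord]] = {}
    for rec in cohort:
        groups.setdefault(rec.group, []).append(rec)
    results = {
        group: pearson([r.delta_rq for r in recs], [r.delta_resp for r in recs])
        for group, recs in sorted(groups.items())
    }
    if plot_path is not None:
        _plot_association(groups, results, endpoints.pop(), plot_path)
    return results


def _plot_association(groups, results, endpoint, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4), squeeze=False)
    for ax, (group, recs) in zip(axes[0], sorted(groups.items())):
        x = np.array([r.delta_rq for r in recs])
        y = np.array([r.delta_resp for r in recs])
        res = results[group]
        ax.scatter(x, y, s=25, color="tab:blue")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, res.slope * xs + res.intercept, color="tab:red")
        ax.set_title(f"{group}: r={res.r:.2f}, p={res.p_value:.3g} (n={res.n})")
        ax.set_xlabel("delta RQ (post - pre)")
        ax.set_ylabel(f"sham - post {endpoint}")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
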