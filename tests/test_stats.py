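"""Exact nonparametric tests vs enumeration oracles; RM-ANOVA; correlation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
import pandas as pd

from mitosignal import (
    CohortRecord,
    association_analysis,
    make_cohort,
    mann_whitney_u,
    pearson,
    rm_anova_genes,
    wilcoxon_signed_rank,
)

from _oracles import (
    mannwhitney_enumeration_p,
    pearson_permutation_p,
    wilcoxon_enumeration_p,
)


class TestWilcoxon:
    def test_all_positive_shift_closed_form(self):
        """n=6, every post > pre: two-sided p = 2 * (1/2)^6 = 0.03125."""
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = wilcoxon_signed_rank(pre, [x + 1 for x in pre])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.method == "exact"

    def test_swap_symmetry(self, rng):
        pre = rng.normal(size=10)
        post = pre + rng.normal(size=10)
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(
            wilcoxon_signed_rank(post, pre).p_value
        )

    def test_all_zero_differences_warns_p1(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0

    @given(seed=st.integers(0, 5000), n=st.integers(4, 12))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_exact_matches_full_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        pre = rng.normal(size=n)
        post = pre + rng.normal(0.3, 1.0, size=n)
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        w_or, p_or = wilcoxon_enumeration_p(post - pre)
        assert res.statistic == pytest.approx(w_or)
        assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        pre = rng.normal(size=11)
        post = pre + rng.normal(0.5, 1.0, size=11)
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        ref = sps.wilcoxon(post, pre, mode="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_pratt_handles_zero_differences(self):
        """d = [0,1,2,2,3]: zero keeps rank 1, nonzero ranks {2, 3.5, 3.5, 5} all
        positive -> W+ = 14 (the maximum), exact two-sided p = 2/2^4."""
        pre = [1.0, 2.0, 3.0, 4.0, 5.0]
        post = [1.0, 3.0, 5.0, 6.0, 8.0]
        res = wilcoxon_signed_rank(pre, post, zero_policy="pratt", mode="exact")
        assert res.n == 4
        assert res.statistic == pytest.approx(14.0)
        assert res.p_value == pytest.approx(2 / 16)

    def test_monotone_transform_of_differences_invariant(self, rng):
        """Any odd increasing transform of the paired differences preserves p."""
        pre = rng.normal(size=9)
        post = pre + rng.normal(0.2, 1.0, size=9)
        d = post - pre
        for f in (lambda x: 3 * x, lambda x: np.sign(x) * np.abs(x) ** 1.7):
            res1 = wilcoxon_signed_rank(np.zeros_like(d), d)
            res2 = wilcoxon_signed_rank(np.zeros_like(d), f(d))
            assert res1.p_value == pytest.approx(res2.p_value)


class TestMannWhitney:
    def test_extreme_arrangement_closed_form(self):
        """All of a below all of b at n1=n2=3: p = 2 / C(6,3) = 0.1."""
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_p1(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    @given(seed=st.integers(0, 5000), n1=st.integers(2, 6), n2=st.integers(2, 7))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_exact_matches_enumeration(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n1)
        b = rng.normal(0.5, 1.2, size=n2)
        res = mann_whitney_u(a, b, mode="exact")
        u_or, p_or = mannwhitney_enumeration_p(a, b)
        assert res.statistic == pytest.approx(u_or)
        assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_ties_handled_by_enumeration(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 3.0, 4.0]
        res = mann_whitney_u(a, b, mode="exact")
        u_or, p_or = mannwhitney_enumeration_p(a, b)
        assert res.statistic == pytest.approx(u_or)
        assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(0.4, 1.0, size=8)
        base = mann_whitney_u(a, b).p_value
        for f in (np.exp, lambda x: x**3, lambda x: 10 * x + 2):
            assert mann_whitney_u(f(a), f(b)).p_value == pytest.approx(base)

    def test_agrees_with_scipy_exact(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=7)
        res = mann_whitney_u(a, b, mode="exact")
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue)


class TestRmAnova:
    def test_identical_genes_give_f0_p1(self):
        X = np.array([[1.0, 1.0, 1.0], [2.5, 2.5, 2.5], [0.3, 0.3, 0.3]])
        res = rm_anova_genes(X)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_manual_sum_of_squares_example(self):
        """Hand-worked 3 animals x 4 genes example.

        X = [[1,2,3,4],[2,3,4,5],[3,5,4,6]]; grand mean = 3.5
        SS_gene = 3*((2-3.5)^2+(10/3-3.5)^2+(11/3-3.5)^2+(5-3.5)^2) = 13.667
        SS_subject = 4*((2.5-3.5)^2+(3.5-3.5)^2+(4.5-3.5)^2) = 8
        SS_total = 23; SS_err = 1.333; F = (13.667/3)/(1.333/6) = 20.5
        """
        X = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0], [3.0, 5.0, 4.0, 6.0]])
        res = rm_anova_genes(X)
        assert res.statistic == pytest.approx(20.5, rel=1e-9)
        assert res.df == (3, 6)
        assert res.p_value == pytest.approx(float(sps.f.sf(20.5, 3, 6)), rel=1e-9)

    def test_row_shift_invariance(self, rng):
        X = rng.normal(size=(6, 3))
        res1 = rm_anova_genes(X)
        X2 = X.copy()
        X2[2] += 7.3  # constant added to one animal's whole row
        res2 = rm_anova_genes(X2)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_matches_statsmodels(self, rng):
        X = rng.normal(size=(8, 3))
        res = rm_anova_genes(X)
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "animal": np.repeat(np.arange(8), 3),
                "gene": np.tile(np.arange(3), 8),
            }
        )
        ref = AnovaRM(long, depvar="y", subject="animal", within=["gene"]).fit()
        assert res.statistic == pytest.approx(float(ref.anova_table["F Value"].iloc[0]))
        assert res.p_value == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]))

    def test_missing_cells_raise(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_genes(X)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation(self):
        x = np.arange(8.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = pearson(x, y)
        p_perm = pearson_permutation_p(x, y, n_perm=100_000, seed=3)
        assert res.p_value == pytest.approx(p_perm, abs=0.01)


class TestAssociation:
    def test_recovers_generator_correlation(self):
        records, _ = make_cohort(2, n=100, true_r=0.9, sham_mean_flux=82.6)
        res = association_analysis(records)["RNR-6h"]
        assert abs(res.r - 0.9) < 0.08

    def test_constant_sham_equal_post_raises(self):
        recs = [
            CohortRecord(f"a{i}", "g", delta_rq=float(i), post_resp=76.0, sham_mean=76.0) for i in range(5)
        ]
        with pytest.raises(ValueError, match="variance"):
            association_analysis(recs)

    def test_mixed_endpoints_rejected(self):
        recs = [
            CohortRecord("a", "g", 1.0, 70.0, 82.6, endpoint="OXPHOS_CI+CII"),
            CohortRecord("b", "g", 2.0, 71.0, 82.6, endpoint="RCR"),
            CohortRecord("c", "g", 3.0, 72.0, 82.6, endpoint="RCR"),
        ]
        with pytest.raises(ValueError, match="endpoint"):
            association_analysis(recs)

    def test_sham_reference_carried_verbatim(self):
        records, _ = make_cohort(4, n=10, true_r=0.5, sham_mean_flux=82.6)
        assert all(r.sham_mean == 82.6 for r in records)
        records_rcr, _ = make_cohort(
            4, n=10, true_r=0.5, sham_mean_flux=5.91, endpoint="RCR"
        )
        assert all(r.sham_mean == 5.91 for r in records_rcr)
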