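"""Mann-Whitney ranking, permutation FDR, chi-square and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import csfmarker.simulate as sim
from csfmarker.simulate import CohortDesign
import csfmarker.stats as _stats
from csfmarker.stats import (
    chi_square_homogeneity,
    global_fdr_curve,
    local_fdr,
    mann_whitney,
    proteoform_sum_test,
    suppression_diagnostic,
)


def enumeration_mwu(x, y):
    """Exhaustive two-sided MWU oracle: enumerate all group assignments of
    the pooled tie-free sample and count arrangements with U at least as
    extreme (min of the two one-sided statistics) as observed."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_min(xs, ys):
        u1 = sum((xi > yj) for xi in xs for yj in ys)
        return min(u1, len(xs) * len(ys) - u1)

    observed = u_min(x, y)
    total = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(combo)] = True
        if u_min(pooled[mask], pooled[~mask]) <= observed:
            hits += 1
        total += 1
    u1 = sum((xi > yj) for xi in x for yj in y)
    return float(u1), hits / total


class TestMannWhitney:
    def test_printed_example(self):
        u, p = mann_whitney([5, 6, 7], [1, 2, 3])
        assert u == 9 and p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_branch_matches_enumeration(self, rng):
        for n1, n2 in [(2, 2), (3, 3), (2, 6), (4, 4), (5, 3)]:
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            u, p = mann_whitney(x, y)
            u_o, p_o = enumeration_mwu(x, y)
            assert u == u_o
            assert p == pytest.approx(p_o, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=-3, max_value=3))
    def test_invariant_under_monotone_transform(self, scale, shift):
        x = np.array([1.0, 4.0, 6.0, 9.0])
        y = np.array([2.0, 3.0, 7.0, 8.0])
        _, p0 = mann_whitney(x, y)
        _, p1 = mann_whitney(np.exp(scale * x + shift), np.exp(scale * y + shift))
        assert p1 == pytest.approx(p0, rel=1e-12)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


def _meta(n1=10, n2=10, age="P90"):
    rows = [(f"e{i}", "ENU", age) for i in range(n1)] + [
        (f"c{i}", "control", age) for i in range(n2)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "age"])


class TestTestAllPeaks:
    def test_huge_effect_ranks_first(self, rng):
        meta = _meta()
        cols = list(meta["sample_id"])
        mat = pd.DataFrame(
            rng.normal(10, 1, (30, 20)), index=[f"p{i}" for i in range(30)], columns=cols
        )
        mat.loc["p7", meta.query("group=='ENU'")["sample_id"]] += 50.0
        out = _stats.test_all_peaks(mat, meta, "P90")
        assert out.iloc[0]["peak_id"] == "p7"
        assert (out["p_value"].diff().dropna() >= 0).all()

    def test_missing_group_rejected(self, rng):
        meta = _meta().query("group=='ENU'")
        mat = pd.DataFrame(
            rng.normal(size=(3, 10)), index=list("abc"), columns=meta["sample_id"]
        )
        with pytest.raises(ValueError):
            _stats.test_all_peaks(mat, meta, "P90")

    def test_group_summaries_match_numpy(self, rng):
        meta = _meta(4, 5)
        mat = pd.DataFrame(
            rng.normal(10, 2, (2, 9)), index=["a", "b"], columns=meta["sample_id"]
        )
        out = _stats.test_all_peaks(mat, meta, "P90").set_index("peak_id")
        enu = mat[meta.query("group=='ENU'")["sample_id"]]
        assert out.loc["a", "mean_enu"] == pytest.approx(enu.loc["a"].mean())
        assert out.loc["a", "sem_enu"] == pytest.approx(
            enu.loc["a"].std(ddof=1) / np.sqrt(4)
        )


class TestGlobalFDR:
    def test_null_curve_tracks_threshold_times_peaks(self):
        proteins, _ = sim.null_panel(seed=0)
        mat, truth = sim.simulate_peak_matrix(CohortDesign(seed=0), proteins, None)
        curve = global_fdr_curve(mat, truth.metadata, "P90", n_perm=100, seed=1)
        expected = 0.05 * mat.shape[0]
        assert curve.null_mean[-1] == pytest.approx(expected, rel=0.2)
        # exchangeability: observed within Monte-Carlo range of the null
        assert abs(curve.observed[-1] - curve.null_mean[-1]) < 4 * np.sqrt(expected)

    def test_planted_effects_exceed_null_at_small_p(self, default_cohort):
        mat, truth = default_cohort
        curve = global_fdr_curve(mat, truth.metadata, "P90", n_perm=50, seed=2)
        small = curve.thresholds <= 0.01
        assert (curve.observed[small] > 3 * curve.null_mean[small]).all()

    def test_counts_nondecreasing(self, default_cohort):
        mat, truth = default_cohort
        curve = global_fdr_curve(mat, truth.metadata, "P60", n_perm=20, seed=3)
        assert (np.diff(curve.observed) >= 0).all()
        assert (np.diff(curve.null_mean) >= -1e-9).all()


class TestLocalFDR:
    def test_constant_matrix_gives_one(self):
        meta = _meta(5, 5)
        mat = pd.DataFrame(
            np.ones((10, 10)), index=[f"p{i}" for i in range(10)],
            columns=meta["sample_id"],
        )
        lf = local_fdr(mat, meta, "P90", n_perm=20, seed=0)
        assert (lf == 1.0).all()

    def test_bounded_and_monotone_in_p(self, default_cohort):
        mat, truth = default_cohort
        lf = local_fdr(mat, truth.metadata, "P90", n_perm=50, seed=4)
        assert ((lf >= 0) & (lf <= 1)).all()
        tests = _stats.test_all_peaks(mat, truth.metadata, "P90")
        ordered = lf.reindex(tests["peak_id"]).to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_null_cohort_high_everywhere(self):
        proteins, _ = sim.null_panel(seed=1)
        mat, truth = sim.simulate_peak_matrix(CohortDesign(seed=1), proteins, None)
        lf = local_fdr(mat, truth.metadata, "P90", n_perm=100, seed=5)
        assert lf.mean() >= 0.8
        tests = _stats.test_all_peaks(mat, truth.metadata, "P90")
        smallest_decile = tests["peak_id"].iloc[: len(tests) // 10]
        assert lf[smallest_decile].median() >= 0.25

    def test_bandwidth_validated(self, default_cohort):
        mat, truth = default_cohort
        with pytest.raises(ValueError):
            local_fdr(mat, truth.metadata, "P90", bandwidth=0.5)


class TestChiSquare:
    def test_printed_microtumor_table(self):
        stat, dof, p = chi_square_homogeneity([[0, 20], [4, 18], [14, 7]])
        assert stat == pytest.approx(24.1, abs=0.1)
        assert dof == 2
        assert p < 0.001

    def test_equal_proportions_zero_statistic(self):
        stat, dof, p = chi_square_homogeneity([[5, 10], [10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_2x2(self):
        stat, dof, _ = chi_square_homogeneity([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_homogeneity([[0, 5], [0, 7]])


class TestDiagnostics:
    def test_exact_line_gives_r_minus_one(self):
        meta = _meta(3, 3)
        a = np.arange(1.0, 7.0)
        mat = pd.DataFrame(
            [a, -2 * a + 10], index=["a", "b"], columns=meta["sample_id"]
        )
        r, slope, intercept = suppression_diagnostic(mat, "a", "b")
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-2.0)
        assert intercept == pytest.approx(10.0)

    def test_simulated_suppression_strongly_negative(self, default_cohort):
        mat, _ = default_cohort
        r, _, _ = suppression_diagnostic(
            mat, "albumin||parent|high", "pgd2s||parent|high"
        )
        assert r <= -0.8

    def test_independent_peaks_weak(self, rng):
        meta = _meta(22, 23)
        mat = pd.DataFrame(
            rng.normal(10, 1, (2, 45)), index=["a", "b"], columns=meta["sample_id"]
        )
        r, _, _ = suppression_diagnostic(mat, "a", "b")
        assert abs(r) < 0.3

    def test_zero_variance_rejected(self):
        meta = _meta(3, 3)
        mat = pd.DataFrame(
            [np.ones(6), np.arange(6.0)], index=["a", "b"], columns=meta["sample_id"]
        )
        with pytest.raises(ValueError):
            suppression_diagnostic(mat, "a", "b")


class TestProteoformSum:
    def test_single_peak_family_equals_peak_test(self, default_cohort):
        mat, truth = default_cohort
        peak = "albumin||parent|high"
        fam = proteoform_sum_test(mat, truth.metadata, [peak], "P90")
        tests = _stats.test_all_peaks(mat, truth.metadata, "P90").set_index("peak_id")
        assert fam["p_value"] == pytest.approx(tests.loc[peak, "p_value"], rel=1e-9)
        assert fam["u_stat"] == pytest.approx(tests.loc[peak, "u_stat"])

    def test_sum_is_additive_over_disjoint_families(self, default_cohort):
        mat, truth = default_cohort
        f1 = ["albumin||parent|high", "albumin||z2|high"]
        f2 = ["pgd2s||parent|high"]
        both = proteoform_sum_test(mat, truth.metadata, f1 + f2, "P90")
        s1 = mat.loc[f1].sum(axis=0) + mat.loc[f2].sum(axis=0)
        meta = truth.metadata.query("age=='P90'")
        assert both["mean_enu"] == pytest.approx(
            s1[meta.query("group=='ENU'")["sample_id"]].mean()
        )

    def test_empty_family_rejected(self, default_cohort):
        mat, truth = default_cohort
        with pytest.raises(ValueError):
            proteoform_sum_test(mat, truth.metadata, [], "P90")
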