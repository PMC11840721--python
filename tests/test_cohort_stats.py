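import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fibropet.cohort_stats import (
    cohort_deltas,
    delta_longitudinal,
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney,
    median_iqr,
    predictive_correlation,
    quantify_cohort,
    run_study_analysis,
    significance_stars,
    spearman,
)
from fibropet.phantom import default_study_design, simulate_cohort


class TestMedianIqr:
    def test_worked_example(self):
        r = median_iqr([1, 2, 3, 4, 5])
        assert r == {"median": 3.0, "q1": 2.0, "q3": 4.0}

    def test_singleton(self):
        assert median_iqr([7.0]) == {"median": 7.0, "q1": 7.0, "q3": 7.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    @given(
        vals=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
        c=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_equivariance(self, vals, c):
        base = median_iqr(vals)
        shifted = median_iqr([v + c for v in vals])
        for k in ("median", "q1", "q3"):
            assert shifted[k] == pytest.approx(base[k] + c, abs=1e-6)


def _brute_force_mw_p(a, b):
    """Independent oracle: enumerate labelings, recompute U by pair counting."""
    pooled = list(a) + list(b)
    na, n = len(a), len(pooled)

    def u_of(ix):
        a_vals = [pooled[i] for i in ix]
        b_vals = [pooled[i] for i in range(n) if i not in set(ix)]
        u = 0.0
        for x in a_vals:
            for y in b_vals:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    mu = na * (n - na) / 2.0
    obs = abs(u_of(tuple(range(na))) - mu)
    hits = total = 0
    for ix in itertools.combinations(range(n), na):
        if abs(u_of(ix) - mu) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_worked_example_u_zero(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_symmetric_u(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(4.5)  # n_a*n_b/2

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        na = rng.integers(2, 5)
        nb = rng.integers(2, 5)
        pool = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
        a, b = pool[:na], pool[na:]
        r = mann_whitney(a, b, mode="exact")
        assert r.p_value == pytest.approx(_brute_force_mw_p(a, b))

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 7)
        r = mann_whitney(a, b, mode="exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        r = mann_whitney(a, b, mode="normal_approx")
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney([1, 1, 2], [2, 3, 4], mode="exact")


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_worked_example(self):
        # rank sums 3, 7, 11 -> H = 12/(6*7)*(9/2+49/2+121/2) - 21 = 4.571
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(4.571, abs=5e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 9) for m in (0.0, 0.5, 1.2)]
        r = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_chi2_close_to_enumeration_at_n8(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 3), rng.normal(0.8, 1, 3), rng.normal(0.4, 1, 2)]
        approx = kruskal_wallis(groups).p_value
        exact = kruskal_wallis(groups, exact=True).p_value
        assert abs(approx - exact) < 0.05

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunnBonferroni:
    def test_two_groups_adjusted_equals_raw(self):
        r = dunn_bonferroni([[1, 2], [3, 4]], labels=("a", "b"))
        assert r.n_comparisons == 1
        assert r.adjusted_p("a", "b") == pytest.approx(r.raw_p("a", "b"))

    def test_hand_computed_z(self):
        # ranks 1..4, mean ranks 1.5 vs 3.5, var = (4*5/12)*(1/2+1/2)
        r = dunn_bonferroni([[1, 2], [3, 4]], labels=("a", "b"))
        z = 2.0 / math.sqrt(20.0 / 12.0)
        assert abs(r.z[0, 1]) == pytest.approx(z)
        assert r.raw_p("a", "b") == pytest.approx(2 * sps.norm.sf(z))

    def test_identical_groups_p_one(self):
        r = dunn_bonferroni([[2, 2], [2, 2], [2, 2]])
        assert np.all(r.p_adjusted == 1.0)

    def test_adjustment_monotone_and_clipped(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.3, 0.6, 2.5)]
        r = dunn_bonferroni(groups)
        assert np.all(r.p_adjusted >= r.p_raw - 1e-15)
        assert np.all(r.p_adjusted <= 1.0)


def _brute_force_spearman_p(x, y):
    """Oracle: full permutation of y, rho via np.corrcoef of ranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30]).rho == pytest.approx(1.0)
        assert spearman(x, [30, 16, 9, 4, 2]).rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration_n5(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 5)
        y = 0.8 * x + rng.normal(0, 0.5, 5)
        r = spearman(x, y)
        assert r.p_value == pytest.approx(_brute_force_spearman_p(x, y))

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        r = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_undefined(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r.rho)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        base = spearman(x, y)
        trans = spearman(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho)
        assert trans.p_value == pytest.approx(base.p_value)


class TestDeltas:
    def test_worked_example(self):
        d = delta_longitudinal({8: 2.1, 22: 5.3}, "uptake", "s1")
        assert d.delta == pytest.approx(3.2)

    def test_equal_values_zero(self):
        assert delta_longitudinal({8: 4.0, 22: 4.0}, "mld").delta == 0.0

    def test_missing_timepoint_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            delta_longitudinal({8: 2.0}, "uptake")

    def test_additive_over_intervals(self):
        vals = {0: 1.0, 8: 2.5, 22: 7.0}
        d_02 = delta_longitudinal(vals, "m", t0=0, t1=22).delta
        d_01 = delta_longitudinal(vals, "m", t0=0, t1=8).delta
        d_12 = delta_longitudinal(vals, "m", t0=8, t1=22).delta
        assert d_02 == pytest.approx(d_01 + d_12)


class TestSignificanceStars:
    def test_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == "ns"


def _toy_df():
    rows = []
    rng = np.random.default_rng(0)
    for g, slope in (("BLM", 1.0), ("BLM+nintedanib", -1.0)):
        for i in range(5):
            base = 1.0 + 0.2 * i
            rows.append(dict(subject_id=f"{g}{i}", group=g, day=8,
                             uptake=base, mld=-600.0))
            rows.append(dict(subject_id=f"{g}{i}", group=g, day=22,
                             uptake=base + slope, mld=-600.0 + slope * base * 50))
    return pd.DataFrame(rows)


class TestPredictiveCorrelation:
    def test_signs_by_construction(self):
        res = predictive_correlation(_toy_df())
        by_group = {r.group: r for r in res}
        assert by_group["BLM"].rho > 0
        assert by_group["BLM+nintedanib"].rho < 0

    def test_small_group_skipped_with_warning(self):
        df = _toy_df()
        df = pd.concat(
            [df, pd.DataFrame([
                dict(subject_id="x1", group="tiny", day=8, uptake=1, mld=-600),
                dict(subject_id="x1", group="tiny", day=22, uptake=2, mld=-550),
            ])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = predictive_correlation(df)
        assert all(r.group != "tiny" for r in res)


@pytest.fixture(scope="module")
def quantified(tiny_config):
    design = default_study_design(
        n_per_group=3, groups=("NaCl", "BLM", "BLM+nintedanib")
    )
    records = simulate_cohort(design, config=tiny_config, seed=123)
    return quantify_cohort(records)


class TestStudyAnalysis:
    def test_report_complete(self, quantified):
        report = run_study_analysis(quantified)
        assert set(report.summary["group"]) == {"NaCl", "BLM", "BLM+nintedanib"}
        assert set(report.summary["day"]) == {0, 8, 15, 22}
        assert {"uptake", "mld"} <= set(report.summary["metric"])
        assert not report.deltas.empty
        groups_corr = {c.group for c in report.correlations}
        assert {"pooled", "BLM", "BLM+nintedanib"} <= groups_corr

    def test_report_deterministic(self, quantified):
        r1 = run_study_analysis(quantified)
        r2 = run_study_analysis(quantified)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        pd.testing.assert_frame_equal(r1.deltas, r2.deltas)

    def test_report_written_to_disk(self, quantified, tmp_path):
        report = run_study_analysis(quantified)
        report.write(tmp_path)
        for name in ("summary.csv", "deltas.csv", "correlations.csv", "tests.json"):
            assert (tmp_path / name).exists()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_study_analysis(pd.DataFrame())
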