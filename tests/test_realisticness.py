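"""Statistical-test oracles, verdict hierarchy, Kendall correlation stages."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from healthgym.realisticness import (
    DISTRIBUTION_MATCHED,
    FAILED,
    MOMENT_MATCHED,
    RANGE_PLAUSIBLE,
    anova_f_test,
    dynamic_kendall,
    f_test,
    hierarchical_validate,
    ks_test,
    render_report,
    static_kendall,
    t_test,
    three_sigma_test,
    top_pairs,
    trend_cycle_decompose,
    verdict_of,
)
from healthgym.schema import (
    CohortSchema,
    LongitudinalDataset,
    SchemaError,
    VariableSpec,
)
from healthgym.simulator import SimulatorConfig, simulate_cohort


def brute_ks(a, b):
    """ECDF sup-distance by direct evaluation at every observed point."""
    pts = np.concatenate([a, b])
    fa = np.array([(a <= p).mean() for p in pts])
    fb = np.array([(b <= p).mean() for p in pts])
    return np.abs(fa - fb).max()


def brute_t(a, b):
    """Textbook pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1)) + ((nb - 1) * b.var(ddof=1))) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestComponentOracles:
    def test_ks_identical_and_disjoint(self):
        x = np.arange(10.0)
        assert ks_test(x, x)[0] == 0.0
        assert ks_test(x, x + 100.0)[0] == 1.0

    def test_ks_toy_half_overlap(self):
        # {1,2,3,4} vs {3,4,5,6}: ECDF sup-distance exactly 0.5
        stat, _ = ks_test([1, 2, 3, 4], [3, 4, 5, 6])
        assert stat == pytest.approx(0.5, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 50), st.integers(5, 50))
    @settings(max_examples=25, deadline=None)
    def test_ks_matches_brute_force(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=na)
        b = rng.normal(0.5, 1.3, size=nb)
        assert ks_test(a, b)[0] == pytest.approx(brute_ks(a, b), abs=1e-10)

    def test_t_equal_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = t_test(x, x)
        assert stat == 0.0 and p == 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_t_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=20), rng.normal(0.3, 1.0, size=15)
        assert t_test(a, b)[0] == pytest.approx(brute_t(a, b), abs=1e-10)

    def test_t_power_at_one_sigma_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=1000)
        b = rng.normal(1.0, 1.0, size=1000)
        assert t_test(a, b)[1] < 0.05

    def test_t_rejects_single_observation(self):
        with pytest.raises(SchemaError):
            t_test([1.0], [2.0])

    def test_f_equal_samples_unit_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, p = f_test(x, x)
        assert stat == 1.0 and p == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_f_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=12), rng.normal(size=18)
        stat, p = f_test(a, b)
        F = a.var(ddof=1) / b.var(ddof=1)
        assert stat == pytest.approx(F, abs=1e-10)
        tail = stats.f.cdf(F, 11, 17)
        assert p == pytest.approx(2 * min(tail, 1 - tail), abs=1e-10)

    def test_f_detects_variance_ratio_four(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=500)
        b = rng.normal(0, 2, size=500)
        assert f_test(a, b)[1] < 0.05

    def test_f_rejects_zero_variance(self):
        with pytest.raises(SchemaError):
            f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_anova_identical_shares_statistic_zero(self):
        real = np.repeat([0, 1, 2], 100)
        syn = np.repeat([0, 1, 2], 100)
        stat, p = anova_f_test(real, syn, [0, 1, 2])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_anova_detects_swapped_share(self):
        rng = np.random.default_rng(2)
        real = rng.choice([0, 1, 2], p=[0.60, 0.34, 0.06], size=2000)
        syn = rng.choice([0, 1, 2], p=[0.06, 0.34, 0.60], size=2000)
        assert anova_f_test(real, syn, [0, 1, 2])[1] < 0.05

    def test_anova_rejects_single_class(self):
        with pytest.raises(SchemaError):
            anova_f_test([0, 0], [0, 0], [0])

    def test_three_sigma_self_consistent_gaussian(self):
        rng = np.random.default_rng(3)
        real = rng.normal(size=5000)
        syn = rng.normal(size=5000)
        frac, ok = three_sigma_test(real, syn)
        assert ok and frac >= 0.997

    def test_three_sigma_fails_on_large_shift(self):
        rng = np.random.default_rng(4)
        real = rng.normal(size=500)
        syn = rng.normal(10.0, 1.0, size=500)
        frac, ok = three_sigma_test(real, syn)
        assert frac < 0.01 and not ok

    def test_three_sigma_fraction_matches_hand_count(self):
        rng = np.random.default_rng(5)
        real = np.exp(rng.normal(size=200))
        syn = np.exp(rng.normal(size=200))
        m, s = real.mean(), real.std(ddof=1)
        hand = np.mean((syn >= m - 3 * s) & (syn <= m + 3 * s))
        frac, _ = three_sigma_test(real, syn)
        assert frac == pytest.approx(hand, abs=1e-12)


class TestVerdictHierarchy:
    @pytest.mark.parametrize(
        "ks,par,sig", list(itertools.product(
            [True, False], [(True, True), (True, False), (False, False)],
            [True, False]))
    )
    def test_verdict_is_pure_function_of_outcomes(self, ks, par, sig):
        v = verdict_of(ks, list(par), sig)
        if ks:
            assert v == DISTRIBUTION_MATCHED
        elif all(par):
            assert v == MOMENT_MATCHED
        elif sig:
            assert v == RANGE_PLAUSIBLE
        else:
            assert v == FAILED

    def test_bootstrap_resample_mostly_distribution_matched(self, toy_cohort_large):
        rng = np.random.default_rng(6)
        T = toy_cohort_large.schema.timesteps_per_patient
        idx = rng.integers(0, toy_cohort_large.n_patients,
                           toy_cohort_large.n_patients)
        rows = np.concatenate([np.arange(i * T, (i + 1) * T) for i in idx])
        frame = toy_cohort_large.frame.iloc[rows].copy()
        frame["pid"] = np.repeat([f"b{i:04d}" for i in range(len(idx))], T)
        syn = LongitudinalDataset(toy_cohort_large.schema, frame)
        report = hierarchical_validate(toy_cohort_large, syn,
                                       include_correlations=False)
        n_ok = report.n_with_verdict(DISTRIBUTION_MATCHED)
        assert n_ok >= 0.9 * len(report.results)

    def test_bimodal_same_moments_is_moment_matched(self):
        # mirrors the pattern where a lab fails KS but keeps mean/variance
        rng = np.random.default_rng(7)
        sch = CohortSchema("mini", (VariableSpec("x", "numeric"),), "pid", "t", 1)
        n = 4000
        real_v = rng.normal(0.0, 1.0, size=n)
        syn_v = np.where(rng.random(n) < 0.5, -1.0, 1.0) + rng.normal(
            0, 0.05, size=n)
        syn_v = (syn_v - syn_v.mean()) / syn_v.std(ddof=1)

        def ds(v):
            return LongitudinalDataset(sch, pd.DataFrame(
                {"x": v, "pid": [f"p{i}" for i in range(n)], "t": 0}))

        report = hierarchical_validate(ds(real_v), ds(syn_v),
                                       include_correlations=False)
        res = report.results[0]
        assert res.verdict == MOMENT_MATCHED
        assert res.ks[1] < 0.05 and res.t[1] >= 0.05 and res.f[1] >= 0.05

    def test_variance_inflated_bounded_is_range_plausible(self):
        # mirrors the skewed-variable pattern: F fails, three-sigma passes
        rng = np.random.default_rng(8)
        sch = CohortSchema("mini", (VariableSpec("x", "numeric"),), "pid", "t", 1)
        n = 3000
        real_v = rng.normal(0.0, 1.0, size=n)
        syn_v = rng.uniform(-2.0, 2.0, size=n)  # var 4/3, hard KS fail

        def ds(v):
            return LongitudinalDataset(sch, pd.DataFrame(
                {"x": v, "pid": [f"p{i}" for i in range(n)], "t": 0}))

        report = hierarchical_validate(ds(real_v), ds(syn_v),
                                       include_correlations=False)
        res = report.results[0]
        assert res.verdict == RANGE_PLAUSIBLE
        assert res.f[1] < 0.05 and res.three_sigma[1]


class TestStageThree:
    def test_static_kendall_self_unit(self, toy_cohort):
        m = static_kendall(toy_cohort)
        assert np.allclose(np.diag(m.r), 1.0)
        assert np.allclose(m.r, m.r.T)

    def test_static_kendall_recovers_copula_tau(self):
        sch = CohortSchema(
            "pair", (VariableSpec("x", "numeric"), VariableSpec("y", "numeric")),
            "pid", "t", 10,
        )
        cfg = SimulatorConfig(
            schema=sch, n_patients=500,
            latent_corr=np.array([[1.0, 0.5], [0.5, 1.0]]),
            ar_coefficient=0.0,
            marginals={"x": ("lognormal", 0.0, 1.0), "y": ("normal", 0.0, 1.0)},
            cutpoints={}, indicator_rate={}, seed=31,
        )
        ds = simulate_cohort(cfg)
        m = static_kendall(ds)
        n = len(ds)
        se = np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(m.r[0, 1] - 1.0 / 3.0) < 3 * se

    def test_trend_cycle_reconstruction_exact(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=17)
        trend, cycle = trend_cycle_decompose(y)
        assert np.allclose(trend + cycle, y, atol=1e-12)
        # idempotent on trends
        t2, c2 = trend_cycle_decompose(trend)
        assert np.allclose(t2, trend, atol=1e-10) and np.allclose(c2, 0, atol=1e-10)

    def test_pure_line_has_zero_cycle(self):
        y = 2.0 + 3.0 * np.arange(10)
        _, cycle = trend_cycle_decompose(y)
        assert np.abs(cycle).max() < 1e-10

    def test_even_oscillation_on_symmetric_grid_has_flat_trend(self):
        # cos is even about the grid centre, so the OLS slope vanishes
        t = np.arange(21)
        y = np.cos(2 * np.pi * (t - 10) / 21)
        trend, _ = trend_cycle_decompose(y)
        assert abs(trend[-1] - trend[0]) < 1e-10

    def test_trend_matches_hand_ols_on_length_five_series(self):
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        t = np.arange(5.0)
        slope = ((t - 2.0) * (y - y.mean())).sum() / ((t - 2.0) ** 2).sum()
        intercept = y.mean() - slope * 2.0
        trend, _ = trend_cycle_decompose(y)
        assert np.allclose(trend, intercept + slope * t, atol=1e-12)

    def test_dynamic_kendall_shared_monotone_trends(self):
        # every patient trends upward in both variables -> trend tau 1
        sch = CohortSchema(
            "pair", (VariableSpec("x", "numeric"), VariableSpec("y", "numeric")),
            "pid", "t", 6,
        )
        rows = []
        rng = np.random.default_rng(10)
        for p in range(8):
            base = rng.normal()
            for t in range(6):
                rows.append({"x": base + t + rng.normal(0, 0.01),
                             "y": base + 2 * t + rng.normal(0, 0.01),
                             "pid": f"p{p}", "t": t})
        ds = LongitudinalDataset(sch, pd.DataFrame(rows))
        trend_m, _ = dynamic_kendall(ds)
        assert trend_m.r[0, 1] == pytest.approx(1.0)

    def test_dynamic_kendall_hand_average(self):
        # per-patient trend-sign products {+1, -1, +1} average to 1/3
        sch = CohortSchema(
            "pair", (VariableSpec("x", "numeric"), VariableSpec("y", "numeric")),
            "pid", "t", 4,
        )
        rows = []
        slopes = [(1, 1), (1, -1), (-1, -1)]
        for p, (sx, sy) in enumerate(slopes):
            for t in range(4):
                rows.append({"x": sx * t + 0.0, "y": sy * t + 0.0,
                             "pid": f"p{p}", "t": t})
        ds = LongitudinalDataset(sch, pd.DataFrame(rows))
        trend_m, _ = dynamic_kendall(ds)
        assert trend_m.r[0, 1] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_dynamic_kendall_independent_cycles_near_zero(self):
        sch = CohortSchema(
            "pair", (VariableSpec("x", "numeric"), VariableSpec("y", "numeric")),
            "pid", "t", 12,
        )
        cfg = SimulatorConfig(
            schema=sch, n_patients=300, latent_corr=np.eye(2),
            ar_coefficient=0.0,
            marginals={"x": ("normal", 0.0, 1.0), "y": ("normal", 0.0, 1.0)},
            cutpoints={}, indicator_rate={}, seed=12,
        )
        _, cycle_m = dynamic_kendall(simulate_cohort(cfg))
        assert abs(cycle_m.r[0, 1]) < 0.02


class TestRendering:
    def test_report_files_written(self, toy_cohort, tmp_path):
        syn = simulate_cohort(
            SimulatorConfig(
                schema=toy_cohort.schema, n_patients=40,
                latent_corr=np.eye(5), ar_coefficient=0.3,
                marginals={"alpha": ("lognormal", 0.7, 0.5),
                           "beta": ("lognormal", 3.0, 0.5),
                           "gamma": ("normal", 0.0, 0.8)},
                cutpoints={"grade": (0.6, 0.85)},
                indicator_rate={"alpha (M)": 0.25}, seed=77,
            )
        )
        report = hierarchical_validate(toy_cohort, syn)
        written = render_report(report, toy_cohort, syn, tmp_path / "out")
        import pathlib

        for key in ("distributions", "static_correlations", "summary_csv",
                    "summary_json", "top_pairs"):
            assert pathlib.Path(written[key]).exists()

    def test_top_pairs_sorted_by_magnitude(self):
        from healthgym.gan import CorrelationMatrix

        rng = np.random.default_rng(13)
        C = 8
        r = rng.uniform(-1, 1, size=(C, C))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        m = CorrelationMatrix(r, [f"v{i}" for i in range(C)])
        pairs = top_pairs(m, 20)
        mags = [abs(t) for _, _, t in pairs]
        assert mags == sorted(mags, reverse=True)
        # matches an exhaustive sort of the strict upper triangle
        all_pairs = sorted(
            (abs(r[i, j]) for i in range(C) for j in range(i + 1, C)),
            reverse=True,
        )
        assert mags == pytest.approx(all_pairs[:20])

    def test_empty_report_rejected(self, toy_cohort, tmp_path):
        from healthgym.realisticness import ValidationReport

        with pytest.raises(SchemaError, match="empty"):
            render_report(ValidationReport([], 0.05), toy_cohort, toy_cohort,
                          tmp_path)
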