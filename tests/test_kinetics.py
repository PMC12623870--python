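"""Normalization, the grid-search biexponential fitter, rates, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import curve_fit

from aidquant.kinetics import (GridSpec, biexp_model, fit_biexponential,
                               fit_initial_rate, group_compare,
                               loss_delta_analysis, normalize_table,
                               normalize_to_reference, per_synapse_correlation,
                               population_average)


class TestNormalization:
    def test_reference_division(self):
        tr = normalize_to_reference([-1.0, 1.0, 2.0], [10.0, 8.0, 5.0], 0.0)
        np.testing.assert_allclose(tr.values, [1.0, 0.8, 0.5])
        assert tr.reference_index == 0

    def test_scale_invariance(self):
        t, v = [-1.0, 1.0, 2.0], np.array([10.0, 8.0, 5.0])
        a = normalize_to_reference(t, v, 0.0).values
        b = normalize_to_reference(t, 7.3 * v, 0.0).values
        np.testing.assert_allclose(a, b)

    def test_no_pre_inducer_point_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference([1.0, 2.0], [1.0, 2.0], 0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference([-1.0, 1.0], [0.0, 2.0], 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(-2.0, 10.0)
        v = rng.uniform(0.5, 2.0, t.size)
        once = normalize_to_reference(t, v, 0.0).values
        twice = normalize_to_reference(t, once, 0.0).values
        np.testing.assert_allclose(once, twice)

    def test_table_drops_bad_traces(self):
        df = pd.DataFrame(
            {
                "punctum_id": [0, 0, 1, 1],
                "channel": "t",
                "time_h": [-1.0, 1.0, -1.0, 1.0],
                "corrected": [10.0, 5.0, 0.0, 3.0],
            }
        )
        out = normalize_table(df, 0.0)
        assert set(out["punctum_id"]) == {0}


class TestPopulationAverage:
    def test_identical_traces(self):
        df = pd.DataFrame(
            {
                "neuron_id": [0, 0, 1, 1],
                "punctum_id": [0, 0, 1, 1],
                "time_h": [0.0, 1.0, 0.0, 1.0],
                "normalized": [1.0, 0.5, 1.0, 0.5],
            }
        )
        pop = population_average(df)
        np.testing.assert_allclose(pop["mean"], [1.0, 0.5])
        np.testing.assert_allclose(pop["sd"], [0.0, 0.0])

    def test_simple_mean(self):
        df = pd.DataFrame(
            {
                "neuron_id": [0, 1],
                "punctum_id": [0, 1],
                "time_h": [0.0, 0.0],
                "normalized": [0.4, 0.6],
            }
        )
        assert population_average(df)["mean"].iloc[0] == pytest.approx(0.5)

    def test_two_level_average_matches_brute_force(self):
        rng = np.random.default_rng(11)
        rows = []
        t_grid = np.arange(0.0, 5.0)
        for n in range(20):
            for s in range(rng.integers(3, 8)):
                vals = rng.uniform(0, 1, t_grid.size)
                for t, v in zip(t_grid, vals):
                    rows.append({"neuron_id": n, "punctum_id": (n, s),
                                 "time_h": t, "normalized": v})
        df = pd.DataFrame(rows)
        pop = population_average(df)
        for t in t_grid:
            per_neuron = [
                df[(df.neuron_id == n) & (df.time_h == t)]["normalized"].mean()
                for n in range(20)
            ]
            assert pop[pop.time_h == t]["mean"].iloc[0] == pytest.approx(
                np.mean(per_neuron)
            )
            assert pop[pop.time_h == t]["sd"].iloc[0] == pytest.approx(
                np.std(per_neuron, ddof=1)
            )

    def test_mismatched_grids_rejected(self):
        df = pd.DataFrame(
            {
                "neuron_id": [0, 1],
                "punctum_id": [0, 1],
                "time_h": [0.0, 1.0],
                "normalized": [1.0, 1.0],
            }
        )
        with pytest.raises(ValueError):
            population_average(df)


class TestBiexpFitter:
    def test_single_exponential_limit(self):
        t = np.arange(0.0, 25.0)
        y = np.exp(-t / 3.0)
        fit = fit_biexponential(t, y, 0.0)
        assert fit.tau_major == pytest.approx(3.0, rel=0.06)  # one grid step
        assert fit.f_major >= 0.98

    def test_noiseless_biexp_recovery_and_oracle_ssr(self):
        f, t1, t2 = 0.9, 2.0, 30.0
        t = np.arange(0.0, 25.0)
        y = biexp_model(t, 1.0, f, t1, t2)
        fit = fit_biexponential(t, y, 0.0)
        step = 10 ** (1 / 40.0)
        assert t1 / step**1.5 <= fit.tau_major <= t1 * step**1.5
        assert t2 / step**1.5 <= fit.tau_minor <= t2 * step**1.5
        assert abs(fit.f_major - f) <= 0.015
        # independent continuous least-squares oracle
        popt, _ = curve_fit(
            lambda tt, ff, a, b: biexp_model(tt, 1.0, ff, a, b),
            t, y, p0=(0.8, 3.0, 20.0),
        )
        ssr_oracle = float(np.sum(
            (y - biexp_model(t, 1.0, *popt)) ** 2
        ))
        # grid SSR can exceed the continuous optimum only by the
        # discretization bound: the SSR at the snapped-to-grid truth
        taus = GridSpec().tau_grid()
        snap = lambda x: taus[np.argmin(np.abs(np.log(taus) - np.log(x)))]
        y_snap = biexp_model(t, 1.0, round(f, 2), snap(t1), snap(t2))
        bound = float(np.sum((y - y_snap) ** 2))
        assert fit.ssr <= ssr_oracle + bound + 1e-12

    def test_constant_trace_flagged_non_decaying(self):
        t = np.arange(0.0, 10.0)
        fit = fit_biexponential(t, np.ones_like(t), 0.0)
        assert fit.non_decaying
        assert max(fit.tau_major, fit.tau_minor) == pytest.approx(1000.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential([0.0, 1.0, 2.0], [1.0, 0.5, 0.2], 0.0)

    def test_grid_optimality_spot_check(self):
        # fit SSR must not exceed the SSR of randomly sampled grid points
        rng = np.random.default_rng(4)
        t = np.arange(0.0, 17.0)
        y = biexp_model(t, 1.0, 0.85, 3.7, 40.0) + rng.normal(0, 0.02, t.size)
        fit = fit_biexponential(t, y, 0.0)
        grid = GridSpec()
        taus, fs = grid.tau_grid(), grid.f_grid()
        for _ in range(200):
            i, j = sorted(rng.integers(0, len(taus), 2))
            ff = fs[rng.integers(0, len(fs))]
            ssr = float(np.sum(
                (y - biexp_model(t, 1.0, ff, taus[i], taus[j])) ** 2
            ))
            assert fit.ssr <= ssr + 1e-12

    def test_refinement_monotonicity(self):
        rng = np.random.default_rng(6)
        t = np.arange(0.0, 17.0)
        y = biexp_model(t, 1.0, 0.9, 2.5, 25.0) + rng.normal(0, 0.01, t.size)
        coarse = GridSpec(steps_per_decade=10, f_step=0.05)
        fine = coarse.refine(2)
        ssr_coarse = fit_biexponential(t, y, 0.0, coarse).ssr
        ssr_fine = fit_biexponential(t, y, 0.0, fine).ssr
        assert ssr_fine <= ssr_coarse + 1e-12

    def test_component_relabelling_invariance(self):
        # (tau1, f) <-> (tau2, 1-f) describes the same model; the reported
        # major pool is identical either way
        t = np.arange(0.0, 25.0)
        y1 = biexp_model(t, 1.0, 0.9, 2.0, 30.0)
        y2 = biexp_model(t, 1.0, 0.1, 30.0, 2.0)
        np.testing.assert_allclose(y1, y2)
        f1 = fit_biexponential(t, y1, 0.0)
        f2 = fit_biexponential(t, y2, 0.0)
        assert f1.tau_major == f2.tau_major
        assert f1.f_major == f2.f_major

    def test_missing_points_dropped_pairwise(self):
        t = np.arange(0.0, 17.0)
        y = biexp_model(t, 1.0, 0.9, 3.7, 37.0)
        y_nan = y.copy()
        y_nan[5] = np.nan
        fit = fit_biexponential(t, y_nan, 0.0)
        assert fit.n_points == 16
        assert fit.tau_major == pytest.approx(3.7, rel=0.06)


class TestInitialRate:
    def test_linear_trace_slope(self):
        t = [-1.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        v = [1.1, 1.0, 0.9, 0.8, 0.7, 0.6]
        rate = fit_initial_rate(t, v, 0.0)
        assert rate.slope == pytest.approx(-0.1)
        assert rate.n_points == 5

    def test_exponential_matches_closed_form_ols(self):
        tau = 3.7
        t = np.array([-1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.where(t > 0, np.exp(-t / tau), 1.0)
        rate = fit_initial_rate(t, v, 0.0)
        # closed-form OLS slope over the 5 post-inducer samples
        x, y = t[1:], v[1:]
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
        assert rate.slope == pytest.approx(slope, rel=1e-12)

    def test_four_points_rejected(self):
        with pytest.raises(ValueError):
            fit_initial_rate([-1.0, 1.0, 2.0, 3.0, 4.0],
                             [1.0, 0.9, 0.8, 0.7, 0.6], 0.0)


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert per_synapse_correlation(x, x).r == pytest.approx(1.0)
        assert per_synapse_correlation(x, -x).r == pytest.approx(-1.0)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(8)
        rho, n = 0.6, 500
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        res = per_synapse_correlation(z[:, 0], z[:, 1])
        zf = np.arctanh(rho)
        lo, hi = np.tanh(zf - 1.96 / np.sqrt(n - 3)), np.tanh(
            zf + 1.96 / np.sqrt(n - 3))
        assert lo <= res.r <= hi

    def test_per_neuron_summary(self):
        rng = np.random.default_rng(12)
        xs, ys, gs = [], [], []
        for g in range(10):
            z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 40)
            xs.append(z[:, 0]); ys.append(z[:, 1]); gs.append(np.full(40, g))
        res = per_synapse_correlation(
            np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)
        )
        assert len(res.per_group_r) == 10
        assert res.per_group_mean == pytest.approx(
            np.mean(res.per_group_r)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            per_synapse_correlation(np.ones(5), np.arange(5.0))


class TestLossDelta:
    def test_simple_deltas_and_ratio(self):
        # loss analysis needs >= 3 pairs for the correlation
        table, _ = loss_delta_analysis(
            [100.0, 80.0, 60.0], [0.0, 40.0, 30.0],
            [50.0, 40.0, 30.0], [25.0, 20.0, 25.0],
        )
        assert table["delta_a"].iloc[0] == 100.0
        assert table["delta_b"].iloc[0] == 25.0
        assert table["ratio"].iloc[0] == pytest.approx(0.25)

    def test_unchanged_reporter_zero_ratio(self):
        table, _ = loss_delta_analysis(
            [100.0, 80.0, 60.0], [50.0, 40.0, 30.0],
            [50.0, 40.0, 30.0], [50.0, 40.0, 30.0],
        )
        np.testing.assert_allclose(table["ratio"], 0.0)

    def test_missing_end_point_rejected(self):
        with pytest.raises(ValueError):
            loss_delta_analysis([1.0, 2.0, 3.0], [0.5, np.nan, 1.0],
                                [1.0, 2.0, 3.0], [0.5, 1.0, 1.5])

    def test_synthetic_co_loss_correlation_recovered(self):
        rng = np.random.default_rng(13)
        rho, n = 0.4, 500
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        da = 100 + 20 * z[:, 0]
        db = 40 + 10 * z[:, 1]
        _, corr = loss_delta_analysis(
            200 * np.ones(n), 200 - da, 80 * np.ones(n), 80 - db
        )
        zf = np.arctanh(rho)
        lo, hi = np.tanh(zf - 1.96 / np.sqrt(n - 3)), np.tanh(
            zf + 1.96 / np.sqrt(n - 3))
        assert lo <= corr.r <= hi


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        t, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "welch_t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_hand_computed(self):
        # means 2 and 5, both variances 1, n = 3 each:
        # t = -3 / sqrt(2/3), Welch df = 4
        t, p = group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "welch_t")
        t_hand = -3.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(t_hand, rel=1e-12)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_ranksum_fully_separated_exact_p(self):
        # complete separation of two groups of 5: the exact two-sided
        # rank-sum p is 2 / C(10, 5) = 2/252
        _, p = group_compare([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], "wilcoxon")
        assert p == pytest.approx(2.0 / 252.0, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0], "wilcoxon")
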