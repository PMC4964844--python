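"""Doubling-time estimator: closed forms, oracle equivalence, bias diagnostic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terminvest import growth
from terminvest.errors import (
    DomainError,
    InsufficientDataError,
    LengthMismatchError,
    ZeroGrowthError,
)
from terminvest.growth import (
    GrowthCurve,
    doubling_time,
    estimate_od_noise_sd,
    fit_plate,
    max_slope_window,
    od_bias_experiment,
)


def brute_force_fit(curve, window_points, floor=0.0, z=2.0, k=15.0):
    """Independent re-derivation of the window selection: explicit loops and
    np.polyfit per window (polyfit weights are sqrt of inverse variances)."""
    usable = [i for i in range(len(curve)) if curve.od[i] > max(floor, 0.0)]
    od = curve.od[usable]
    t = curve.times[usable]
    d2 = [od[i + 1] - 2 * od[i] + od[i - 1] for i in range(1, len(od) - 1)]
    sd = 1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0) if len(od) >= 3 else 0.0
    w = (od / sd) ** 2 if sd > 0 else np.ones_like(od)
    candidates = []
    for s in range(len(od) - window_points + 1):
        sl = slice(s, s + window_points)
        coeff = np.polyfit(t[sl], np.log(od[sl]), 1, w=np.sqrt(w[sl]))
        tbar = np.average(t[sl], weights=w[sl])
        stt = float(np.sum(w[sl] * (t[sl] - tbar) ** 2))
        se = 1.0 / math.sqrt(stt) if sd > 0 else 0.0
        mean_od = np.average(od[sl], weights=w[sl])
        candidates.append((s, coeff[0], se, mean_od))
    eligible = [c for c in candidates if c[3] >= k * sd]
    pool = eligible if eligible else candidates
    crit = [c[1] - z * c[2] for c in pool]
    tol = 1e-9 * max(1.0, abs(max(crit)))
    best = next(c for c, cr in zip(pool, crit) if cr >= max(crit) - tol)
    return usable[best[0]], best[1]


class TestDoublingTime:
    @pytest.mark.parametrize(
        "delta_t,n0,n_star,expected",
        [(2.0, 0.1, 0.4, 1.0), (1.0, 1.0, 2.0, 1.0), (3.0, 0.2, 1.6, 1.0)],
    )
    def test_closed_form(self, delta_t, n0, n_star, expected):
        assert doubling_time(delta_t, n0, n_star) == pytest.approx(expected, abs=1e-12)

    def test_zero_growth_is_a_named_error(self):
        with pytest.raises(ZeroGrowthError):
            doubling_time(5.0, 0.2, 0.2)

    @pytest.mark.parametrize("args", [(-1, 0.1, 0.2), (1, 0.0, 0.2), (1, 0.1, -0.3)])
    def test_domain_violations(self, args):
        with pytest.raises(DomainError):
            doubling_time(*args)

    def test_negative_for_shrinking_population(self):
        assert doubling_time(1.0, 0.4, 0.2) < 0


class TestMaxSlopeWindow:
    def test_pure_exponential_recovers_rate_exactly(self):
        t = np.linspace(0.0, 10.0, 100)
        curve = GrowthCurve("w", t, 0.05 * np.exp(0.5 * t))
        fit = max_slope_window(curve, 10)
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert fit.doubling_time == pytest.approx(math.log(2) / 0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.doubling_time == pytest.approx(
            doubling_time(fit.delta_t, fit.n0, fit.n_star), abs=1e-9
        )

    def test_lag_exp_plateau_window_lands_in_exponential_phase(self):
        t = np.linspace(0.0, 10.0, 250)
        od = np.where(
            t < 2, 0.05, np.minimum(0.05 * np.exp(0.7 * (t - 2)), 1.0)
        )
        fit = max_slope_window(GrowthCurve("w", t, od), 25)
        oracle_start, oracle_slope = brute_force_fit(GrowthCurve("w", t, od), 25)
        assert fit.window_start_index == oracle_start
        assert fit.slope == pytest.approx(oracle_slope, rel=1e-9)
        assert fit.slope == pytest.approx(0.7, rel=0.02)
        assert t[fit.window_start_index] >= 2.0
        assert t[fit.window_end_index] <= 2.0 + math.log(1.0 / 0.05) / 0.7 + 1e-9

    def test_constant_curve_has_undefined_doubling_time(self):
        t = np.linspace(0.0, 10.0, 50)
        fit = max_slope_window(GrowthCurve("w", t, np.full(50, 0.3)), 10)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(fit.doubling_time)

    def test_oracle_equivalence_on_random_noisy_curves(self, rng):
        for _ in range(25):
            r = rng.uniform(0.2, 1.0)
            lag = rng.uniform(0.0, 3.0)
            t = np.linspace(0.0, 24.0, 120)
            od = np.where(t < lag, 0.01, np.minimum(0.01 * np.exp(r * (t - lag)), 1.0))
            od = np.maximum(od + rng.normal(0, 0.01, t.size), 1e-4)
            curve = GrowthCurve("w", t, od)
            fit = max_slope_window(curve, 15)
            start, slope = brute_force_fit(curve, 15)
            assert fit.window_start_index == start
            assert fit.slope == pytest.approx(slope, rel=1e-9)

    def test_insufficient_points_raises(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(InsufficientDataError):
            max_slope_window(GrowthCurve("w", t, np.full(10, 0.2)), 11)

    def test_tiny_window_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(DomainError):
            max_slope_window(GrowthCurve("w", t, np.full(10, 0.2)), 2)

    @given(factor=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, factor):
        """Multiplying every OD by a common factor changes nothing: the fit
        lives on log scale and all safeguards are relative to OD."""
        t = np.linspace(0.0, 12.0, 80)
        rng = np.random.default_rng(7)
        od = np.maximum(
            np.minimum(0.01 * np.exp(0.4 * t), 1.0) + rng.normal(0, 0.005, 80), 1e-4
        )
        base = max_slope_window(GrowthCurve("w", t, od), 12)
        scaled = max_slope_window(GrowthCurve("w", t, od * factor), 12)
        assert scaled.window_start_index == base.window_start_index
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)

    def test_noise_sd_estimator_on_known_noise(self, rng):
        od = 0.3 + rng.normal(0, 0.02, 5000)
        assert estimate_od_noise_sd(od) == pytest.approx(0.02, rel=0.1)
        assert estimate_od_noise_sd(np.full(100, 0.3)) == 0.0


class TestFitPlate:
    def test_noiseless_doubling_times_match_truth(self, noiseless_dataset):
        curves, truth = noiseless_dataset
        dt_table, diagnostics = fit_plate(curves)
        diag = pd.DataFrame(diagnostics).merge(truth, on="well")
        expected = np.log(2) / diag["r_per_h"]
        assert np.allclose(diag["doubling_time"], expected, rtol=1e-6)
        assert list(dt_table.columns) == ["Day", "Phages", "dt"]
        assert len(dt_table) == 96

    def test_all_baseline_well_is_flagged_not_dropped(self, noiseless_dataset):
        curves, _ = noiseless_dataset
        curves = curves.copy()
        first_well = curves["well"].iloc[0]
        curves.loc[curves["well"] == first_well, "od650"] = 1e-4
        dt_table, diagnostics = fit_plate(curves)
        assert len(dt_table) == 96
        flagged = [d for d in diagnostics if d["flagged"]]
        assert len(flagged) == 1 and flagged[0]["well"] == first_well
        assert dt_table["dt"].isna().sum() == 1

    def test_missing_columns_rejected(self):
        with pytest.raises(Exception, match="missing columns"):
            fit_plate(pd.DataFrame({"well": ["a"], "od650": [0.1]}))


class TestODBias:
    def test_constant_size_is_bias_free(self):
        t = np.linspace(0, 5, 100)
        counts = 1e6 * np.exp(0.7 * t)
        res = od_bias_experiment(t, counts, np.ones_like(t))
        assert res.dt_observed == pytest.approx(res.dt_true, abs=1e-9)

    def test_perfect_cancellation_hides_growth(self):
        t = np.linspace(0, 5, 100)
        res = od_bias_experiment(t, 1000.0 * 2.0**t, 2.0**-t)
        assert res.dt_true == pytest.approx(1.0, abs=1e-9)
        assert math.isnan(res.dt_observed)

    def test_shrinking_cells_shift_slope_by_log_size_rate(self):
        """10%/h shrinkage subtracts exactly ln(0.9) from the observed
        log-slope, so the observed doubling time exceeds the true one."""
        t = np.linspace(0, 5, 100)
        counts = 1e6 * np.exp(0.7 * t)
        res = od_bias_experiment(t, counts, 0.9**t)
        assert res.fit_observed.slope == pytest.approx(0.7 + math.log(0.9), abs=1e-9)
        assert res.dt_observed >= res.dt_true

    @given(shrink=st.floats(min_value=0.01, max_value=0.5))
    @settings(max_examples=20, deadline=None)
    def test_bias_direction_for_any_shrinkage(self, shrink):
        t = np.linspace(0, 5, 60)
        counts = 1e5 * np.exp(0.8 * t)
        res = od_bias_experiment(t, counts, (1.0 - shrink) ** t)
        assert math.isnan(res.dt_observed) or res.dt_observed >= res.dt_true - 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            od_bias_experiment([0, 1, 2], [1, 2, 3], [1, 1])
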