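import math

import numpy as np
import pytest

import telqpcr as tq
from telqpcr.errors import (AggregationError, InsufficientDataError,
                            InvalidCurveError)
from tests.conftest import exponential_curve


class TestStandardCurve:
    def test_perfect_doubling(self):
        pts = [(10.0 ** k, 12 + 3.321928 * (6 - k)) for k in range(2, 7)]
        fit = tq.fit_standard_curve(pts)
        assert fit.slope_M == pytest.approx(-3.321928, abs=1e-9)
        assert fit.efficiency_E == pytest.approx(2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_efficiency_from_slope(self):
        # cq = 30 - 3.1 * log10(conc): M = -3.1 -> E = 10**(1/3.1)
        pts = [(10.0 ** k, 30 - 3.1 * k) for k in range(2, 7)]
        fit = tq.fit_standard_curve(pts)
        assert fit.efficiency_E == pytest.approx(10 ** (1 / 3.1), abs=1e-9)
        assert fit.efficiency_E == pytest.approx(2.1017480113, abs=1e-6)

    def test_efficiency_slope_identity(self):
        rng = np.random.default_rng(3)
        pts = [(10.0 ** k, 28 - 3.3 * k + rng.normal(0, 0.1)) for k in range(6)]
        fit = tq.fit_standard_curve(pts)
        assert fit.efficiency_E == pytest.approx(10 ** (-1 / fit.slope_M), abs=1e-12)

    def test_positive_slope_is_invalid(self):
        pts = [(10.0 ** k, 10 + k) for k in range(2, 7)]
        with pytest.raises(InvalidCurveError):
            tq.fit_standard_curve(pts)

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            tq.fit_standard_curve([(100.0, 20.0), (100.0, 20.1), (10.0, 23.0)])


class TestBaselineCorrect:
    def test_constant_curve_goes_to_zero(self):
        c = exponential_curve(a=0.0, e=2.0)
        c = c.with_fluorescence(np.full(40, 5.0))
        out = tq.baseline_correct(c, 10)
        np.testing.assert_allclose(out.fluorescence, 0.0, atol=1e-15)
        assert out.baseline_value == pytest.approx(5.0)

    def test_toy_exponential_with_offset(self):
        c = exponential_curve(a=0.0)
        cyc = np.arange(1, 41)
        c = c.with_fluorescence(0.02 + 0.001 * 2.0 ** cyc)
        out = tq.baseline_correct(c, 5)
        # subtracted constant = 0.02 + mean signal over cycles 1-5 = 0.0324
        assert out.baseline_value == pytest.approx(0.0324, abs=1e-12)
        tol = 2 * 0.001 * 2 ** 5
        np.testing.assert_allclose(out.fluorescence[:5], 0.0, atol=tol)
        np.testing.assert_allclose(out.fluorescence[20:],
                                   0.001 * 2.0 ** cyc[20:], atol=tol)

    def test_second_pass_subtracts_almost_nothing(self):
        cyc = np.arange(1, 41)
        c = exponential_curve(a=0.0).with_fluorescence(1e-12 * 2.0 ** cyc)
        once = tq.baseline_correct(c, 5)
        twice = tq.baseline_correct(once, 5)
        assert abs(twice.baseline_value) < 1e-9


def brute_force_window(curves, min_points=4, candidate_grid=50,
                       plateau_fraction=0.9, noise_floor_mult=3.0,
                       min_feasible_fraction=0.8):
    """Independent naive enumeration of the window search (polyfit per band)."""
    floors = [noise_floor_mult * (c.baseline_sd or 0.0) for c in curves]
    plats = [plateau_fraction * c.fluorescence.max() for c in curves]
    gmin, gmax = np.inf, 0.0
    for c, fl, pl in zip(curves, floors, plats):
        f = c.fluorescence
        ok = f[(f > 0) & (f >= fl) & (f <= pl)]
        if ok.size:
            gmin, gmax = min(gmin, ok.min()), max(gmax, ok.max())
    grid = np.geomspace(gmin, gmax, candidate_grid)
    best = None
    for i in range(candidate_grid):
        for j in range(i + 1, candidate_grid):
            lo, hi = grid[i], grid[j]
            r2s, feas = [], 0
            for c, fl, pl in zip(curves, floors, plats):
                f = c.fluorescence
                m = (f > 0) & (f >= lo) & (f <= hi)
                if m.sum() < min_points or lo < fl or hi > pl:
                    continue
                x, y = c.cycles[m], np.log10(f[m])
                if np.ptp(x) == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2s.append(min(r * r, 1.0))
                feas += 1
            if feas < min_feasible_fraction * len(curves):
                continue
            score = (sum(r2s) / len(curves), feas, math.log(hi / lo))
            if best is None or score > best[0]:
                best = (score, lo, hi)
    return best[1], best[2]


class TestWindowOfLinearity:
    def _group(self, amplitudes, e=2.0, noise=0.0, seed=0, plateau=None):
        rng = np.random.default_rng(seed)
        curves = []
        for k, a in enumerate(amplitudes):
            c = exponential_curve(a, e=e, well=f"W{k + 1:03d}", sample_id=f"s{k}")
            f = c.fluorescence
            if plateau is not None:
                f = np.minimum(f, plateau)
            if noise:
                f = f * np.exp(rng.normal(0, noise, len(f)))
            curves.append(c.with_fluorescence(f, baseline_sd=0.0))
        return curves

    def test_pure_exponentials_give_exact_slope(self):
        curves = self._group(np.geomspace(1e-8, 1e-6, 10))
        w = tq.set_window_of_linearity(curves)
        assert w.mean_r_squared == pytest.approx(1.0, abs=1e-12)
        for c in curves:
            est = tq.estimate_reaction_efficiency(c, w)
            if est.valid:
                assert est.slope == pytest.approx(math.log10(2), abs=1e-9)

    def test_plateau_constrains_upper_bound(self):
        curves = self._group(np.geomspace(1e-8, 1e-7, 6), plateau=1.0)
        w = tq.set_window_of_linearity(curves)
        assert w.upper_fluorescence <= 0.9 + 1e-12

    @pytest.mark.parametrize("noise,seed", [(0.0, 0), (0.01, 1), (0.02, 5)])
    def test_matches_brute_force_enumeration(self, noise, seed):
        params = tq.CurveModelParams(noise_sd_rel=noise)
        rng = np.random.default_rng(seed)
        curves = [
            tq.baseline_correct(tq.generate_curve(
                tq.CurveModelParams(true_E=1.8 + 0.02 * k, x0=8e-7 * (1 + k),
                                    noise_sd_rel=noise),
                rng, well=f"W{k + 1:03d}", sample_id=f"s{k}"))
            for k in range(8)
        ]
        w = tq.set_window_of_linearity(curves)
        lo, hi = brute_force_window(curves)
        assert w.lower_fluorescence == pytest.approx(lo, rel=1e-12)
        assert w.upper_fluorescence == pytest.approx(hi, rel=1e-12)


class TestReactionEfficiency:
    def _window(self, lo=0.04, hi=0.35, min_points=4):
        return tq.WindowOfLinearity("G2", lo, hi, min_points)

    def test_exact_doubling(self):
        c = exponential_curve(0.01, e=2.0, n_cycles=20)
        est = tq.estimate_reaction_efficiency(c, self._window())
        assert est.slope == pytest.approx(0.3010300, abs=1e-7)
        assert est.value_E == pytest.approx(2.0, abs=1e-9)

    def test_exact_1p9(self):
        # only cycles 3-5 of 0.01 * 1.9**c fall inside [0.04, 0.35]
        c = exponential_curve(0.01, e=1.9, n_cycles=20)
        est = tq.estimate_reaction_efficiency(c, self._window(min_points=3))
        assert est.value_E == pytest.approx(1.9, abs=1e-9)

    def test_too_few_points_flags_no_amplification(self):
        c = exponential_curve(0.01, e=2.0, n_cycles=20)
        est = tq.estimate_reaction_efficiency(c, self._window(0.04, 0.06))
        assert "no_amplification" in est.flags and not est.valid

    def test_noisy_sigmoid_recovery(self):
        # recovery at 0.5% noise with the window set on the amplicon group, as
        # in the pipeline; the 100-seed sweep lives in the acceptance suite
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            group = [tq.baseline_correct(tq.generate_curve(
                tq.CurveModelParams(true_E=1.85, noise_sd_rel=0.005,
                                    x0=8e-7 * float(rng.uniform(0.5, 2.0))),
                rng, well=f"W{k:03d}", sample_id=f"s{k}")) for k in range(10)]
            w = tq.set_window_of_linearity(group)
            for c in group:
                est = tq.estimate_reaction_efficiency(c, w)
                if est.valid:
                    errs.append(est.value_E - 1.85)
        assert np.max(np.abs(errs)) < 0.05


class TestComputeCq:
    def test_closed_form_crossing(self, pure_exponential):
        cq = tq.compute_cq(pure_exponential, 0.4260)
        assert cq.cq == pytest.approx(math.log2(42.60), abs=1e-9)

    def test_threshold_above_maximum_is_no_cq(self, pure_exponential):
        assert tq.compute_cq(pure_exponential, 1e13) is None

    def test_doubling_template_shifts_cq_by_one(self):
        c1 = exponential_curve(0.01, n_cycles=20)
        c2 = exponential_curve(0.02, n_cycles=20)
        d = tq.compute_cq(c1, 0.4260).cq - tq.compute_cq(c2, 0.4260).cq
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_regression_mode_uses_fitted_line(self):
        c = exponential_curve(0.01, e=2.0, n_cycles=20)
        est = tq.estimate_reaction_efficiency(
            c, tq.WindowOfLinearity("G2", 0.04, 0.35, 4))
        cq = tq.compute_cq(c, 0.4260, fit=est)
        assert cq.cq == pytest.approx(math.log2(42.60), abs=1e-9)


def _replicate(value, sample, plate, role="sample", amplicon="T", rid=None):
    return tq.EfficiencyEstimate(
        value_E=value, level="replicate", method="log_linear",
        source_reactions=[rid or f"{plate}:{sample}"], sample_id=sample,
        plate_id=plate, role=role, amplicon=amplicon)


class TestAggregation:
    def test_constant_values_any_level(self):
        ests = [_replicate(2.0, "s1", "P1") for _ in range(3)]
        for level in ("sample", "plate", "batch"):
            out = tq.aggregate_efficiencies(ests, level)
            assert out[0].value_E == pytest.approx(2.0)

    def test_standards_excluded_from_plate_mean(self):
        ests = [_replicate(1.8, f"s{i}", "P1") for i in range(66)]
        ests += [_replicate(2.2, f"std{i}", "P1", role="standard") for i in range(15)]
        out = tq.aggregate_efficiencies(ests, "plate")
        assert out[0].value_E == pytest.approx(1.8)

    def test_batch_mean_weights_reactions_not_plates(self):
        ests = [_replicate(1.8, f"a{i}", "P1") for i in range(3)]
        ests += [_replicate(2.0, f"b{i}", "P2") for i in range(5)]
        out = tq.aggregate_efficiencies(ests, "batch")
        assert out[0].value_E == pytest.approx((3 * 1.8 + 5 * 2.0) / 8)
        assert out[0].value_E != pytest.approx((1.8 + 2.0) / 2)

    def test_empty_scope_raises(self):
        ests = [_replicate(2.2, "std1", "P1", role="standard")]
        with pytest.raises(AggregationError):
            tq.aggregate_efficiencies(ests, "plate")


class TestCrossMethodInvariants:
    def test_standard_curve_agrees_with_log_linear_on_noiseless_series(self):
        # pure exponentials: no baseline, plateau far above the window
        params = tq.CurveModelParams(true_E=1.9, x0=1e-4, noise_sd_rel=0.0,
                                     baseline_intercept=0.0, f_max=1e12)
        curves = tq.generate_standard_series("T", params, 0)
        w = tq.set_window_of_linearity(curves)
        n_valid = 0
        for c in curves:
            est = tq.estimate_reaction_efficiency(c, w)
            if est.valid:
                assert est.value_E == pytest.approx(1.9, abs=1e-9)
                n_valid += 1
        assert n_valid >= 0.8 * len(curves)
        pts = [(c.known_concentration, tq.compute_cq(c, 0.4260).cq)
               for c in curves]
        fit = tq.fit_standard_curve(pts)
        assert fit.efficiency_E == pytest.approx(1.9, abs=1e-9)

    def test_estimated_e_monotone_in_true_e(self):
        true_es = np.linspace(1.6, 2.1, 8)
        ests = []
        for e in true_es:
            c = exponential_curve(1e-6, e=e, n_cycles=30)
            w = tq.WindowOfLinearity("G2", 1e-4, 0.3, 4)
            ests.append(tq.estimate_reaction_efficiency(c, w).value_E)
        assert np.all(np.diff(ests) > 0)
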