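import math

import numpy as np
import pytest

import telqpcr as tq
from telqpcr.errors import ConfigError, LayoutError


class TestCurveModel:
    def test_reduces_to_pure_exponential(self):
        params = tq.CurveModelParams(true_E=2.0, x0=1e-6, f_max=1e12,
                                     baseline_intercept=0.0, noise_sd_rel=0.0)
        c = tq.generate_curve(params, 0)
        # exact up to the saturating term's u/f_max correction (~1e-6 by c=40)
        np.testing.assert_allclose(
            c.fluorescence[:25], 1e-6 * 2.0 ** c.cycles[:25].astype(float),
            rtol=1e-9)
        w = tq.set_window_of_linearity([c])
        est = tq.estimate_reaction_efficiency(c, w)
        assert est.value_E == pytest.approx(2.0, abs=1e-6)

    def test_doubling_template_shifts_true_cq(self):
        p1 = tq.CurveModelParams(true_E=1.9, noise_sd_rel=0.0)
        p2 = tq.CurveModelParams(true_E=1.9, x0=2 * p1.x0, noise_sd_rel=0.0)
        shift = p1.true_cq(0.426) - p2.true_cq(0.426)
        assert shift == pytest.approx(math.log(2) / math.log(1.9), abs=1e-12)

    def test_true_cq_closed_form_inversion(self):
        # choose x0 so the saturating term crosses 0.426 at cycle 20 exactly
        f_max, thr, e = 10.0, 0.426, 2.0
        u_star = thr * f_max / (f_max - thr)
        x0 = u_star / e ** 20
        params = tq.CurveModelParams(true_E=e, x0=x0, f_max=f_max,
                                     noise_sd_rel=0.0)
        assert params.true_cq(thr) == pytest.approx(20.0, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            tq.CurveModelParams(true_E=2.5)
        with pytest.raises(ConfigError):
            tq.CurveModelParams(noise_sd_rel=-0.1)


class TestStandardSeries:
    def test_noiseless_series_recovers_truth_exactly(self):
        params = tq.CurveModelParams(true_E=1.9, x0=1e-4, noise_sd_rel=0.0,
                                     baseline_intercept=0.0, f_max=1e12)
        curves = tq.generate_standard_series("T", params, 0)
        assert len(curves) == 15
        pts = [(c.known_concentration, tq.compute_cq(c, 0.426).cq)
               for c in curves]
        fit = tq.fit_standard_curve(pts)
        assert fit.efficiency_E == pytest.approx(1.9, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_cq_spacing_matches_dilution_factor(self):
        params = tq.CurveModelParams(true_E=2.0, x0=1e-4, noise_sd_rel=0.0,
                                     baseline_intercept=0.0, f_max=1e12)
        curves = tq.generate_standard_series("T", params, 0, replicates=1)
        cqs = [tq.compute_cq(c, 0.426).cq for c in curves]
        for d in np.diff(cqs):
            assert d == pytest.approx(math.log(10) / math.log(2), abs=1e-9)
            assert d == pytest.approx(3.3219, abs=1e-4)

    def test_one_percent_noise_recovery(self):
        # 10-seed spot check; the 100-seed sweep is in the acceptance suite
        for seed in range(10):
            params = tq.CurveModelParams(true_E=1.9, x0=1e-4, noise_sd_rel=0.01)
            curves = tq.generate_standard_series("T", params, seed)
            cc = [tq.baseline_correct(c, 5) for c in curves]
            pts = [(c.known_concentration, tq.compute_cq(k, 0.426).cq)
                   for c, k in zip(curves, cc)]
            fit = tq.fit_standard_curve(pts)
            assert fit.efficiency_E == pytest.approx(1.9, abs=0.05)


class TestCohort:
    def test_perfect_cross_tissue_correlation_means_identical_tl(self):
        params = tq.CohortParams(n_families=20, cross_tissue_r=1.0,
                                 p_leukocyte_adult=1.0, p_leukocyte_child=1.0)
        cohort = tq.generate_cohort(params, 0)
        wide = cohort.samples.pivot(index="person_id", columns="tissue",
                                    values="true_tl").dropna()
        np.testing.assert_allclose(wide["leukocyte"], wide["buccal"], rtol=1e-12)

    def test_cross_tissue_correlation_calibrated(self):
        params = tq.CohortParams(n_families=7200, p_leukocyte_adult=1.0,
                                 p_leukocyte_child=1.0)
        cohort = tq.generate_cohort(params, 1)
        wide = cohort.samples.pivot(index="person_id", columns="tissue",
                                    values="true_tl")
        ln = np.log(wide.dropna())
        r = np.corrcoef(ln["leukocyte"], ln["buccal"])[0, 1]
        assert r == pytest.approx(0.70, abs=0.02)

    def test_null_parent_offspring_correlation(self):
        params = tq.CohortParams(n_families=1700, parent_offspring_r=0.0)
        cohort = tq.generate_cohort(params, 2)
        buccal = cohort.samples[cohort.samples["tissue"] == "buccal"]
        tl = dict(zip(buccal["person_id"], np.log(buccal["true_tl"])))
        pairs = [(tl[p], tl[c]) for p, c in cohort.parent_offspring_pairs()]
        assert len(pairs) >= 10_000
        a, b = np.array(pairs).T
        assert abs(np.corrcoef(a, b)[0, 1]) <= 0.03

    def test_default_parent_offspring_correlation_calibrated(self):
        params = tq.CohortParams(n_families=1700)
        cohort = tq.generate_cohort(params, 3)
        buccal = cohort.samples[cohort.samples["tissue"] == "buccal"]
        tl = dict(zip(buccal["person_id"], np.log(buccal["true_tl"])))
        pairs = [(tl[p], tl[c]) for p, c in cohort.parent_offspring_pairs()]
        a, b = np.array(pairs).T
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.45, abs=0.03)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ConfigError):
            tq.generate_cohort(tq.CohortParams(parent_offspring_r=0.9,
                                               family_variance=0.5), 0)


class TestBatchLayout:
    def test_44_samples_make_two_plate_pairs(self, mini_study):
        _, run = mini_study
        assert len(run.t_plates) == 2 and len(run.s_plates) == 2
        for plate in run.plates():
            assert len(plate.reactions) == 100

    def test_oversized_layout_rejected(self):
        with pytest.raises(LayoutError):
            tq.PlateLayout(samples_per_plate=30)

    def test_plate_composition(self, mini_study):
        _, run = mini_study
        plate = run.t_plates[0]
        roles = {}
        for rc in plate.reactions:
            roles[rc.role] = roles.get(rc.role, 0) + 1
        assert roles == {"sample": 66, "standard": 15,
                         "positive_control": 18, "ntc": 1}

    def test_noiseless_pipeline_recovers_true_tl_ordering(self):
        """With all noise off and one shared efficiency, T/S equals true TL up
        to one global scale: correlation 1 across samples for every approach."""
        cohort, run = tq.simulate_study(
            22, seed=11,
            curve=tq.CurveModelParams(noise_sd_rel=0.0),
            batch=tq.BatchParams(e_sd_within_plate=0.0, e_sd_between_plates=0.0,
                                 copies_sd=0.0, pipette_sd=0.0, dilution_sd=0.0))
        bundle = tq.analyze_batch(run, tq.PipelineConfig(), cohort)
        truth = dict(zip(cohort.samples["sample_id"], cohort.samples["true_tl"]))
        for name in tq.APPROACHES:
            pairs = np.array([(r.ts[name], truth[r.sample_id])
                              for r in bundle["records"] if name in r.ts])
            assert len(pairs) == 22
            r = np.corrcoef(np.log(pairs[:, 0]), np.log(pairs[:, 1]))[0, 1]
            # residual 1e-4-level departure comes from interpolating the Cq on
            # the (slightly saturating) observed curve
            assert r == pytest.approx(1.0, abs=1e-3)
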