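import numpy as np
import pytest

import telqpcr as tq


@pytest.fixture(scope="session")
def mini_study():
    """A complete miniature study: 44 samples on 2 paired T/S plate pairs."""
    return tq.simulate_study(44, seed=7)


@pytest.fixture(scope="session")
def mini_bundle(mini_study):
    cohort, run = mini_study
    return tq.analyze_batch(run, tq.PipelineConfig(), cohort)


@pytest.fixture()
def pure_exponential():
    """Noiseless curve F = 0.01 * 2**c (no baseline, no plateau in range)."""
    params = tq.CurveModelParams(true_E=2.0, x0=0.01, f_scale=1.0, f_max=1e12,
                                 baseline_intercept=0.0, noise_sd_rel=0.0,
                                 n_cycles=20)
    return tq.generate_curve(params, 0)


def exponential_curve(a, e=2.0, n_cycles=40, **kw):
    """Hand-built pure exponential F = a * e**c as a ReactionCurve."""
    c = np.arange(1, n_cycles + 1)
    return tq.ReactionCurve(
        plate_id=kw.pop("plate_id", "T01"), well=kw.pop("well", "W001"),
        amplicon="T", role="sample", sample_id=kw.pop("sample_id", "s1"),
        replicate_index=1, cycles=c, fluorescence=a * e ** c.astype(float), **kw)
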