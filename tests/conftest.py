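import numpy as np
import pytest

from ppg2bp import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects x 5 clean beats, noise-free, fixed seed."""
    cfg = synthetic.SynthConfig(n_subjects=20, beats_per_subject=5, seed=42)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def cohort_with_abnormal():
    """100 beats with a 20% labeled abnormal fraction."""
    cfg = synthetic.SynthConfig(
        n_subjects=20, beats_per_subject=5, abnormal_rate=0.2, seed=99
    )
    return synthetic.generate(cfg)


def random_code(rng, n_harmonics, period_s=1.0, dc=0.0, amp_scale=1.0):
    from ppg2bp.harmonics import HarmonicCode

    return HarmonicCode(
        period_s=period_s,
        amplitudes=amp_scale * rng.uniform(0.05, 1.0, size=n_harmonics),
        phases=rng.uniform(-np.pi, np.pi, size=n_harmonics),
        dc=dc,
    )
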