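import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cerepulse.synthcohort import SimConfig, iter_subjects

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: overrides that silence every stochastic component of the generator
NOISELESS = dict(
    noise_sd_pct=0.0,
    drift_amplitude_pct=0.0,
    n_artifact_windows=0,
    ekg_noise_sd=0.0,
    ekg_wander_amp=0.0,
)


def noiseless_config(**kw) -> SimConfig:
    base = dict(
        n_subjects=1,
        duration_s=120.0,
        n_channels=6,
        include_out_of_range_channels=False,
        seed=101,
    )
    base.update(NOISELESS)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noiseless_subject():
    """One noiseless subject (6 channels, 120 s): kernel recovery fixture."""
    row, subj = next(iter_subjects(noiseless_config()))
    return row, subj


@pytest.fixture(scope="session")
def default_subject():
    """One subject at the default study conditions (360 s, default noise)."""
    cfg = SimConfig(n_subjects=1, seed=202)
    row, subj = next(iter_subjects(cfg))
    return row, subj


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20259)
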