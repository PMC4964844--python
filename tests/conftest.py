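import numpy as np
import pytest
from hypothesis import settings

from terminvest import synthetic_data as synth

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from terminvest.synthetic_data import ExperimentDesign, GrowthBaseline

UNIT_PROFILE = {d: {t: 1.0 for t in synth.TREATMENTS} for d in range(1, 5)}


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default design, all multipliers 1, no noise or replicate jitter."""
    baseline = GrowthBaseline(noise_sd=0.0, rate_cv=0.0)
    return synth.generate_growth_dataset(
        ExperimentDesign(), effect_profile=UNIT_PROFILE, seed=1, baseline=baseline
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default design at the 2%-of-K noise stress level, default effect profile."""
    baseline = GrowthBaseline(noise_sd=0.02, rate_cv=0.0)
    return synth.generate_growth_dataset(ExperimentDesign(), seed=3, baseline=baseline)


@pytest.fixture
def rng():
    return np.random.default_rng(20230520)
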