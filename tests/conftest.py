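import pytest

from camoil.synthetic_data import ScenarioSpec, gen_timecourse


@pytest.fixture(scope="session")
def noiseless_courses():
    """Noise-free time courses for all three cultivar templates."""
    courses, truth = gen_timecourse(ScenarioSpec(noise_cv=0.0))
    return courses, truth


@pytest.fixture(scope="session")
def noisy_courses():
    """Default-noise (CV 5%) time courses at the default seed."""
    courses, truth = gen_timecourse(ScenarioSpec())
    return courses, truth
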