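import numpy as np
import pytest

from melrad import ExtractionConfig, GeneratorConfig, generate_cohort

#: fast extraction settings: original image only (107 features)
FAST_EXTRACTION = ExtractionConfig(log_sigmas_mm=(), wavelet=None)


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients, default marginals, no images (clinical-side tests)."""
    cfg = GeneratorConfig(n_patients=60, seed=7, render_images=False)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def calibration_cohort():
    """Full-size cohort (n=262) without images, for marginal checks."""
    cfg = GeneratorConfig(n_patients=262, seed=11, render_images=False)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
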