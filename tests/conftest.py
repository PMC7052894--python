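import numpy as np
import pytest

from vcqmsi.pipeline import DEFAULT_DOSED_CONC, calibration_experiment
from vcqmsi.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    """Default study conditions: 8 organs, 5-fold matrix spread, 20 features."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(noise_sigma=0.0, noise_floor=0.0, mz_jitter_ppm=0.0)


@pytest.fixture(scope="session")
def dosed_phantom(phantom_spec):
    """Dosed whole-body phantom at default noise, fixed seed."""
    return generate_phantom(phantom_spec, DEFAULT_DOSED_CONC, seed=101)


@pytest.fixture(scope="session")
def calibration_result(phantom_spec):
    """Full mimetic-model calibration run: screen, train, calibrate, curves."""
    return calibration_experiment(phantom_spec, seed=7)


@pytest.fixture(scope="session")
def pipeline_run_noseg():
    """Full pipeline on the default config, segmentation stage excluded
    (covered separately on the clean tissue mask)."""
    from vcqmsi.pipeline import PipelineConfig, run_vcqmsi
    return run_vcqmsi(PipelineConfig(run_segmentation=False))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
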