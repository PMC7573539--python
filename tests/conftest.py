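import numpy as np
import pytest

from deltareach.leadfield import build_leadfield
from deltareach.pipeline import PipelineConfig, run_pipeline
from deltareach.simulate import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def lf64():
    """Default-sized forward model."""
    return build_leadfield(64, 200, seed=0)


@pytest.fixture(scope="session")
def experiment16():
    """Small synthetic subject with exported signal components."""
    cfg = SimulationConfig(n_trials=16, n_voxels=96)
    return generate_experiment(cfg, seed=7, return_components=True)


@pytest.fixture(scope="session")
def cohort_report():
    """Desk-scale cohort run through the full pipeline (shared across the
    end-to-end tests; ~1 min per subject)."""
    cfg = PipelineConfig.desk()
    cfg.n_subjects = 4
    cfg.sim = SimulationConfig(n_trials=120, n_voxels=96)
    cfg.gfp_reps = 300
    cfg.n_perm = 500
    cfg.decode_windowed = False
    return cfg, run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
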