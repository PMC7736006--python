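import numpy as np
import pytest

from piperbrain.core_model import BrainModelParams, DosingRegimen, PlasmaModelParams
from piperbrain.experiments import reference_design, reference_plasma, reference_truth
from piperbrain.io import default_config
from piperbrain.synthetic import StudyDesign, generate_study


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def truth(cfg):
    """Reference brain-model parameters (the simulation truth)."""
    return reference_truth(cfg)


@pytest.fixture(scope="session")
def plasma(cfg):
    return reference_plasma(cfg)


@pytest.fixture(scope="session")
def plasma_simple():
    """Round-number plasma model for closed-form checks."""
    return PlasmaModelParams(CL=10.0, Q=15.0, Vc=12.0, Vp=10.0, FU=0.7)


@pytest.fixture(scope="session")
def q8h_regimen():
    return DosingRegimen(dose=4000.0, tau=8.0, t_inf=0.5, n_doses=15)


@pytest.fixture(scope="session")
def small_design(q8h_regimen):
    """Compact study design used by most estimation tests."""
    return StudyDesign(n_subjects=6, regimen=q8h_regimen, samples_per_occasion=5, seed=5)


@pytest.fixture(scope="session")
def small_dataset(truth, plasma, small_design):
    return generate_study(truth, plasma, small_design, rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def noise_free_params(truth):
    """Truth with IIV and residual error switched off."""
    return BrainModelParams(
        K_pb=truth.K_pb, K_bp_fd=truth.K_bp_fd, K_bp_md=truth.K_bp_md,
        T_lag_fd=truth.T_lag_fd, T_lag_md=truth.T_lag_md,
        omega_tlag=0.0, sigma_add=0.0, sigma_prop=0.0,
    )
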