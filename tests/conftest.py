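import numpy as np
import pytest

from scpmech import (
    CurveNoiseModel,
    FitConfig,
    OgdenModel,
    PronySeries,
    QLVMaterial,
    default_impact_config,
    fit_cord_qlv,
    generate_cord_curves,
)
from scpmech import materials

# published fit constants, used as generator truth throughout
CORD_MU = 209.0
CORD_ALPHA = 7.52
CORD_G = (0.033, 0.296, 0.406)
CORD_BETAS = (2.0, 13.0, 406.0)
PIA_MU = 42_000.0
PIA_ALPHA = 12.58

# surrogate impact events last a few ms; sample well above 4.5 kHz so that
# phase segmentation has enough samples to work with
SURROGATE_HZ = 45_000.0


@pytest.fixture(scope="session")
def cord_ogden() -> OgdenModel:
    return materials.CORD_OGDEN


@pytest.fixture(scope="session")
def cord_prony() -> PronySeries:
    return materials.CORD_PRONY


@pytest.fixture(scope="session")
def cord_qlv() -> QLVMaterial:
    return materials.CORD_QLV


@pytest.fixture(scope="session")
def pia_ogden() -> OgdenModel:
    return materials.PIA_OGDEN


@pytest.fixture(scope="session")
def impact_config():
    return default_impact_config()


@pytest.fixture(scope="session")
def cord_truth_curves(cord_qlv):
    """Noise-free compression curves at the four experimental rates."""
    return generate_cord_curves(
        cord_qlv, noise=CurveNoiseModel(relative_sd=0.0, seed=0), sample_count=120
    )


def perturbed_cord_config(seed: int, fraction: float = 0.3) -> FitConfig:
    """Fit config with (mu, alpha, G_i) starts perturbed +/-fraction, betas fixed."""
    rng = np.random.default_rng(seed)
    pert = lambda v: float(v * (1.0 + rng.uniform(-fraction, fraction)))
    return FitConfig(
        initial_mu=pert(CORD_MU),
        initial_alpha=pert(CORD_ALPHA),
        initial_g=tuple(pert(g) for g in CORD_G),
        betas=CORD_BETAS,
        fix_betas=True,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cord_recovery_fit(cord_truth_curves):
    """The seed-1 noise-free multi-rate recovery fit (shared across tests)."""
    return fit_cord_qlv(cord_truth_curves, perturbed_cord_config(seed=1))
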