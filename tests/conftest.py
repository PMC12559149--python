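import numpy as np
import pytest

from torsionlab.phantom import LimbSpec, generate_limb


@pytest.fixture(scope="session")
def fine_limb():
    """One clean limb at 0.6 mm in-plane spacing (measurement-grade)."""
    spec = LimbSpec(
        femoral_torsion_deg=15.0,
        tibial_torsion_deg=35.0,
        condylar_angle_deg=3.0,
        tibial_plateau_angle_deg=-2.0,
        seed=11,
    )
    return generate_limb(spec)


@pytest.fixture(scope="session")
def coarse_spec():
    """Phantom geometry at the fast 1.2 mm / 96 px experiment scale."""
    return LimbSpec(stack_shape=(12, 96, 96), spacing_mm=(3.0, 1.2, 1.2), seed=7)


@pytest.fixture(scope="session")
def coarse_limb(coarse_spec):
    return generate_limb(coarse_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
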