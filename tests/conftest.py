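import numpy as np
import pytest

from depfield import (
    ChannelGeometry,
    DriveCondition,
    MediumProperties,
    ParticleProperties,
    VoltagePattern,
)


@pytest.fixture(scope="session")
def chip() -> ChannelGeometry:
    """The validation chip: 150 um wide, 80 um high, 8 electrodes per wall."""
    return ChannelGeometry(width_L=150e-6, height_h=80e-6, n_top=8, n_bottom=8)


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    return MediumProperties(rel_permittivity_em=78.0, wall_rel_permittivity_ew=4.0)


@pytest.fixture(scope="session")
def particle() -> ParticleProperties:
    """8 um diameter bead, as in the validation runs."""
    return ParticleProperties(radius_r=4e-6, rel_permittivity_ep=2.5)


@pytest.fixture(scope="session")
def drive() -> DriveCondition:
    """Negative-DEP drive with the Clausius-Mossotti factor pinned to -0.5."""
    return DriveCondition(cm_real_override=-0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)


@pytest.fixture()
def random_pattern(rng, chip) -> VoltagePattern:
    return VoltagePattern(
        u_top=rng.uniform(-1, 1, chip.n_top),
        u_bottom=rng.uniform(-1, 1, chip.n_bottom),
    )
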