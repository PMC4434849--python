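import numpy as np
import pytest

from helixswitch.sequences import TROP2IC, TROP2ICP, TROP2TM
from helixswitch.synthetic import (
    GeneratorConfig,
    build_ideal_peptide,
    jitter_ensemble,
    simulate_rigid_dimerization,
)


@pytest.fixture(scope="session")
def trop2ic():
    return TROP2IC


@pytest.fixture(scope="session")
def trop2icp():
    return TROP2ICP


@pytest.fixture(scope="session")
def trop2tm():
    return TROP2TM


@pytest.fixture(scope="session")
def helical_ic_model():
    """Cytosolic-tail model with the central 305-314 alpha-helix."""
    return build_ideal_peptide(TROP2IC, ss_plan=[((305, 314), -57.0, -47.0)])


@pytest.fixture(scope="session")
def full_helix_model():
    """Fully alpha-helical cytosolic-tail model (dense NOE geometry)."""
    return build_ideal_peptide(TROP2IC, ss_plan=[((298, 323), -57.0, -47.0)])


@pytest.fixture(scope="session")
def jittered_ensemble(helical_ic_model):
    return jitter_ensemble(helical_ic_model, 20, 0.5, seed=1)


@pytest.fixture(scope="session")
def docked_trajectory():
    """500-frame surrogate with encounter at frame 120, -27 deg dimer."""
    cfg = GeneratorConfig(
        seed=3, n_frames=500, encounter_frame=120, crossing_angle_deg=-27.0
    )
    return simulate_rigid_dimerization(cfg)
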