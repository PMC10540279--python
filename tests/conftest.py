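import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def trigonal_structure():
    """Pd at origin with donors P, C, C in the z=0 plane (near-ideal Y)."""
    from stereonn.geometry import Role, Structure

    coords = np.array([
        [0.0, 0.0, 0.0],      # Pd
        [2.0, 0.0, 0.0],      # P
        [-1.0, 1.7, 0.0],     # C
        [-1.0, -1.7, 0.0],    # C
    ])
    return Structure(["Pd", "P", "C", "C"], coords, ligand_id="L1", role=Role.pro_S)


@pytest.fixture
def donor_set():
    from stereonn.geometry import DonorSet

    return DonorSet(metal_index=0, donor_indices=(1, 2, 3), p_index=1)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.stats import special_ortho_group

    rot = special_ortho_group.rvs(3, random_state=np.random.RandomState(rng.integers(2**31)))
    trans = rng.uniform(-10, 10, size=3)
    return rot, trans
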