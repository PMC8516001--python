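import numpy as np
import pytest

from unfoldmap import Segment, SyntheticSpec, make_unfolding_trajectory


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """A fast planted-event spec: 10 residues, 120 frames, one boundary."""
    return SyntheticSpec(
        n_residues=10,
        n_frames=120,
        segments=(Segment(0, 5, "rigid"), Segment(5, 10, "responsive")),
        amplitude_A=15.0,
        noise_sigma_A=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_spec):
    return make_unfolding_trajectory(tiny_spec)
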