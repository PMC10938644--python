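import numpy as np
import pytest

from dnaelastic import AnalysisWindow, HelicalTrajectory


@pytest.fixture
def simple_traj():
    """12-bp, 2-frame trajectory with uniform rises and twists."""
    nf, ns = 2, 11
    return HelicalTrajectory(
        sequence="GCGCATATGCGC",
        force=0.0,
        temperature=300.0,
        rise=np.full((nf, ns), 0.34),
        twist=np.full((nf, ns), 34.3),
        u=np.full((nf, ns), 0.36),
        anchor_distance=np.array([3.7, 3.71]),
    )


@pytest.fixture
def rich_traj():
    """Randomized valid trajectory exercising every optional field."""
    rng = np.random.default_rng(42)
    nf, nbp = 5, 11
    ns = nbp - 1
    center = np.cumsum(rng.uniform(0.3, 0.4, (nf, nbp, 1)) *
                       np.array([0.0, 0.0, 1.0]), axis=1)
    center += rng.normal(0, 0.02, center.shape)
    triads = np.full((nf, nbp, 3, 3), np.nan)
    for f in range(nf):
        for b in (0, nbp - 1):
            # random small rotation away from identity, exactly orthonormal
            from scipy.spatial.transform import Rotation
            triads[f, b] = Rotation.from_rotvec(
                rng.normal(0, 0.05, 3)).as_matrix()
    rise = rng.uniform(0.30, 0.36, (nf, ns))
    return HelicalTrajectory(
        sequence="GCACATAAGAG",
        force=5.0,
        temperature=300.0,
        rise=rise,
        twist=rng.normal(34.3, 3.0, (nf, ns)),
        slide=rng.normal(0.0, 0.05, (nf, ns)),
        center=center,
        anchor_distance=rng.uniform(3.0, 3.6, nf),
        triads=triads,
        triad_origins=np.where(np.isnan(triads[:, :, 0, :]), np.nan, center),
        tilt=rng.normal(0.0, 4.0, (nf, ns)),
        roll=rng.normal(3.0, 5.0, (nf, ns)),
        save_stride_note="fixture",
    )


@pytest.fixture
def window10():
    return AnalysisWindow(0, 10)
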