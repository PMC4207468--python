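import numpy as np
import pytest

import modediff as md


@pytest.fixture
def toy_topology():
    """3-residue peptide-like fragment with N/CA/C heavy atoms."""
    return md.Topology(
        names=np.array(["N", "CA", "C"] * 3),
        elements=np.array(["N", "C", "C"] * 3),
        resnames=np.array(sum(([r] * 3 for r in ("ALA", "GLY", "SER")), [])),
        resids=np.repeat([1, 2, 3], 3),
        chainids=np.array(["A"] * 9),
    )


@pytest.fixture
def toy_ensemble(toy_topology):
    rng = np.random.default_rng(7)
    base = rng.normal(scale=3.0, size=(9, 3))
    coords = base[None] + rng.normal(scale=0.2, size=(10, 9, 3))
    return md.Ensemble(toy_topology, coords)


@pytest.fixture
def gaussian_ensemble():
    """50-residue, 3-mode planted ensemble plus its ground truth."""
    spec = md.EnsembleSpec(50, [10.0, 6.0, 3.0], seed=1)
    ens, truth = md.generate_gaussian_ensemble(spec, 4000, seed=2)
    return ens, truth


def random_rigid_transform(rng):
    """A uniform random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


def apply_rigid(coords, R, t):
    return coords @ R.T + t
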