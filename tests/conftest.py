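import numpy as np
import pytest

from neiltriage import structio, synthdata


@pytest.fixture(scope="session")
def toy_models():
    """In-memory toy conformers for the three loop states."""
    return {state: synthdata.gen_toy_structure(state) for state in ("apo", "in242", "in244")}


@pytest.fixture(scope="session")
def toy_pdb_dir(tmp_path_factory):
    """The same conformers written as plain-text PDB fixtures."""
    d = tmp_path_factory.mktemp("toy_pdb")
    for state in ("apo", "in242", "in244"):
        synthdata.gen_toy_structure(state, path=d / f"toy_{state}.pdb")
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A uniformly random rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return structio.RigidTransform(R, t)
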