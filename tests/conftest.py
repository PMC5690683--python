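import numpy as np
import pandas as pd
import pytest

from mdnets.alphabet import FragmentLibrary, fragment_from_internal
from mdnets.trajectory_io import CoordinateEnsemble


def make_ensemble(coords, resnums=None, atom_names=None, resnames=None,
                  chains=None, elements=None, spacing=1.0, label="test"):
    """Build a CoordinateEnsemble from raw (F, A, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if resnums is None:
        resnums = list(range(1, n_atoms + 1))
    if atom_names is None:
        atom_names = ["CA"] * n_atoms
    if resnames is None:
        resnames = ["ALA"] * n_atoms
    if chains is None:
        chains = ["A"] * n_atoms
    if elements is None:
        elements = [n[:1] for n in atom_names]
    meta = pd.DataFrame({
        "residue_number": resnums,
        "residue_name": resnames,
        "atom_name": atom_names,
        "chain_id": chains,
        "element": elements,
    })
    return CoordinateEnsemble(coords=coords, atom_meta=meta,
                              frame_spacing_ps=spacing, label=label)


def chain_coords(n_residues, rng=None, jitter=0.0):
    """A non-collinear Cα chain along x with a zigzag in y/z."""
    t = np.arange(n_residues)
    coords = np.stack([3.8 * t, 1.5 * np.sin(t), 1.5 * np.cos(0.7 * t)], axis=1)
    if jitter and rng is not None:
        coords = coords + rng.normal(0, jitter, coords.shape)
    return coords


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_library():
    """Three well-separated fragment prototypes."""
    protos = np.stack([
        fragment_from_internal(88, 88, -30),
        fragment_from_internal(116, 116, 35),
        fragment_from_internal(144, 144, -160),
    ])
    return FragmentLibrary(letters=["a", "b", "c"], prototypes=protos, name="toy3")


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
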