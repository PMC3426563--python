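import numpy as np
import pytest

from foldens.structures import Structure
from foldens.synthetic import ToySpec, make_toy_protein


def bead_structure(coords, residue_names=None, radii=1.7):
    """Minimal one-bead-per-residue Structure from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = residue_names or ["ALA"] * n
    return Structure(
        atom_names=["CA"] * n,
        residue_index=np.arange(1, n + 1),
        residue_name=list(names),
        coords=coords,
        elements=["C"] * n,
        radii=np.full(n, float(radii)) if np.isscalar(radii) else np.asarray(radii),
    )


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(n_residues=60, core_ranges=[(1, 20), (41, 60)],
                   loop_ranges=[(21, 40)], trp_positions=[8, 15, 47, 54], seed=1)


@pytest.fixture(scope="session")
def toy_native(toy_spec):
    return make_toy_protein(toy_spec)


@pytest.fixture(scope="session")
def small_helix():
    return make_toy_protein(ToySpec(n_residues=20, core_ranges=[(1, 20)], seed=2))
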