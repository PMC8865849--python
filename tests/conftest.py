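import numpy as np
import pytest
from hypothesis import settings

from sansemble.nma_refine import build_enm
from sansemble.structures import Structure
from sansemble.synthetic_data import (DEFAULT_Q_GRID, build_toy_pentamer,
                                      sphere_beads)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pentamer():
    """Symmetric toy pentamer (350 beads, C5 about z)."""
    return build_toy_pentamer()


@pytest.fixture(scope="session")
def enm_basis(pentamer):
    return build_enm(pentamer, cutoff=10.0)


@pytest.fixture(scope="session")
def q_grid():
    return DEFAULT_Q_GRID


@pytest.fixture(scope="session")
def quad_sphere():
    """1000-bead quadrature model of a uniform R = 30 Å sphere."""
    return sphere_beads(1000, 30.0)


def single_bead_structure(positions, res_names=None):
    """Minimal coarse structure: one CA bead per residue, single chain."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = np.array(res_names if res_names is not None else ["ALA"] * n)
    return Structure(
        chain_ids=np.array(["A"] * n),
        res_nums=np.arange(1, n + 1),
        res_names=names,
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        positions=positions,
    )
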