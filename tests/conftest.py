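"""Shared fixtures: everything is generated programmatically at test time."""

import numpy as np
import pytest

from atomdenoise.chemgraph import ChemGraph, Conformation, build_chemgraph
from atomdenoise.fixtures import FixtureSpec, make_molecule, make_toy_pocket
from atomdenoise.io_formats import MolRecord


@pytest.fixture(scope="session")
def chain5():
    return make_molecule(FixtureSpec("chain", size=5))


@pytest.fixture(scope="session")
def ring6():
    return make_molecule(FixtureSpec("ring", size=6, elements=["C"]))


@pytest.fixture(scope="session")
def dipeptide():
    return make_molecule(FixtureSpec("dipeptide"))


@pytest.fixture(scope="session")
def chiral_pair():
    return (make_molecule(FixtureSpec("chiral", sign=+1)),
            make_molecule(FixtureSpec("chiral", sign=-1)))


@pytest.fixture(scope="session")
def toy_pocket():
    return make_toy_pocket(FixtureSpec("toy-pocket", seed=1, n_residues=20))


def random_molecule(rng, n_min=6, n_max=14):
    """A random connected molecule: spanning tree plus an occasional extra
    edge, with plausible coordinates. Used as oracle-test input."""
    n = int(rng.integers(n_min, n_max + 1))
    elements = rng.choice(["C", "N", "O", "S"], size=n, p=[0.6, 0.18, 0.18, 0.04])
    bonds = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        bonds.append((j, i, 1))
    if n > 4 and rng.random() < 0.5:  # close one ring
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if (i, j, 1) not in bonds and j - i > 1:
            bonds.append((int(i), int(j), 1))
    coords = rng.normal(0, 2.0, size=(n, 3))
    # push bonded atoms to plausible distances
    for _ in range(60):
        for i, j, _o in bonds:
            d = coords[j] - coords[i]
            r = np.linalg.norm(d)
            if r < 1e-6:
                continue
            corr = 0.3 * (r - 1.5) * d / r
            coords[i] += corr
            coords[j] -= corr
    rec = MolRecord(name="rand", atoms=[(e, 0) for e in elements],
                    bonds=bonds, coords=coords)
    graph, ref = build_chemgraph(ligands=[rec])
    return graph, ref


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
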