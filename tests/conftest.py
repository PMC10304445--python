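import numpy as np
import pytest

from eduqgc import molgraph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def molecules():
    """A small pool of generated molecules reused across tests."""
    return molgraph.generate_molecules(30, seed=99)


@pytest.fixture(scope="session")
def bonded_molecule():
    """A molecule guaranteed to have several bonds."""
    return next(
        g for g in molgraph.generate_molecules(50, seed=7) if len(g.bonds) >= 4
    )


def make_star(n_leaves: int) -> molgraph.MolecularGraph:
    """C center singly bonded to F leaves (valence-consistent for n<=4)."""
    nodes = [molgraph.AtomNode(atomic_number=6, n_hydrogens=4 - n_leaves)]
    nodes += [molgraph.AtomNode(atomic_number=9)] * n_leaves
    bonds = [molgraph.Bond(0, i + 1, "single") for i in range(n_leaves)]
    return molgraph.MolecularGraph(nodes=nodes, bonds=bonds, id="star")
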