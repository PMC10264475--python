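import numpy as np
import pytest

from rehydra import synthetic, trajio


@pytest.fixture(scope="session")
def toy20():
    """20-residue globular toy protein with full per-residue atom set."""
    return synthetic.make_toy_protein(
        synthetic.ToyProteinSpec(n_residues=20, atoms_per_residue=5, seed=1)
    )


@pytest.fixture(scope="session")
def toy5_calpha():
    """5-residue Cα-only toy protein for hand-checkable oracles."""
    return synthetic.make_toy_protein(
        synthetic.ToyProteinSpec(n_residues=5, atoms_per_residue=1, seed=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_two_residue_frame(distance: float):
    """Two single-atom residues a given distance apart."""
    atoms = [
        trajio.Atom(1, "CA", "C", 0, "GLY"),
        trajio.Atom(2, "CA", "C", 1, "GLY"),
    ]
    topo = trajio.Topology(atoms)
    frame = trajio.Frame(np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]))
    return topo, frame
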