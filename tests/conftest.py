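import numpy as np
import pytest

from pairfda import (
    Atom,
    Bond,
    Topology,
    TrajectoryFrame,
    ToySystemSpec,
    build_system,
)


@pytest.fixture
def chain8():
    """Neutral 8-atom linear chain with its collinear equilibrium."""
    return build_system(ToySystemSpec(kind="linear_chain", n_atoms=8))


@pytest.fixture
def charged_dimer():
    return build_system(ToySystemSpec(kind="charged_dimer"))


def random_two_body_system(rng, n_atoms=20, n_bonds=10):
    """Random bonds/LJ/Coulomb-only system for oracle comparisons.

    Atoms sit on a jittered grid so no pair is pathologically close.
    """
    grid = np.stack(
        np.meshgrid(*(np.arange(3) * 0.4,) * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)[:n_atoms]
    coords = grid + rng.normal(0, 0.03, size=(n_atoms, 3))
    atoms = [
        Atom(
            i,
            f"X{i}",
            i // 4,
            f"R{i // 4}",
            float(rng.uniform(-0.5, 0.5)),
            float(rng.uniform(0.2, 0.4)),
            float(rng.uniform(0.0, 1.0)),
        )
        for i in range(n_atoms)
    ]
    pairs = rng.permutation([(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)])
    bonds = [
        Bond(int(i), int(j), float(rng.uniform(0.1, 0.5)), float(rng.uniform(1e3, 1e5)))
        for i, j in pairs[:n_bonds]
    ]
    topo = Topology(atoms=atoms, bonds=bonds)
    topo.exclusions = topo.bonded_exclusions()
    topo.validate()
    return topo, TrajectoryFrame(time=0.0, coordinates=coords)
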