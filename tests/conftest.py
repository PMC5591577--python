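import numpy as np
import pytest

from restfep.forcefield import Atom, Region, TorsionTerm, ToySystem


def random_system(rng: np.random.Generator, n_env: int = 6) -> ToySystem:
    """A small random system: a 4-atom torsional chain (2 ligand atoms,
    2 hot-residue atoms) plus free environment atoms, with random
    charges and LJ parameters.  Used by decomposition/property tests."""
    atoms = []
    chain_pos = np.array(
        [[-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.5, 1.0, 0.5]]
    ) + rng.normal(scale=0.05, size=(4, 3))
    regions = [Region.LIGAND, Region.LIGAND, Region.HOT_RESIDUE, Region.HOT_RESIDUE]
    for i in range(4):
        atoms.append(
            Atom(i, tuple(chain_pos[i]), float(rng.uniform(-0.2, 0.2)),
                 float(rng.uniform(2.5, 3.5)), float(rng.uniform(0.0, 0.3)),
                 regions[i])
        )
    for i in range(4, 4 + n_env):
        # environment shell well away from the chain to avoid overlaps
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = direction * rng.uniform(5.0, 8.0)
        atoms.append(
            Atom(i, tuple(pos), float(rng.uniform(-0.2, 0.2)),
                 float(rng.uniform(2.5, 3.5)), float(rng.uniform(0.0, 0.3)),
                 Region.ENVIRONMENT, mobile=False)
        )
    torsion = TorsionTerm((0, 1, 2, 3), *rng.uniform(-2.0, 2.0, size=3))
    fragments = [[0, 1], [2, 3]] + [[i] for i in range(4, 4 + n_env)]
    exclusions = [(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)]
    pairs14 = [(0, 3)]
    return ToySystem(atoms, fragments, [torsion], exclusions, pairs14)


@pytest.fixture
def rng():
    return np.random.default_rng(2017)
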