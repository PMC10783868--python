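import numpy as np
import pytest

from pocketdiff.chem_core import (
    DEFAULT_VOCAB,
    LigandAtoms,
    ProteinLigandComplex,
    ProteinPocket,
)
from pocketdiff.diffusion import NoiseSchedule
from pocketdiff.fixtures import FixtureSpec, make_dataset
from pocketdiff.network import NetworkConfig, NetworkParams


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCAB


# ---------------------------------------------------------------------------
# Frozen micro-fixtures anchoring the hand-derived scoring examples.
#
# micro2: one ligand atom of the flag-free catch-all class at the origin, one
# pocket atom of the same class at center distance 3.8 Å = R + R, i.e. exactly
# surface distance 0.  Only the two Gaussian terms fire.
#
# micro5: two ligand atoms (C-N) and three pocket atoms with mixed chemistry,
# all coordinates hard-coded.
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def micro2(vocab):
    x_idx = vocab.elements.index("X")
    z_lig = np.zeros((1, vocab.K)); z_lig[0, x_idx] = 1.0
    z_pkt = np.zeros((1, vocab.K)); z_pkt[0, x_idx] = 1.0
    lig = LigandAtoms(np.array([[0.0, 0.0, 0.0]]), z_lig, bonds=[])
    pkt = ProteinPocket(np.array([[3.8, 0.0, 0.0]]), z_pkt)
    return ProteinLigandComplex(pkt, lig, id="micro2")


@pytest.fixture(scope="session")
def micro5(vocab):
    lig = LigandAtoms(
        np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        vocab.one_hot(["C", "N"]),
        bonds=[(0, 1, 1)],
    )
    pkt = ProteinPocket(
        np.array([[4.0, 0.0, 0.0], [0.0, 3.6, 0.0], [-2.0, -2.0, 6.0]]),
        vocab.one_hot(["O", "C", "N"]),
    )
    return ProteinLigandComplex(pkt, lig, id="micro5")


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(6, FixtureSpec(n_pocket_atoms=24, n_ligand_atoms=6), seed=11)


@pytest.fixture(scope="session")
def small_complex(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def sched100():
    return NoiseSchedule.create(T=100)


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(K=8, D=32, L=2, k_neighbors=8, T=100)


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return NetworkParams.init(tiny_config, np.random.default_rng(42))
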