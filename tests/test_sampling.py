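"""Guided reverse process: guidance isolation, positivity, bond rebuilding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketdiff.chem_core import LigandAtoms, ProteinPocket, center_complex
from pocketdiff.diffusion import (
    DiffusionState,
    NoiseSchedule,
    forward_coords,
    forward_types,
    posterior_types,
)
from pocketdiff.network import NetworkConfig, NetworkParams
from pocketdiff.sampling import (
    GuidanceConfig,
    generate,
    guided_coord_step,
    guided_type_step,
    reconstruct_bonds,
    sample_num_atoms,
)


@pytest.fixture(scope="module")
def gen_setup(small_complex, tiny_config):
    theta = NetworkParams.init(tiny_config, np.random.default_rng(7))
    sched = NoiseSchedule.create(T=10)
    c, _ = center_complex(small_complex)
    return theta, sched, c


class TestGuidanceConfig:
    def test_negative_scales_rejected(self):
        with pytest.raises(ValueError):
            GuidanceConfig(s=-1.0)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            GuidanceConfig(delta=0.0)


class TestGuidedCoordStep:
    def test_zero_scale_equals_unguided_under_same_seed(self, gen_setup):
        theta, sched, c = gen_setup
        rng = np.random.default_rng(3)
        x_t = forward_coords(c.ligand.x, 5, sched, rng)
        state = DiffusionState(x_t, c.ligand.z, 5)
        out_off = guided_coord_step(theta, state, c.pocket,
                                    GuidanceConfig(s=0.0, r=0.0),
                                    sched, np.random.default_rng(42))
        out_on_zero_grad = guided_coord_step(
            theta, state, c.pocket, GuidanceConfig(s=0.0, r=10.0),
            sched, np.random.default_rng(42))
        assert np.array_equal(out_off, out_on_zero_grad)

    def test_constant_affinity_head_matches_unguided(self, gen_setup, tiny_config):
        theta, sched, c = gen_setup
        frozen = theta.copy()
        frozen.head_affinity["w2"] = np.zeros_like(frozen.head_affinity["w2"])
        frozen.head_affinity["b2"] = np.zeros_like(frozen.head_affinity["b2"])
        rng = np.random.default_rng(3)
        x_t = forward_coords(c.ligand.x, 5, sched, rng)
        state = DiffusionState(x_t, c.ligand.z, 5)
        guided = guided_coord_step(frozen, state, c.pocket,
                                   GuidanceConfig(s=50.0), sched,
                                   np.random.default_rng(1))
        unguided = guided_coord_step(frozen, state, c.pocket,
                                     GuidanceConfig(s=0.0), sched,
                                     np.random.default_rng(1))
        assert np.allclose(guided, unguided, atol=1e-12)


class TestGuidedTypeStep:
    def test_z_prime_strictly_positive(self, gen_setup):
        theta, sched, c = gen_setup
        rng = np.random.default_rng(5)
        z_t = forward_types(c.ligand.z, 5, sched, rng)
        state = DiffusionState(c.ligand.x, z_t, 5)
        z_prime, z_next = guided_type_step(theta, state, c.pocket,
                                           GuidanceConfig(r=10.0), sched, rng)
        assert z_prime.min() > 0.0
        assert np.array_equal(z_next.sum(axis=1), np.ones(len(z_next)))

    def test_positive_gradient_on_current_class_boosts_posterior(self, sched100):
        # mechanism check on the posterior itself: reweighting the observed
        # class upward can only raise (or keep) its posterior mass
        z_t = np.array([[0.0, 1.0, 0.0, 0.0]])
        z0_hat = np.array([[0.25, 0.25, 0.25, 0.25]])
        delta = 0.01
        base = np.atleast_2d(posterior_types(z_t + delta, z0_hat, 5, sched100))
        boost = (z_t + delta) * np.exp(3.0 * z_t)  # r = 3 gradient on class 1
        guided = np.atleast_2d(posterior_types(boost, z0_hat, 5, sched100))
        assert guided[0, 1] >= base[0, 1]


class TestSampleNumAtoms:
    def test_tiny_pocket_hits_lower_clamp(self, vocab):
        pkt = ProteinPocket(np.zeros((3, 3)), vocab.one_hot(["C"] * 3))
        n = sample_num_atoms(pkt, np.random.default_rng(0))
        assert n == 4

    def test_deterministic_given_seed(self, gen_setup):
        _, _, c = gen_setup
        a = sample_num_atoms(c.pocket, np.random.default_rng(11))
        b = sample_num_atoms(c.pocket, np.random.default_rng(11))
        assert a == b

    def test_mean_tracks_configured_rate(self, vocab):
        pkt = ProteinPocket(np.zeros((200, 3)), vocab.one_hot(["C"] * 200))
        rng = np.random.default_rng(1)
        draws = [sample_num_atoms(pkt, rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 0.08 * 200) / (0.08 * 200) < 0.05


class TestGenerate:
    def test_bit_identical_across_runs_with_same_seed(self, gen_setup):
        theta, sched, c = gen_setup
        g = GuidanceConfig(s=10.0, r=2.0)
        m1, t1 = generate(theta, c.pocket, 2, g, sched, seed=5)
        m2, t2 = generate(theta, c.pocket, 2, g, sched, seed=5)
        assert t1 == t2
        for a, b in zip(m1, m2):
            assert np.array_equal(a.x, b.x)
            assert np.array_equal(a.z, b.z)

    def test_guidance_off_is_identical_to_unguided(self, gen_setup):
        theta, sched, c = gen_setup
        off = GuidanceConfig(s=0.0, r=0.0)
        also_off = GuidanceConfig(s=0.0, r=0.0, delta=0.5)
        m1, _ = generate(theta, c.pocket, 2, off, sched, seed=9)
        m2, _ = generate(theta, c.pocket, 2, also_off, sched, seed=9)
        for a, b in zip(m1, m2):
            assert np.array_equal(a.x, b.x)
            assert np.array_equal(a.z, b.z)

    def test_uncentered_pocket_rejected(self, gen_setup, vocab):
        theta, sched, _ = gen_setup
        pkt = ProteinPocket(np.ones((5, 3)) * 10, vocab.one_hot(["C"] * 5))
        with pytest.raises(ValueError, match="centered"):
            generate(theta, pkt, 1, GuidanceConfig(), sched, seed=0)

    def test_generation_equivariance_under_rotated_noise_stream(self, gen_setup):
        """Rotating pocket and noise stream together rotates the outputs."""
        theta, sched, c = gen_setup

        class RotatedRng:
            # wraps a Generator, rotating every (n, 3) normal draw
            def __init__(self, seed, R):
                self._rng = np.random.default_rng(seed)
                self._R = R

            def standard_normal(self, shape=None):
                draw = self._rng.standard_normal(shape)
                if isinstance(shape, tuple) and len(shape) == 2 and shape[1] == 3:
                    return draw @ self._R.T
                return draw

            def __getattr__(self, name):
                return getattr(self._rng, name)

        R = Rotation.random(random_state=2).as_matrix()
        rot_pocket = ProteinPocket(c.pocket.x @ R.T, c.pocket.z)
        g = GuidanceConfig(s=5.0, r=1.0)
        m1, _ = generate(theta, c.pocket, 1, g, sched,
                         seed=RotatedRng(3, np.eye(3)), n_atoms=5)
        m2, _ = generate(theta, rot_pocket, 1, g, sched,
                         seed=RotatedRng(3, R), n_atoms=5)
        assert np.abs(m1[0].x @ R.T - m2[0].x).max() < 1e-4
        assert np.array_equal(m1[0].z, m2[0].z)

    def test_vhat_trajectory_recorded_per_step(self, gen_setup):
        theta, sched, c = gen_setup
        _, trajs = generate(theta, c.pocket, 1, GuidanceConfig(s=0, r=0,
                                                               delta=0.01),
                            sched, seed=1)
        assert len(trajs[0]) == sched.T
        assert all(0.0 < v < 1.0 for v in trajs[0])


class TestReconstructBonds:
    def test_two_carbons_at_bonding_distance(self, vocab):
        lig = LigandAtoms(np.array([[0.0, 0, 0], [1.5, 0, 0]]),
                          vocab.one_hot(["C", "C"]))
        out = reconstruct_bonds(lig, vocab)
        assert out.bonds == [(0, 1, 1)]

    def test_two_distant_carbons_stay_unbonded(self, vocab):
        lig = LigandAtoms(np.array([[0.0, 0, 0], [3.5, 0, 0]]),
                          vocab.one_hot(["C", "C"]))
        assert reconstruct_bonds(lig, vocab).bonds == []

    def test_valence_cap_prunes_longest_excess_bond(self, vocab):
        # central carbon with five neighbors in range; the farthest loses out
        center = np.zeros((1, 3))
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1]], dtype=float)
        dists = np.array([1.40, 1.45, 1.50, 1.55, 1.60])
        coords = np.vstack([center, dirs * dists[:, None]])
        lig = LigandAtoms(coords, vocab.one_hot(["C"] * 6))
        out = reconstruct_bonds(lig, vocab)
        degree0 = sum(1 for i, j, _ in out.bonds if 0 in (i, j))
        assert degree0 == 4
        assert (0, 5, 1) not in out.bonds  # the 1.60 Å bond is the pruned one
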