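"""Desk-scale benchmark protocol: train, evaluate the expert, test guidance.

This module fixes the study conditions used by the package's own evaluation:

* a corpus of 50 synthetic labeled complexes (the generator's defaults);
* a compact network (2 trunk layers, width 64) on a 100-step chain, trained
  jointly for 200 epochs;
* expert quality measured as the Pearson correlation between predictions and
  oracle labels over 10 equally spaced noise levels;
* guidance efficacy measured on held-out pockets with paired seeds: the same
  random stream drives a guided and an unguided batch, and the per-pocket
  mean oracle scores are compared with a one-sided sign test.

These sizes are the package's compromise between statistical resolution and
a single-CPU runtime of a few minutes; every knob is an argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chem_core import ProteinLigandComplex, ProteinPocket
from .diffusion import NoiseSchedule
from .fixtures import FixtureSpec, make_complex, make_dataset
from .network import NetworkConfig, NetworkParams
from .reporting import high_affinity_fraction
from .sampling import GuidanceConfig, generate, reconstruct_bonds
from .training import TrainConfig, evaluate_expert, train_joint
from .vina import raw_affinity

__all__ = ["DESK_NETWORK", "desk_schedule", "train_desk_model",
           "expert_correlation", "guidance_comparison"]

DESK_NETWORK = NetworkConfig(K=8, D=64, L=2, k_neighbors=12, T=100)


def desk_schedule() -> NoiseSchedule:
    return NoiseSchedule.create(T=DESK_NETWORK.T)


def train_desk_model(seed: int = 0, n_complexes: int = 50, epochs: int = 200):
    """Train the joint model on a fresh synthetic corpus.

    Returns (theta, sched, dataset).
    """
    dataset = make_dataset(n_complexes, FixtureSpec(), seed=seed)
    sched = desk_schedule()
    cfg = TrainConfig(epochs=epochs, seed=seed, val_fraction=0.0)
    theta, _ = train_joint(dataset, cfg, sched, DESK_NETWORK)
    return theta, sched, dataset


def expert_correlation(theta, sched, dataset, seed: int = 1,
                       n_points: int = 10) -> float:
    """Pearson correlation of v̂ against oracle labels across noise levels."""
    rng = np.random.default_rng(seed)
    pcc, _ = evaluate_expert(theta, dataset, n_points, rng, sched)
    return pcc


@dataclass
class GuidanceComparison:
    guided_means: list[float]       # per-pocket mean oracle raw score, guided
    unguided_means: list[float]
    reference_scores: list[float]   # oracle score of each pocket's own ligand
    guided_scores: list[float]      # all individual guided molecule scores
    sign_test_p: float
    wins: int
    n_pockets: int

    @property
    def guided_mean(self) -> float:
        return float(np.mean(self.guided_means))

    @property
    def unguided_mean(self) -> float:
        return float(np.mean(self.unguided_means))

    @property
    def high_affinity(self) -> float:
        per_pocket = []
        i = 0
        n_per = len(self.guided_scores) // self.n_pockets
        for p in range(self.n_pockets):
            chunk = self.guided_scores[i:i + n_per]
            i += n_per
            per_pocket.append(
                high_affinity_fraction(chunk, self.reference_scores[p])
            )
        return float(np.mean(per_pocket))


def _centered(pocket: ProteinPocket) -> ProteinPocket:
    return ProteinPocket(pocket.x - pocket.x.mean(axis=0), pocket.z)


def guidance_comparison(theta, sched, seed: int = 0, n_pockets: int = 32,
                        samples_per_pocket: int = 2,
                        g: GuidanceConfig | None = None) -> GuidanceComparison:
    """Guided vs unguided generation with paired seeds on fresh pockets.

    Each pocket comes from a fixture complex whose own ligand provides the
    reference oracle score.  For every pocket the guided and unguided batches
    share one generation seed, so the comparison is paired; a one-sided sign
    test asks whether guidance lowers (improves) the mean oracle score.
    """
    g = g or GuidanceConfig()
    off = GuidanceConfig(s=0.0, r=0.0, delta=g.delta)
    guided_means, unguided_means, refs, all_guided = [], [], [], []
    base = np.random.default_rng(seed).integers(0, 2**31 - 10**6)
    for p in range(n_pockets):
        ref_complex = make_complex(FixtureSpec(seed=int(base) + p))
        shift = ref_complex.pocket.x.mean(axis=0)
        pocket = _centered(ref_complex.pocket)
        ref_lig = ref_complex.ligand.copy()
        ref_lig.x = ref_lig.x - shift
        refs.append(raw_affinity(ProteinLigandComplex(pocket, ref_lig)))
        pair_seed = int(base) + 500_000 + p

        def batch_scores(cfg_g):
            mols, _ = generate(theta, pocket, samples_per_pocket, cfg_g,
                               sched, seed=pair_seed)
            scores = []
            for m in mols:
                m = reconstruct_bonds(m)
                scores.append(raw_affinity(ProteinLigandComplex(pocket, m)))
            return scores

        g_scores = batch_scores(g)
        u_scores = batch_scores(off)
        guided_means.append(float(np.mean(g_scores)))
        unguided_means.append(float(np.mean(u_scores)))
        all_guided.extend(g_scores)
    diffs = np.array(guided_means) - np.array(unguided_means)
    wins = int((diffs < 0).sum())  # lower raw score = stronger binding
    n_informative = int((diffs != 0).sum())
    p_val = stats.binomtest(wins, max(n_informative, 1),
                            alternative="greater").pvalue
    return GuidanceComparison(
        guided_means=guided_means,
        unguided_means=unguided_means,
        reference_scores=refs,
        guided_scores=all_guided,
        sign_test_p=float(p_val),
        wins=wins,
        n_pockets=n_pockets,
    )
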