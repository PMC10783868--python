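"""Empirical Vina-style binding-affinity oracle.

This is the ground-truth scorer the expert branch distills: a weighted sum of
five pairwise interaction terms over all ligand–protein heavy-atom pairs
within a cutoff, divided by a flexibility penalty on the rotatable-bond count,
then min–max normalized to v ∈ [0, 1] with 1 = strongest binding.

All terms are functions of the *surface distance* d_s = ‖x_i − x_j‖ − R_i − R_j
(interatomic distance minus both van der Waals radii):

    gauss1      = exp(−(d_s / 0.5)²)
    gauss2      = exp(−((d_s − 3) / 2)²)
    repulsion   = d_s²            if d_s < 0, else 0
    hydrophobic = ramp 1→0 over d_s ∈ [0.5, 1.5]   (both atoms hydrophobic)
    hbond       = ramp 1→0 over d_s ∈ [−0.7, 0]    (donor paired with acceptor)

Scoring only — there is no pose optimization here; the oracle exists to label
complexes, not to replace a docking engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .chem_core import (
    AtomTypeVocabulary,
    DEFAULT_VOCAB,
    LigandAtoms,
    ProteinLigandComplex,
)

__all__ = [
    "VinaTermWeights",
    "AffinityNormalizer",
    "DEFAULT_WEIGHTS",
    "DEFAULT_NORMALIZER",
    "surface_distance",
    "pair_terms",
    "count_rotatable_bonds",
    "raw_affinity",
    "normalize_affinity",
    "score_complex",
]


@dataclass(frozen=True)
class VinaTermWeights:
    """Term weights (kcal/mol scale) and interaction cutoff.

    Defaults are the published AutoDock Vina fit; the 8 Å cutoff is the usual
    non-covalent interaction cutoff.
    """

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_rot: float = 0.05846
    cutoff: float = 8.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.w_repulsion < 0:
            raise ValueError("repulsion weight must be non-negative")


@dataclass(frozen=True)
class AffinityNormalizer:
    """Affine min–max map from raw kcal/mol to v ∈ [0, 1], clipped.

    lo is the most favorable raw score (maps to 1), hi the least (maps to 0);
    the map is strictly decreasing on [lo, hi] so larger v = stronger binding.
    """

    lo: float = -12.0
    hi: float = 0.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")


DEFAULT_WEIGHTS = VinaTermWeights()
DEFAULT_NORMALIZER = AffinityNormalizer()


def surface_distance(xi, xj, Ri: float, Rj: float) -> float:
    """Interatomic distance minus both vdW radii (may be negative)."""
    if Ri <= 0 or Rj <= 0:
        raise ValueError("radii must be positive")
    return float(np.linalg.norm(np.asarray(xi) - np.asarray(xj))) - Ri - Rj


def _term_matrix(ds: np.ndarray, hyd_pair: np.ndarray, hb_pair: np.ndarray) -> np.ndarray:
    """Evaluate the five terms on an array of surface distances.

    Returns an array of shape ds.shape + (5,) ordered
    (gauss1, gauss2, repulsion, hydrophobic, hbond).
    """
    ds = np.asarray(ds, dtype=np.float64)
    gauss1 = np.exp(-((ds / 0.5) ** 2))
    gauss2 = np.exp(-(((ds - 3.0) / 2.0) ** 2))
    repulsion = np.where(ds < 0, ds**2, 0.0)
    hydrophobic = np.clip((1.5 - ds) / 1.0, 0.0, 1.0) * hyd_pair
    hbond = np.clip(ds / -0.7, 0.0, 1.0) * hb_pair
    return np.stack([gauss1, gauss2, repulsion, hydrophobic, hbond], axis=-1)


def pair_terms(ds: float, type_i: str, type_j: str,
               vocab: AtomTypeVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """The 5-vector of Vina terms for one atom pair at surface distance ds."""
    hyd = float(type_i in vocab.hydrophobic and type_j in vocab.hydrophobic)
    hb = float(
        (type_i in vocab.hbond_donor and type_j in vocab.hbond_acceptor)
        or (type_j in vocab.hbond_donor and type_i in vocab.hbond_acceptor)
    )
    return _term_matrix(np.float64(ds), hyd, hb)


def count_rotatable_bonds(lig: LigandAtoms) -> int:
    """Count single acyclic bonds whose endpoints are both non-terminal.

    This is the heavy-atom torsion count Vina penalizes flexibility with.
    """
    if lig.bonds is None:
        raise ValueError(
            "ligand has no bonds; run bond reconstruction before scoring"
        )
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(lig.n_atoms))
    g.add_edges_from([(i, j) for i, j, _ in lig.bonds])
    cycle_edges = set()
    for cyc in nx.cycle_basis(g):
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            cycle_edges.add(frozenset((a, b)))
    n_rot = 0
    for i, j, order in lig.bonds:
        if order != 1 or frozenset((i, j)) in cycle_edges:
            continue
        if g.degree[i] >= 2 and g.degree[j] >= 2:
            n_rot += 1
    return n_rot


def _pair_sum(c: ProteinLigandComplex, w: VinaTermWeights,
              vocab: AtomTypeVocabulary, per_atom: bool = False):
    """Weighted pairwise-term sum within cutoff (no rotor penalty)."""
    lig, pkt = c.ligand, c.pocket
    d = cdist(lig.x, pkt.x)
    ds = d - vocab.radii_for(lig.z)[:, None] - vocab.radii_for(pkt.z)[None, :]
    hyd = (vocab.flags_for(lig.z, "hydrophobic")[:, None]
           & vocab.flags_for(pkt.z, "hydrophobic")[None, :])
    don_l = vocab.flags_for(lig.z, "hbond_donor")[:, None]
    acc_l = vocab.flags_for(lig.z, "hbond_acceptor")[:, None]
    don_p = vocab.flags_for(pkt.z, "hbond_donor")[None, :]
    acc_p = vocab.flags_for(pkt.z, "hbond_acceptor")[None, :]
    hb = (don_l & acc_p) | (don_p & acc_l)
    terms = _term_matrix(ds, hyd.astype(float), hb.astype(float))
    weights = np.array([w.w_gauss1, w.w_gauss2, w.w_repulsion,
                        w.w_hydrophobic, w.w_hbond])
    pair_scores = terms @ weights
    pair_scores[d > w.cutoff] = 0.0  # pairs beyond cutoff contribute exactly 0
    atom_scores = pair_scores.sum(axis=1)
    return atom_scores if per_atom else float(atom_scores.sum())


def raw_affinity(c: ProteinLigandComplex, w: VinaTermWeights = DEFAULT_WEIGHTS,
                 vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
                 n_rot: int | None = None) -> float:
    """Raw empirical affinity in kcal/mol-scale units (lower = stronger).

    `n_rot` overrides the rotatable-bond count; otherwise it is computed from
    the ligand's bonds, or taken as 0 when the ligand carries no bond list
    (noisy intermediate states have no meaningful topology).
    """
    if n_rot is None:
        n_rot = count_rotatable_bonds(c.ligand) if c.ligand.bonds is not None else 0
    inter = _pair_sum(c, w, vocab)
    return inter / (1.0 + w.w_rot * n_rot)


def per_atom_affinity(c: ProteinLigandComplex, w: VinaTermWeights = DEFAULT_WEIGHTS,
                      vocab: AtomTypeVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """Per-ligand-atom decomposition of the pairwise sum (no rotor penalty)."""
    return _pair_sum(c, w, vocab, per_atom=True)


def normalize_affinity(raw: float, n: AffinityNormalizer = DEFAULT_NORMALIZER) -> float:
    """Map raw score to v ∈ [0, 1]; strictly decreasing on [lo, hi], clipped."""
    return float(np.clip((n.hi - raw) / (n.hi - n.lo), 0.0, 1.0))


def score_complex(c: ProteinLigandComplex,
                  w: VinaTermWeights = DEFAULT_WEIGHTS,
                  n: AffinityNormalizer = DEFAULT_NORMALIZER,
                  vocab: AtomTypeVocabulary = DEFAULT_VOCAB) -> tuple[float, float]:
    """Convenience: (raw, normalized) affinity of a complex."""
    raw = raw_affinity(c, w, vocab)
    return raw, normalize_affinity(raw, n)
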