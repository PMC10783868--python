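"""Deterministic synthetic pocket–ligand fixtures with oracle labels.

Every test and desk-scale experiment runs on complexes produced here: a rigid
shell of typed "protein" atoms forming a concave cavity (a spherical cap of
configurable solid-angle coverage), a small ligand grown by a short random
walk inside the cavity, and a ground-truth normalized affinity computed by the
built-in Vina-style oracle.  These fixtures emulate the geometry the model
cares about — a concave typed environment enclosing a ligand at non-covalent
range — not protein chemistry: there are no residues, no secondary structure
and no protonation states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chem_core import (
    AtomTypeVocabulary,
    DEFAULT_VOCAB,
    LigandAtoms,
    OTHER,
    ProteinLigandComplex,
    ProteinPocket,
)
from .vina import (
    AffinityNormalizer,
    DEFAULT_NORMALIZER,
    DEFAULT_WEIGHTS,
    VinaTermWeights,
    normalize_affinity,
    raw_affinity,
)

__all__ = ["FixtureSpec", "make_pocket", "make_ligand", "make_dataset",
           "FIXTURE_NORMALIZER"]

# Min-max bounds matched to the raw-score range the generator actually
# produces (toy complexes of 4-11 atoms score about -2..0 kcal/mol, an order
# of magnitude weaker than real protein-ligand pairs).  The general-purpose
# bounds sized for experimental score ranges would compress every label into
# a few percent of [0, 1] and leave the affinity branch nothing to distill;
# clashed decoy poses (raw > 0) clip to 0.
FIXTURE_NORMALIZER = AffinityNormalizer(lo=-2.5, hi=0.0)

# element sampling frequencies for generated atoms; the catch-all class is
# excluded so every atom carries meaningful oracle chemistry
_DEFAULT_FREQS = {"C": 0.62, "N": 0.16, "O": 0.16, "S": 0.03, "F": 0.02, "Cl": 0.01}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_pocket_atoms: int = 48
    cavity_radius: float = 8.0      # Å, shell radius around the cavity center
    shell_thickness: float = 1.5    # Å, radial jitter of shell atoms
    concavity: float = 0.75         # solid-angle fraction covered (1 = closed)
    n_ligand_atoms: int = 8
    element_freqs: tuple[tuple[str, float], ...] = tuple(_DEFAULT_FREQS.items())

    def __post_init__(self):
        if self.n_pocket_atoms < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if not 0.0 <= self.concavity <= 1.0:
            raise ValueError("concavity must lie in [0, 1]")
        # the walk must stay clear of the shell; clearance ~ vdW contact range
        if self.cavity_radius <= 3.2 + 1.5:
            raise ValueError("cavity_radius too small for a ligand to fit")


def _sample_elements(rng, freqs, n, vocab):
    names = [e for e, _ in freqs]
    p = np.array([w for _, w in freqs])
    chosen = rng.choice(len(names), size=n, p=p / p.sum())
    return vocab.one_hot([names[i] for i in chosen])


def make_pocket(spec: FixtureSpec,
                vocab: AtomTypeVocabulary = DEFAULT_VOCAB) -> ProteinPocket:
    """Sample pocket atoms on a spherical cap shell around the origin.

    The cap covers a fraction `concavity` of the full solid angle, opening
    upward: concavity 1 is a closed shell, 0.5 a hemisphere (no atom below the
    equator), small values a nearly flat wall.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pocket_atoms
    # cos(theta) uniform on [1 - 2*concavity, 1] covers the requested fraction,
    # measured from the downward axis so the opening faces up (+z)
    cos_lo = 1.0 - 2.0 * spec.concavity
    cos_t = rng.uniform(cos_lo, 1.0, size=n)
    theta = np.arccos(cos_t)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = spec.cavity_radius + rng.uniform(
        -spec.shell_thickness / 2, spec.shell_thickness / 2, size=n
    )
    x = np.stack(
        [r * np.sin(theta) * np.cos(phi),
         r * np.sin(theta) * np.sin(phi),
         -r * np.cos(theta)],  # cap grows from the bottom pole
        axis=1,
    )
    return ProteinPocket(x, _sample_elements(rng, spec.element_freqs, n, vocab))


def make_ligand(spec: FixtureSpec, pocket: ProteinPocket,
                vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
                clearance: float = 3.2, step: float = 1.5,
                max_rejects: int = 1000) -> LigandAtoms:
    """Grow a ligand by a short random walk from the cavity center.

    Each step adds an atom 1.5 Å from the previous one, rejection-sampled to
    stay at least `clearance` Å from every pocket atom; walk edges become
    single bonds.  The default clearance (3.2 Å) keeps ligand atoms near van
    der Waals contact with the shell — the regime where the scoring oracle's
    attractive terms dominate — instead of deep steric clash.
    """
    rng = np.random.default_rng(spec.seed + 1)
    coords = [np.zeros(3)]
    bonds = []
    rejects = 0
    while len(coords) < spec.n_ligand_atoms:
        direction = rng.standard_normal(3)
        cand = coords[-1] + step * direction / np.linalg.norm(direction)
        if cdist(cand[None, :], pocket.x).min() >= clearance:
            bonds.append((len(coords) - 1, len(coords), 1))
            coords.append(cand)
        else:
            rejects += 1
            if rejects > max_rejects:
                raise RuntimeError(
                    "ligand placement failed; increase cavity_radius"
                )
    z = _sample_elements(rng, spec.element_freqs, spec.n_ligand_atoms, vocab)
    return LigandAtoms(np.array(coords), z, bonds)


def _slide_to_contact(lig: LigandAtoms, pocket: ProteinPocket,
                      target: float, rng: np.random.Generator) -> LigandAtoms:
    """Translate a ligand along a random radial direction until its closest
    pocket contact reaches `target` Å — the decoy-pose generator."""
    direction = pocket.x[rng.integers(len(pocket.x))].copy()
    direction /= np.linalg.norm(direction)
    step = 0.1
    out = lig.copy()
    for _ in range(200):
        if cdist(out.x, pocket.x).min() <= target:
            break
        out.x = out.x + step * direction
    return out


def make_complex(spec: FixtureSpec, vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
                 weights: VinaTermWeights = DEFAULT_WEIGHTS,
                 normalizer: AffinityNormalizer = FIXTURE_NORMALIZER,
                 cid: str | None = None,
                 decoy_contact: float | None = None) -> ProteinLigandComplex:
    """Build one labeled complex; `decoy_contact` (Å) slides the ligand into
    the shell until that closest-contact distance, producing a poor pose."""
    pocket = make_pocket(spec, vocab)
    ligand = make_ligand(spec, pocket, vocab)
    if decoy_contact is not None:
        ligand = _slide_to_contact(ligand, pocket, decoy_contact,
                                   np.random.default_rng(spec.seed + 2))
    c = ProteinLigandComplex(pocket, ligand, id=cid or f"fix-{spec.seed}")
    c.v = normalize_affinity(raw_affinity(c, weights, vocab), normalizer)
    return c


def make_dataset(n_complexes: int, template: FixtureSpec, seed: int = 0,
                 vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
                 weights: VinaTermWeights = DEFAULT_WEIGHTS,
                 normalizer: AffinityNormalizer = FIXTURE_NORMALIZER,
                 decoy_fraction: float = 0.0,
                 ) -> list[ProteinLigandComplex]:
    """Generate `n_complexes` labeled complexes with varied geometry.

    Pocket size, cavity radius, concavity and ligand size are jittered around
    the template so the oracle labels carry real variance for the expert to
    learn; labels are v = normalized raw affinity, always in [0, 1].

    An optional `decoy_fraction` of the complexes slide their ligand into
    the shell until the closest pocket contact is 1.8-3.0 Å, running from
    marginal contact into steric clash — poor poses like those found in
    docked corpora, labeled (near) zero.  Off by default: the standard
    corpus contains only physically comfortable poses.
    """
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    rng = np.random.default_rng(seed)
    # decoy decisions use their own substream so enabling them perturbs
    # neither pocket nor ligand geometry of the non-decoy complexes
    decoy_rng = np.random.default_rng(seed + 999_331)
    out = []
    for i in range(n_complexes):
        sub = int(rng.integers(0, 2**31 - 1))
        spec = FixtureSpec(
            seed=sub,
            n_pocket_atoms=int(rng.integers(
                max(8, template.n_pocket_atoms // 2),
                template.n_pocket_atoms * 3 // 2 + 1)),
            cavity_radius=float(template.cavity_radius
                                * rng.uniform(0.85, 1.35)),
            shell_thickness=template.shell_thickness,
            concavity=float(np.clip(
                template.concavity + rng.uniform(-0.25, 0.25), 0.3, 1.0)),
            n_ligand_atoms=int(rng.integers(
                max(4, template.n_ligand_atoms - 3),
                template.n_ligand_atoms + 4)),
            element_freqs=template.element_freqs,
        )
        if decoy_rng.random() < decoy_fraction:
            contact = float(decoy_rng.uniform(1.8, 3.0))
        else:
            contact = None
        out.append(make_complex(spec, vocab, weights, normalizer,
                                cid=f"fix-{seed}-{i}", decoy_contact=contact))
    return out
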