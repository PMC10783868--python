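"""Knowledge-guided reverse diffusion: generation steered by the expert head.

At every reverse step the affinity classifier v̂ supplies two gradients:

* coordinates are sampled from the posterior Gaussian with its mean shifted by
  s · β̃_t · ∇_{x_t} log v̂ (classifier guidance on a continuous variable);
* atom types are reweighted multiplicatively before the categorical posterior
  is sampled: z′_t = (z_t + δ) ⊙ exp(r · ∇_{z_t} v̂), which keeps every entry
  strictly positive so zero entries of a one-hot row can still move.

With both scales at zero the sampler is bit-identical to the unguided reverse
process under the same seed: guidance never touches the random stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .chem_core import AtomTypeVocabulary, DEFAULT_VOCAB, LigandAtoms, ProteinPocket
from .diffusion import DiffusionState, NoiseSchedule, posterior_coords, posterior_types
from .network import NetworkParams, forward, _wrap_params

__all__ = [
    "GuidanceConfig",
    "guided_coord_step",
    "guided_type_step",
    "sample_num_atoms",
    "generate",
    "reconstruct_bonds",
]

logger = logging.getLogger(__name__)

_COVALENT_RADIUS = {"C": 0.77, "N": 0.75, "O": 0.73, "F": 0.71,
                    "P": 1.10, "S": 1.03, "Cl": 0.99, "X": 0.77}
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "X": 4}
_EXP_CLIP = 50.0  # cap on |r·grad| inside the exponent to avoid overflow


@dataclass(frozen=True)
class GuidanceConfig:
    """Guidance scales.

    By default the coordinate gradient is scaled to unit RMS before the mean
    shift, so each step displaces atoms by s·β̃ Å along the expert's uphill
    direction regardless of the expert's raw gradient magnitude — which
    varies several-fold between training runs.  The defaults were calibrated
    on development pocket sets: predicted affinity rises monotonically with
    s, but the true oracle score of the generated molecules peaks at a
    moderate total displacement and collapses once the shift drives atoms
    into steric clash — the usual classifier-guidance strength trade-off."""

    s: float = 0.3      # coordinate gradient scale
    r: float = 10.0     # type gradient scale
    delta: float = 0.01 # positive offset added to type rows before reweighting
    normalize_grad: bool = True  # scale the coordinate gradient to unit RMS

    def __post_init__(self):
        if self.s < 0 or self.r < 0:
            raise ValueError("gradient scales must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be strictly positive")


def _predict_and_grad(theta: NetworkParams, state: DiffusionState,
                      pocket: ProteinPocket, need_grad: bool):
    """One forward pass (plus one backward when guiding)."""
    p = _wrap_params(theta)
    x_t = Tensor(state.x, requires_grad=need_grad)
    z_t = Tensor(state.z, requires_grad=need_grad)
    x0_hat, z0_hat, _, v_hat = forward(p, x_t, z_t, pocket, state.t, theta.config)
    dx = dz = None
    if need_grad:
        v_hat.backward()
        v = float(v_hat.data)
        dx = x_t.grad / v  # ∇ log v̂
        dz = z_t.grad / v if theta.config.log_type_grad else z_t.grad
    return x0_hat.data.copy(), z0_hat.data.copy(), float(v_hat.data), dx, dz


def guided_coord_step(theta: NetworkParams, state: DiffusionState,
                      pocket: ProteinPocket, g: GuidanceConfig,
                      sched: NoiseSchedule, rng: np.random.Generator) -> np.ndarray:
    """Sample x_{t−1} from the guidance-shifted posterior Gaussian."""
    x0_hat, _, _, dx, _ = _predict_and_grad(theta, state, pocket, g.s > 0)
    mu, beta_tilde = posterior_coords(state.x, x0_hat, state.t, sched)
    if g.s > 0:
        if not np.isfinite(dx).all():
            logger.warning("non-finite coordinate gradient at t=%d; "
                           "falling back to unguided step", state.t)
        else:
            mu = mu + _coord_shift(dx, g, beta_tilde)
    return mu + np.sqrt(beta_tilde) * rng.standard_normal(mu.shape)


def guided_type_step(theta: NetworkParams, state: DiffusionState,
                     pocket: ProteinPocket, g: GuidanceConfig,
                     sched: NoiseSchedule, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Reweight z_t by the affinity gradient, then sample z_{t−1}.

    Returns (z′_t, z_{t−1}); z′_t is strictly positive by construction and
    z_{t−1} is one-hot.
    """
    _, z0_hat, _, _, dz = _predict_and_grad(theta, state, pocket, g.r > 0)
    if g.r > 0 and np.isfinite(dz).all():
        expo = np.clip(g.r * dz, -_EXP_CLIP, _EXP_CLIP)
        if (np.abs(g.r * dz) > _EXP_CLIP).any():
            logger.warning("clipped type-guidance exponent at t=%d", state.t)
        z_prime = (state.z + g.delta) * np.exp(expo)
    else:
        z_prime = state.z + g.delta
    post = np.atleast_2d(posterior_types(z_prime, z0_hat, state.t, sched))
    z_next = _sample_categorical_rows(post, rng)
    return z_prime, z_next


def _coord_shift(dx: np.ndarray, g: GuidanceConfig, beta_tilde: float) -> np.ndarray:
    """The guidance mean shift s·β̃·∇ (optionally with the gradient scaled to
    unit RMS so the per-step displacement is s·β̃ Å regardless of the
    expert's gradient magnitude)."""
    if g.normalize_grad:
        rms = np.sqrt(np.mean(dx**2))
        if rms > 0:
            dx = dx / rms
    return g.s * beta_tilde * dx


def _sample_categorical_rows(post: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One-hot sample per row via inverse CDF; one uniform draw per row."""
    u = rng.random(post.shape[0])
    cdf = np.cumsum(post, axis=1)
    cdf[:, -1] = 1.0
    idx = (u[:, None] > cdf).sum(axis=1)
    out = np.zeros_like(post)
    out[np.arange(len(post)), idx] = 1.0
    return out


def sample_num_atoms(pocket: ProteinPocket, rng: np.random.Generator,
                     atoms_per_pocket_atom: float = 0.08,
                     lo: int = 4, hi: int = 60) -> int:
    """Ligand size prior: shifted Poisson with mean ∝ pocket atom count."""
    if pocket.n_atoms == 0:
        raise ValueError("empty pocket")
    mean = atoms_per_pocket_atom * pocket.n_atoms
    n = lo + rng.poisson(max(0.0, mean - lo))
    return int(np.clip(n, lo, hi))


def generate(theta: NetworkParams, pocket: ProteinPocket, n_samples: int,
             g: GuidanceConfig, sched: NoiseSchedule,
             seed: int | np.random.Generator,
             n_atoms: int | None = None,
             ) -> tuple[list[LigandAtoms], list[list[float]]]:
    """Generate ligands for a centered pocket by guided reverse diffusion.

    Each sample starts as a Gaussian cloud at the pocket center with uniform
    random types and is denoised for T steps, applying the type guidance then
    the coordinate guidance at every step from a single network evaluation.
    Returns the molecules (bond-free; see :func:`reconstruct_bonds`) and the
    per-step v̂ trajectory of each.  A sample whose step fails is dropped and
    logged, never silently imputed.
    """
    if np.linalg.norm(pocket.x.mean(axis=0)) > 1e-6:
        raise ValueError("pocket must be centered before generation")
    K = theta.config.K
    # a Generator (or duck-typed stream wrapper) may be passed directly
    rng = seed if hasattr(seed, "standard_normal") else np.random.default_rng(seed)
    mols: list[LigandAtoms] = []
    trajs: list[list[float]] = []
    for _ in range(n_samples):
        n = n_atoms if n_atoms is not None else sample_num_atoms(pocket, rng)
        x = rng.standard_normal((n, 3))
        z = np.zeros((n, K))
        z[np.arange(n), rng.integers(0, K, n)] = 1.0
        traj: list[float] = []
        z0_hat = None
        try:
            for t in range(sched.T, 0, -1):
                state = DiffusionState(x, z, t)
                need_grad = g.s > 0 or g.r > 0
                x0_hat, z0_hat, v_hat, dx, dz = _predict_and_grad(
                    theta, state, pocket, need_grad
                )
                traj.append(v_hat)
                # --- type step (guidance reweights before the posterior) ---
                if g.r > 0 and np.isfinite(dz).all():
                    expo = np.clip(g.r * dz, -_EXP_CLIP, _EXP_CLIP)
                    z_in = (z + g.delta) * np.exp(expo)
                else:
                    z_in = z
                post = np.atleast_2d(posterior_types(z_in, z0_hat, t, sched))
                z = _sample_categorical_rows(post, rng)
                # --- coordinate step ---
                mu, beta_tilde = posterior_coords(x, x0_hat, t, sched)
                if g.s > 0 and np.isfinite(dx).all():
                    mu = mu + _coord_shift(dx, g, beta_tilde)
                x = mu + np.sqrt(beta_tilde) * rng.standard_normal(mu.shape)
        except FloatingPointError as exc:
            logger.warning("dropping sample: %s", exc)
            continue
        # final molecule: predicted coordinates, argmax of the last clean-type
        # prediction
        z_final = np.zeros((n, K))
        z_final[np.arange(n), np.argmax(z0_hat, axis=1)] = 1.0
        mols.append(LigandAtoms(x, z_final))
        trajs.append(traj)
    return mols, trajs


def reconstruct_bonds(lig: LigandAtoms,
                      vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
                      tolerance: float = 0.45) -> LigandAtoms:
    """Assign bonds from a covalent-radius distance rule with valence caps.

    Candidate pairs with distance < r_cov_i + r_cov_j + tolerance are accepted
    shortest-first while both endpoints remain under their element's maximum
    valence, so an over-coordinated atom sheds its longest excess bonds.
    Disconnected results are allowed but logged.
    """
    import networkx as nx
    from scipy.spatial.distance import pdist, squareform

    elements = lig.elements(vocab)
    n = lig.n_atoms
    d = squareform(pdist(lig.x)) if n > 1 else np.zeros((1, 1))
    cands = []
    for i in range(n):
        for j in range(i + 1, n):
            limit = (_COVALENT_RADIUS[elements[i]]
                     + _COVALENT_RADIUS[elements[j]] + tolerance)
            if d[i, j] < limit:
                cands.append((d[i, j], i, j))
    degree = np.zeros(n, dtype=int)
    bonds = []
    for dist, i, j in sorted(cands):
        if (degree[i] < _MAX_VALENCE[elements[i]]
                and degree[j] < _MAX_VALENCE[elements[j]]):
            bonds.append((i, j, 1))
            degree[i] += 1
            degree[j] += 1
    out = LigandAtoms(lig.x.copy(), lig.z.copy(), bonds)
    if n > 1:
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        graph.add_edges_from([(i, j) for i, j, _ in bonds])
        if not nx.is_connected(graph):
            logger.info("reconstructed molecule is disconnected")
    return out
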