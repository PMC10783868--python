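"""Two-branch SE(3)-equivariant graph network.

A shared equivariant trunk embeds the joint pocket+ligand atom cloud; on top
of it sit two heads: a softmax type head predicting clean atom-type
distributions ẑ₀, and a sigmoid affinity head whose per-atom scores average
into a predicted normalized binding affinity v̂ ∈ [0, 1].  The trunk updates
invariant features h additively from attention-weighted messages and updates
coordinates additively along relative vectors, with a ligand mask so protein
coordinates never move.  All invariant inputs (distances, type embeddings,
edge kinds, time embedding) make h — and hence v̂ and ẑ₀ — SE(3)-invariant,
while coordinate outputs are SE(3)-equivariant by construction.

The network runs on the package's own reverse-mode autodiff engine; the same
forward graph serves prediction, training gradients and the affinity
gradients used for guided sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, segment_sum
from .chem_core import ProteinPocket
from .diffusion import DiffusionState

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "build_graph",
    "predict",
    "grad_affinity",
]

EDGE_KINDS = 4  # ligand→ligand, ligand→protein, protein→ligand, protein→protein


@dataclass(frozen=True)
class NetworkConfig:
    K: int = 8            # atom-type vocabulary size
    D: int = 128          # hidden width
    L: int = 4            # number of trunk layers
    k_neighbors: int = 16
    n_rbf: int = 16       # radial basis functions on edge distances
    rbf_max: float = 10.0 # Å, outermost RBF center
    d_edge: int = 8       # edge-kind embedding width
    d_time: int = 16      # sinusoidal time-embedding width (even)
    T: int = 1000         # diffusion horizon used for time normalization
    log_type_grad: bool = False  # use ∇log v̂ (not ∇v̂) for the type guidance


@dataclass
class NetworkParams:
    """Parameter container: one shared trunk `omega` plus two head sets."""

    omega: dict[str, np.ndarray]
    head_type: dict[str, np.ndarray]
    head_affinity: dict[str, np.ndarray]
    config: NetworkConfig

    @staticmethod
    def init(config: NetworkConfig, rng: np.random.Generator) -> "NetworkParams":
        D, K = config.D, config.K

        def mat(n_in, n_out):
            return rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in)

        omega: dict[str, np.ndarray] = {
            "emb_lig": mat(K, D),
            "emb_pkt": mat(K, D),
            "emb_role": mat(2, D),
            "emb_time": mat(config.d_time, D),
            "emb_edge": mat(EDGE_KINDS, config.d_edge),
        }
        e_in = 2 * D + config.n_rbf + config.d_edge
        for layer in range(config.L):
            omega[f"att_{layer}"] = mat(e_in, 1)
            omega[f"msg1_{layer}"] = mat(e_in, D)
            omega[f"msg1b_{layer}"] = np.zeros(D)
            omega[f"msg2_{layer}"] = mat(D, D)
            omega[f"gate1_{layer}"] = mat(e_in, D // 2)
            omega[f"gate1b_{layer}"] = np.zeros(D // 2)
            omega[f"gate2_{layer}"] = mat(D // 2, 1) * 0.1
        head_type = {
            "w1": mat(D, D), "b1": np.zeros(D),
            "w2": mat(D, K), "b2": np.zeros(K),
        }
        head_affinity = {
            "w1": mat(D, D), "b1": np.zeros(D),
            "w2": mat(D, 1), "b2": np.zeros(1),
        }
        return NetworkParams(omega, head_type, head_affinity, config)

    def flat(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, d in (("omega.", self.omega), ("head_type.", self.head_type),
                          ("head_affinity.", self.head_affinity)):
            out.update({prefix + k: v for k, v in d.items()})
        return out

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            {k: v.copy() for k, v in self.omega.items()},
            {k: v.copy() for k, v in self.head_type.items()},
            {k: v.copy() for k, v in self.head_affinity.items()},
            self.config,
        )


def build_graph(x: np.ndarray, is_ligand: np.ndarray, k: int):
    """Symmetrized k-nearest-neighbor edge list with edge-kind labels.

    Returns (dst, src, kind): directed edges src → dst.  Ties in distance are
    broken deterministically by atom index (stable argsort).  With fewer than
    k+1 atoms every node connects to all others.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(x)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    kk = min(k, n - 1)
    pairs = set()
    for i in range(n):
        for j in np.argsort(d[i], kind="stable")[:kk]:
            pairs.add((i, int(j)))
            pairs.add((int(j), i))
    dst, src = np.array(sorted(pairs)).T
    # kind index: 2*is_ligand[src] + is_ligand[dst] — 4 directed categories
    kind = (2 * is_ligand[src].astype(int) + is_ligand[dst].astype(int))
    return dst, src, kind


def _time_features(t: int, cfg: NetworkConfig) -> np.ndarray:
    half = cfg.d_time // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    phase = (t / cfg.T) * freqs
    return np.concatenate([np.sin(phase), np.cos(phase)])


def _mlp2(h: Tensor, p: dict[str, Tensor], pre: str = "") -> Tensor:
    hidden = (h @ p[pre + "w1"] + p[pre + "b1"]).silu()
    return hidden @ p[pre + "w2"] + p[pre + "b2"]


def forward(
    params: dict[str, Tensor],
    x_lig: Tensor,
    z_lig: Tensor,
    pocket: ProteinPocket,
    t: int,
    cfg: NetworkConfig,
):
    """Differentiable forward pass on the joint graph.

    Ligand atoms occupy rows [0, N_M); pocket rows follow.  Returns Tensors
    (x0_hat, z0_hat, per_atom_scores, v_hat).
    """
    n_lig = x_lig.shape[0]
    n_all = n_lig + pocket.n_atoms
    is_lig = np.zeros(n_all, dtype=bool)
    is_lig[:n_lig] = True

    x_pkt = Tensor(pocket.x)
    x = concat([x_lig, x_pkt], axis=0)
    mask = is_lig[:, None].astype(np.float64)

    # initial invariant embeddings
    h_lig = z_lig @ params["omega.emb_lig"]
    h_pkt = Tensor(pocket.z) @ params["omega.emb_pkt"]
    h = concat([h_lig, h_pkt], axis=0)
    role = np.zeros((n_all, 2))
    role[is_lig, 0] = 1.0
    role[~is_lig, 1] = 1.0
    h = h + Tensor(role) @ params["omega.emb_role"]
    h = h + Tensor(_time_features(t, cfg)[None, :]) @ params["omega.emb_time"]

    # neighbor lists fixed at the input geometry; distances recomputed per layer
    dst, src, kind = build_graph(x.data, is_lig, cfg.k_neighbors)
    kind_onehot = np.zeros((len(dst), EDGE_KINDS))
    kind_onehot[np.arange(len(dst)), kind] = 1.0
    e_emb = Tensor(kind_onehot) @ params["omega.emb_edge"]

    centers = np.linspace(0.0, cfg.rbf_max, cfg.n_rbf)[None, :]
    width = cfg.rbf_max / cfg.n_rbf

    for layer in range(cfg.L):
        rel = x.take_rows(dst) - x.take_rows(src)
        d = ((rel * rel).sum(axis=1, keepdims=True) + 1e-10).sqrt()
        rbf = (-((d - Tensor(centers)) * (1.0 / width)) ** 2).exp()
        feats = concat([h.take_rows(dst), h.take_rows(src), rbf, e_emb], axis=1)

        # attention over incoming edges of each destination node
        logits = feats @ params[f"omega.att_{layer}"]
        seg_max = np.full(n_all, -np.inf)
        np.maximum.at(seg_max, dst, logits.data[:, 0])
        elog = (logits - Tensor(seg_max[dst][:, None])).exp()
        denom = segment_sum(elog, dst, n_all).take_rows(dst)
        att = elog / (denom + 1e-30)

        msg = ((feats @ params[f"omega.msg1_{layer}"]
                + params[f"omega.msg1b_{layer}"]).silu()
               @ params[f"omega.msg2_{layer}"])
        h = h + segment_sum(att * msg, dst, n_all)

        gate = ((feats @ params[f"omega.gate1_{layer}"]
                 + params[f"omega.gate1b_{layer}"]).silu()
                @ params[f"omega.gate2_{layer}"]).tanh()
        dx = segment_sum(rel / (d + 1.0) * gate, dst, n_all)
        x = x + dx * Tensor(mask)  # protein coordinates never move

    h_lig_out = h.slice_rows(0, n_lig)
    x0_hat = x.slice_rows(0, n_lig)
    z0_hat = _mlp2(h_lig_out, params, "head_type.").softmax()
    per_atom = _mlp2(h_lig_out, params, "head_affinity.").sigmoid()
    v_hat = per_atom.mean()
    return x0_hat, z0_hat, per_atom, v_hat


def _wrap_params(params: NetworkParams, requires_grad: bool = False):
    return {k: Tensor(v, requires_grad=requires_grad)
            for k, v in params.flat().items()}


def predict(
    theta: NetworkParams,
    state: DiffusionState,
    pocket: ProteinPocket,
):
    """Run the network; returns (x0_hat, z0_hat, v_hat, per_atom_scores).

    z0_hat rows sum to 1; per-atom scores lie in (0, 1); v̂ is exactly their
    mean.
    """
    cfg = theta.config
    if not (0 <= state.t <= cfg.T):
        raise ValueError(f"timestep {state.t} outside [0, {cfg.T}]")
    p = _wrap_params(theta)
    x0_hat, z0_hat, per_atom, v_hat = forward(
        p, Tensor(state.x), Tensor(state.z), pocket, state.t, cfg
    )
    return (x0_hat.data.copy(), z0_hat.data.copy(),
            float(v_hat.data), per_atom.data[:, 0].copy())


def grad_affinity(
    theta: NetworkParams,
    state: DiffusionState,
    pocket: ProteinPocket,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the affinity classifier for guidance.

    Returns (dx, dz) where dx = ∇_{x_t} log v̂ (coordinate guidance uses the
    log-probability gradient) and dz = ∇_{z_t} v̂ (type guidance uses the raw
    probability gradient), both by reverse-mode differentiation through the
    full shared trunk.  `config.log_type_grad` switches dz to the log form.
    """
    cfg = theta.config
    p = _wrap_params(theta)
    x_t = Tensor(state.x, requires_grad=True)
    z_t = Tensor(state.z, requires_grad=True)
    _, _, _, v_hat = forward(p, x_t, z_t, pocket, state.t, cfg)
    v_hat.backward()
    v = float(v_hat.data)
    dx = x_t.grad / v  # chain rule: ∇ log v = ∇v / v
    dz = z_t.grad / v if cfg.log_type_grad else z_t.grad
    if not (np.isfinite(dx).all() and np.isfinite(dz).all()):
        raise FloatingPointError(
            "non-finite affinity gradient (inputs may be exploding)"
        )
    return dx, dz
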