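"""Forward corruption and reverse posteriors for the hybrid diffusion chain.

Coordinates follow a standard Gaussian chain:

    q(x_t | x_0)      = N(√ᾱ_t x_0, (1 − ᾱ_t) I)
    q(x_{t−1}|x_t,x_0) = N(μ̃_t, β̃_t I),
    μ̃_t = (√ᾱ_{t−1} β_t x̂_0 + √α_t (1 − ᾱ_{t−1}) x_t) / (1 − ᾱ_t)
    β̃_t = (1 − ᾱ_{t−1}) β_t / (1 − ᾱ_t)

Atom types follow a categorical chain with uniform transitions: at step t a
label is kept with probability α_t^cat and otherwise resampled uniformly over
the K classes, giving the closed-form marginal
q(z_t | z_0) = ᾱ_t^cat z_0 + (1 − ᾱ_t^cat)/K and a posterior proportional to
the product of the one-step likelihood of z_t and the marginal of z_{t−1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSchedule",
    "DiffusionState",
    "forward_coords",
    "forward_types",
    "posterior_coords",
    "posterior_types",
    "kl_categorical",
]

_EPS = 1e-12


def _sigmoid_betas(T: int, beta_min: float, beta_max: float) -> np.ndarray:
    # sigmoid ramp mapped onto [beta_min, beta_max]
    s = 1.0 / (1.0 + np.exp(-np.linspace(-6.0, 6.0, T)))
    s = (s - s[0]) / (s[-1] - s[0])
    return beta_min + s * (beta_max - beta_min)


def _cosine_keep_probs(T: int) -> np.ndarray:
    # cosine-style cumulative keep-probability for the categorical chain
    t = np.arange(1, T + 1) / T
    ab = np.cos((t + 0.008) / 1.008 * np.pi / 2) ** 2
    return np.clip(ab / np.cos(0.008 / 1.008 * np.pi / 2) ** 2, 1e-4, 1.0)


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule for the coordinate chain and keep-probability
    schedule for the categorical chain; all cumulative products precomputed.

    Index convention: arrays are length T and 1-based via the helpers
    (``beta_at(t)`` for t in 1..T); ᾱ_0 ≡ 1 by definition.
    """

    T: int
    beta: np.ndarray
    cat_alpha: np.ndarray  # per-step keep probability of the categorical chain

    @staticmethod
    def create(T: int = 1000, beta_min: float = 1e-7, beta_max: float = 1e-2,
               ) -> "NoiseSchedule":
        """Build the default schedule: sigmoid β ramp, cosine categorical chain.

        The β ramp is calibrated for T = 1000 (Σβ ≈ 5, so ᾱ_T ≈ 7e-3); for a
        shorter chain the per-step variances are rescaled (β_max ∝ 1000/T) so
        that ᾱ_T stays deep in the noise regime (ᾱ_T < 0.01) regardless of T,
        matching the standard-normal initialization of the sampler.
        """
        scale = 1000.0 / T
        beta = _sigmoid_betas(T, beta_min * scale, min(beta_max * scale, 0.999))
        ab = _cosine_keep_probs(T)
        cat_alpha = np.empty(T)
        cat_alpha[0] = ab[0]
        cat_alpha[1:] = ab[1:] / ab[:-1]
        return NoiseSchedule(T=T, beta=beta, cat_alpha=cat_alpha)

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        if len(beta) != self.T:
            raise ValueError("beta length must equal T")
        if not ((beta > 0).all() and (beta < 1).all()):
            raise ValueError("require 0 < beta_t < 1")
        if (np.diff(beta) < -1e-15).any():
            raise ValueError("beta must be non-decreasing")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(
            self, "cat_alpha", np.asarray(self.cat_alpha, dtype=np.float64)
        )

    @property
    def alpha_bar(self) -> np.ndarray:
        return np.cumprod(1.0 - self.beta)

    @property
    def cat_alpha_bar(self) -> np.ndarray:
        return np.cumprod(self.cat_alpha)

    # 1-based accessors; t = 0 returns the ᾱ_0 = 1 convention
    def beta_at(self, t: int) -> float:
        return float(self.beta[t - 1])

    def alpha_bar_at(self, t: int) -> float:
        return 1.0 if t == 0 else float(self.alpha_bar[t - 1])

    def cat_alpha_at(self, t: int) -> float:
        return float(self.cat_alpha[t - 1])

    def cat_alpha_bar_at(self, t: int) -> float:
        return 1.0 if t == 0 else float(self.cat_alpha_bar[t - 1])

    def to_dict(self) -> dict:
        return {"T": self.T, "beta": self.beta.tolist(),
                "cat_alpha": self.cat_alpha.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "NoiseSchedule":
        return NoiseSchedule(T=int(d["T"]), beta=np.array(d["beta"]),
                             cat_alpha=np.array(d["cat_alpha"]))


@dataclass
class DiffusionState:
    """The ligand part of the chain at one timestep: [x_t, z_t, t]."""

    x: np.ndarray
    z: np.ndarray
    t: int

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if (self.z < 0).any():
            raise ValueError("z entries must be non-negative")


def _check_t(t: int, sched: NoiseSchedule):
    if not (1 <= t <= sched.T):
        raise ValueError(f"timestep {t} outside [1, {sched.T}]")


def forward_coords(x0: np.ndarray, t: int, sched: NoiseSchedule,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample x_t ~ q(x_t | x_0) = N(√ᾱ_t x_0, (1 − ᾱ_t) I)."""
    _check_t(t, sched)
    ab = sched.alpha_bar_at(t)
    return np.sqrt(ab) * np.asarray(x0) + np.sqrt(1.0 - ab) * rng.standard_normal(
        np.shape(x0)
    )


def forward_types(z0: np.ndarray, t: int, sched: NoiseSchedule,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample one-hot z_t with marginal ᾱ_t^cat z_0 + (1 − ᾱ_t^cat)/K."""
    _check_t(t, sched)
    z0 = np.asarray(z0, dtype=np.float64)
    if not np.allclose(z0.sum(axis=-1), 1.0) or not np.isin(z0, (0.0, 1.0)).all():
        raise ValueError("z0 rows must be one-hot")
    K = z0.shape[-1]
    ab = sched.cat_alpha_bar_at(t)
    probs = ab * z0 + (1.0 - ab) / K
    out = np.zeros_like(z0)
    for i, p in enumerate(probs):
        out[i, rng.choice(K, p=p / p.sum())] = 1.0
    return out


def posterior_coords(x_t: np.ndarray, x0_hat: np.ndarray, t: int,
                     sched: NoiseSchedule) -> tuple[np.ndarray, float]:
    """Gaussian reverse-step posterior (μ̃_t, β̃_t) given a clean prediction."""
    if t < 1:
        raise ValueError("posterior undefined at t = 0")
    _check_t(t, sched)
    beta_t = sched.beta_at(t)
    alpha_t = 1.0 - beta_t
    ab_t = sched.alpha_bar_at(t)
    ab_prev = sched.alpha_bar_at(t - 1)
    mu = (
        np.sqrt(ab_prev) * beta_t * np.asarray(x0_hat)
        + np.sqrt(alpha_t) * (1.0 - ab_prev) * np.asarray(x_t)
    ) / (1.0 - ab_t)
    beta_tilde = (1.0 - ab_prev) * beta_t / (1.0 - ab_t)
    return mu, float(beta_tilde)


def posterior_types(z_t: np.ndarray, z0: np.ndarray, t: int,
                    sched: NoiseSchedule) -> np.ndarray:
    """Categorical posterior rows over z_{t−1} given z_t and (soft) z0.

    Accepts single rows or matrices; z_t may be any non-negative weighting of
    classes (guided states are not one-hot), z0 any non-negative distribution
    (normalized internally).  Rows of the result sum to 1.
    """
    if t < 1:
        raise ValueError("posterior undefined at t = 0")
    _check_t(t, sched)
    z_t = np.atleast_2d(np.asarray(z_t, dtype=np.float64))
    z0 = np.atleast_2d(np.asarray(z0, dtype=np.float64))
    if (z0.sum(axis=-1) <= 0).any():
        raise ValueError("z0 rows must have positive mass")
    z0 = z0 / z0.sum(axis=-1, keepdims=True)
    K = z_t.shape[-1]
    a_t = sched.cat_alpha_at(t)
    ab_prev = sched.cat_alpha_bar_at(t - 1)
    # likelihood of observing z_t from each candidate z_{t-1} class,
    # with uniform transitions: Q_t[j, k] = a_t δ_jk + (1 - a_t)/K
    lik = a_t * z_t + (1.0 - a_t) / K * z_t.sum(axis=-1, keepdims=True)
    prior = ab_prev * z0 + (1.0 - ab_prev) / K
    post = lik * prior
    return np.squeeze(post / post.sum(axis=-1, keepdims=True))


def kl_categorical(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p ‖ q) for probability rows, with q floored at 1e-12."""
    p = np.asarray(p, dtype=np.float64)
    q = np.clip(np.asarray(q, dtype=np.float64), _EPS, None)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
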