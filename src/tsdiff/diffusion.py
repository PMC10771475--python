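"""Closed-form machinery of the forward diffusion process.

A conformation ``C_0`` (an ``(N, 3)`` array of Cartesian coordinates in Å) is
noised through a Markov chain ``q(C_t | C_{t-1}) = N(sqrt(alpha_t) C_{t-1},
beta_t I)`` whose marginal is Gaussian in closed form:

    q(C_t | C_0) = N(sqrt(alpha_bar_t) C_0, (1 - alpha_bar_t) I),

with ``alpha_t = 1 - beta_t`` and ``alpha_bar_t = prod_{s<=t} alpha_s``.  The
score network is trained to predict the standardized noise

    eps = (C_t - sqrt(alpha_bar_t) C_0) / sqrt(1 - alpha_bar_t)
        = -sqrt(1 - alpha_bar_t) * grad_{C_t} log q(C_t | C_0),

with the squared-error loss ``||eps - eps_theta||^2`` (all KL coefficient
terms set to one).  The same target exists in distance coordinates, where it
is SE(3)-invariant; the chain rule back to Cartesian lives in the denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Conformation",
    "NoiseSchedule",
    "ScheduleError",
    "make_schedule",
    "default_schedule",
    "zero_center",
    "forward_sample",
    "score_target_cartesian",
    "score_target_distance",
    "training_loss",
    "gaussian_kl",
]

#: A conformation is an (N, 3) float array of Cartesian coordinates in Å.
Conformation = np.ndarray

#: Default full-scale schedule; beta_end chosen so alpha_bar_T < 1e-4
#: (prior matching: C_T is statistically indistinguishable from N(0, I)).
DEFAULT_T = 5000
DEFAULT_KIND = "sigmoid"
DEFAULT_BETA_START = 1e-7
DEFAULT_BETA_END = 4e-3
PRIOR_TOL = 1e-4


class ScheduleError(ValueError):
    """Schedule parameters violate a schedule invariant."""


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noise quantities beta_t, alpha_t, alpha_bar_t, sigma_t^2.

    Arrays are indexed ``[t - 1]`` for ``t = 1..T``; use :meth:`beta` etc.
    for 1-based access.  ``sigma2`` is the reverse-kernel variance: either
    ``beta_t`` (default) or the posterior variance
    ``beta_t (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t)``.
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    sigma2: np.ndarray

    def beta(self, t: int) -> float:
        self._check_t(t)
        return float(self.betas[t - 1])

    def alpha(self, t: int) -> float:
        self._check_t(t)
        return float(self.alphas[t - 1])

    def alpha_bar(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha_bars[t - 1])

    def sigma(self, t: int) -> float:
        self._check_t(t)
        return float(np.sqrt(self.sigma2[t - 1]))

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise IndexError(f"time step {t} outside 1..{self.T}")


def _beta_curve(T: int, kind: str, beta_start: float, beta_end: float) -> np.ndarray:
    if kind == "linear":
        return np.linspace(beta_start, beta_end, T)
    if kind == "sigmoid":
        x = np.linspace(-6.0, 6.0, T)
        return beta_start + (beta_end - beta_start) / (1.0 + np.exp(-x))
    if kind == "cosine":
        # squared-cosine signal decay (Nichol & Dhariwal), betas clipped to range
        s = 0.008
        steps = np.arange(T + 1) / T
        f = np.cos((steps + s) / (1 + s) * np.pi / 2) ** 2
        betas = 1.0 - f[1:] / f[:-1]
        return np.clip(betas, beta_start, beta_end)
    raise ScheduleError(f"unknown schedule kind {kind!r}")


def make_schedule(
    T: int,
    kind: str = DEFAULT_KIND,
    beta_start: float = DEFAULT_BETA_START,
    beta_end: float = DEFAULT_BETA_END,
    sigma_mode: str = "beta",
    prior_tol: float | None = None,
) -> NoiseSchedule:
    """Build a :class:`NoiseSchedule` of ``T`` steps.

    Parameters
    ----------
    kind:
        ``"sigmoid"`` (default), ``"linear"`` or ``"cosine"`` beta curve.
    sigma_mode:
        ``"beta"`` (sigma_t^2 = beta_t) or ``"posterior"``
        (sigma_t^2 = beta_t (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t)).
    prior_tol:
        If given, require ``alpha_bar_T < prior_tol`` so the terminal marginal
        matches the standard-normal prior; short toy schedules legitimately
        violate this, so the check is opt-in.
    """
    if T < 1:
        raise ScheduleError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ScheduleError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    betas = _beta_curve(T, kind, beta_start, beta_end)
    if np.any(betas <= 0.0) or np.any(betas >= 1.0):
        raise ScheduleError("beta curve left the open interval (0, 1)")
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    if np.any(np.diff(alpha_bars) >= 0):
        raise ScheduleError("alpha_bar is not strictly decreasing")
    if prior_tol is not None and alpha_bars[-1] >= prior_tol:
        raise ScheduleError(
            f"alpha_bar_T = {alpha_bars[-1]:.3e} >= prior tolerance {prior_tol:.1e}; "
            "increase T or beta_end"
        )
    if sigma_mode == "beta":
        sigma2 = betas.copy()
    elif sigma_mode == "posterior":
        prev = np.concatenate([[1.0], alpha_bars[:-1]])
        sigma2 = betas * (1.0 - prev) / (1.0 - alpha_bars)
    else:
        raise ScheduleError(f"unknown sigma_mode {sigma_mode!r}")
    return NoiseSchedule(T=T, betas=betas, alphas=alphas, alpha_bars=alpha_bars, sigma2=sigma2)


def default_schedule() -> NoiseSchedule:
    """The full-scale 5000-step sigmoid schedule with the prior check enabled."""
    return make_schedule(DEFAULT_T, prior_tol=PRIOR_TOL)


def zero_center(c: Conformation) -> Conformation:
    """Translate a conformation to zero center of geometry."""
    c = np.asarray(c, dtype=np.float64)
    if c.size == 0:
        return c
    return c - c.mean(axis=0, keepdims=True)


def forward_sample(
    c0: Conformation,
    t: int,
    sched: NoiseSchedule,
    rng: np.random.Generator,
) -> tuple[Conformation, np.ndarray]:
    """Draw ``C_t ~ q(C_t | C_0)`` and return ``(C_t, eps)`` with the drawn noise.

    ``C_0`` is zero-centered before noising (translation gauge fix; the
    SE(3)-invariant loss and metrics make the choice inconsequential).
    """
    sched._check_t(t)
    c0 = zero_center(c0)
    ab = sched.alpha_bar(t)
    z = rng.standard_normal(c0.shape)
    ct = np.sqrt(ab) * c0 + np.sqrt(1.0 - ab) * z
    return ct, z


def score_target_cartesian(
    c0: Conformation, ct: Conformation, t: int, sched: NoiseSchedule
) -> np.ndarray:
    """eps = (C_t - sqrt(alpha_bar_t) C_0) / sqrt(1 - alpha_bar_t); inverts forward_sample."""
    c0 = zero_center(np.asarray(c0, dtype=np.float64))
    ct = np.asarray(ct, dtype=np.float64)
    if c0.shape != ct.shape:
        raise ValueError(f"shape mismatch: {c0.shape} vs {ct.shape}")
    ab = sched.alpha_bar(t)
    if 1.0 - ab <= 0.0:
        raise ZeroDivisionError("alpha_bar_t = 1: noise amplitude is zero")
    return (ct - np.sqrt(ab) * c0) / np.sqrt(1.0 - ab)


def score_target_distance(
    d0: np.ndarray, dt: np.ndarray, t: int, sched: NoiseSchedule
) -> np.ndarray:
    """Per-edge target (d_t - sqrt(alpha_bar_t) d_0) / sqrt(1 - alpha_bar_t).

    Derived from a Gaussian approximation of the noising process in distance
    coordinates; SE(3)-invariant because distances are.
    """
    d0 = np.asarray(d0, dtype=np.float64)
    dt = np.asarray(dt, dtype=np.float64)
    if d0.shape != dt.shape:
        raise ValueError(f"edge-set shapes differ: {d0.shape} vs {dt.shape}")
    ab = sched.alpha_bar(t)
    return (dt - np.sqrt(ab) * d0) / np.sqrt(1.0 - ab)


def training_loss(eps: np.ndarray, eps_pred: np.ndarray) -> float:
    """Score-matching loss: squared error summed over xyz, averaged over atoms."""
    eps = np.asarray(eps, dtype=np.float64)
    eps_pred = np.asarray(eps_pred, dtype=np.float64)
    if eps.shape != eps_pred.shape:
        raise ValueError(f"shape mismatch: {eps.shape} vs {eps_pred.shape}")
    n = eps.shape[0]
    if n == 0:
        return 0.0
    return float(np.sum((eps - eps_pred) ** 2) / n)


def gaussian_kl(mu_q: float, var_q: float, mu_p: float, var_p: float) -> float:
    """KL(N(mu_q, var_q) || N(mu_p, var_p)) for scalar Gaussians.

    The closed form behind the per-step KL whose unit-coefficient limit is the
    squared-error score-matching loss.
    """
    return float(
        0.5 * (np.log(var_p / var_q) + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0)
    )
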