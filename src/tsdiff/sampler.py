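"""Reverse-time generation of transition-state geometries.

Starting from pure noise ``C_T ~ N(0, I)``, the sampler iterates the learned
reverse kernel

    p(C_{t-1} | C_t, G_rxn) = N(mu_theta(C_t, G_rxn, t), sigma_t^2 I),

where the mean is recovered from the predicted standardized noise:

    mu_theta = (C_t - (beta_t / sqrt(1 - alpha_bar_t)) eps_theta) / sqrt(alpha_t).

The final step (t = 1) adds no noise.  An ensemble of models is combined by
averaging their eps_theta predictions at every step.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .denoiser import DenoiserModel, build_geometric_graph
from .diffusion import Conformation, NoiseSchedule
from .rxn_graph import ReactionGraph

__all__ = ["init_state", "denoise_step", "generate", "mu_from_eps", "eps_from_mu"]

#: A score predictor: maps (C_t, reaction graph, t) to per-atom eps (N, 3).
EpsFn = Callable[[np.ndarray, ReactionGraph, int], np.ndarray]


def init_state(n_atoms: int, rng: np.random.Generator) -> Conformation:
    """Draw the fully-noised starting geometry ``C_T ~ N(0, I)``."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return rng.standard_normal((n_atoms, 3))


def mu_from_eps(ct: np.ndarray, eps: np.ndarray, t: int, sched: NoiseSchedule) -> np.ndarray:
    """Reverse-kernel mean from the predicted noise."""
    a = sched.alpha(t)
    ab = sched.alpha_bar(t)
    return (ct - (sched.beta(t) / np.sqrt(1.0 - ab)) * eps) / np.sqrt(a)


def eps_from_mu(ct: np.ndarray, mu: np.ndarray, t: int, sched: NoiseSchedule) -> np.ndarray:
    """Algebraic inverse of :func:`mu_from_eps`:
    eps = sqrt(1 - alpha_bar_t)/beta_t * (C_t - sqrt(alpha_t) mu)."""
    a = sched.alpha(t)
    ab = sched.alpha_bar(t)
    return np.sqrt(1.0 - ab) / sched.beta(t) * (ct - np.sqrt(a) * mu)


def _resolve_eps_fn(
    models: DenoiserModel | Sequence[DenoiserModel] | EpsFn,
) -> EpsFn:
    if callable(models) and not isinstance(models, DenoiserModel):
        return models
    ms: list[DenoiserModel] = (
        [models] if isinstance(models, DenoiserModel) else list(models)
    )
    if not ms:
        raise ValueError("empty model ensemble")
    cutoffs = {m.config.cutoff for m in ms}
    if len(cutoffs) != 1:
        raise ValueError("ensemble members disagree on cutoff radius")
    cutoff = cutoffs.pop()

    def eps_fn(ct: np.ndarray, g: ReactionGraph, t: int) -> np.ndarray:
        gg = build_geometric_graph(g, ct, t, cutoff=cutoff)
        preds = [m.eps_theta(gg) for m in ms]
        return np.mean(preds, axis=0)

    return eps_fn


def denoise_step(
    ct: Conformation,
    t: int,
    g: ReactionGraph,
    models: DenoiserModel | Sequence[DenoiserModel] | EpsFn,
    sched: NoiseSchedule,
    rng: np.random.Generator,
) -> Conformation:
    """One ancestral step: draw ``C_{t-1} ~ p(C_{t-1} | C_t, G_rxn)``.

    ``models`` may be a single model, an ensemble (eps averaged), or a bare
    callable ``(C_t, g, t) -> eps`` (e.g. an exact-score oracle in tests).
    """
    sched._check_t(t)
    eps_fn = _resolve_eps_fn(models)
    eps = eps_fn(np.asarray(ct, dtype=np.float64), g, t)
    if eps.shape != np.shape(ct):
        raise ValueError(f"model output shape {eps.shape} != state shape {np.shape(ct)}")
    mu = mu_from_eps(ct, eps, t, sched)
    if t == 1:
        return mu
    return mu + sched.sigma(t) * rng.standard_normal(mu.shape)


def generate(
    g: ReactionGraph,
    models: DenoiserModel | Sequence[DenoiserModel] | EpsFn,
    sched: NoiseSchedule,
    n_rounds: int,
    rng: np.random.Generator,
) -> list[Conformation]:
    """Sample ``n_rounds`` independent geometries for one reaction graph.

    Each round runs the full T-step denoising chain from fresh noise; the
    geometric graph (radius edges) is rebuilt at every step from the current
    positions.
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    if isinstance(models, DenoiserModel) or (
        not callable(models) and len(list(models))
    ):
        ms = [models] if isinstance(models, DenoiserModel) else list(models)
        if any(m.config.node_feat_dim != g.node_features.shape[1] for m in ms):
            raise ValueError(
                "model node-feature width incompatible with this reaction graph"
            )
    eps_fn = _resolve_eps_fn(models)
    samples: list[Conformation] = []
    for _ in range(n_rounds):
        c = init_state(g.n_atoms, rng)
        for t in range(sched.T, 0, -1):
            c = denoise_step(c, t, g, eps_fn, sched, rng)
        samples.append(c)
    return samples
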