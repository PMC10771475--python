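"""Desk-scale studies shared by the examples, tests and acceptance script.

These wrap the full pipeline (toy fixtures -> training -> ancestral sampling
-> ensemble metrics) at a size that runs in well under a minute on one CPU
core, with every random draw derived from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .denoiser import DenoiserModel, ModelConfig
from .diffusion import NoiseSchedule, make_schedule
from .fixtures import TEMPLATES, augment_reverse, make_toy_dataset
from .metrics import SampleSet, coverage, matching
from .sampler import generate
from .train import train

__all__ = [
    "study_schedule",
    "study_model_config",
    "toy_recovery_study",
]

# Schedule and model sizes chosen for the toy study: T=200 keeps sampling
# cheap, and beta_end=5e-2 still drives alpha_bar_T below 1e-4 at that T.
STUDY_T = 200
STUDY_BETA_START = 1e-5
STUDY_BETA_END = 5e-2


def study_schedule() -> NoiseSchedule:
    """The short noise schedule used for all desk-scale studies."""
    return make_schedule(STUDY_T, beta_start=STUDY_BETA_START, beta_end=STUDY_BETA_END)


def study_model_config() -> ModelConfig:
    """A small denoiser (2 interaction layers) sized for the toy fixtures."""
    return ModelConfig(hidden=64, n_layers=2, n_rbf=32)


def toy_recovery_study(
    seed: int,
    n_reactions: int = 20,
    n_steps: int = 2000,
    batch_size: int = 16,
    lr: float = 2e-3,
    rounds: tuple[int, ...] = (1, 3, 10),
    delta: float = 0.2,
    model: DenoiserModel | None = None,
) -> dict:
    """Train on single-mode toy reactions and measure ensemble recovery.

    Builds ``n_reactions`` single-mode toy records (reverse-augmented),
    trains the small study model, then for each reaction template draws
    ``max(rounds)`` samples and evaluates COV(delta)/MAT against that
    template's noise-free mode geometry at each cumulative round count.
    Because the per-round sample sets are nested prefixes of one run,
    COV is non-decreasing and MAT non-increasing in the round count by
    construction; the study reports the measured values.

    Returns a dict with the trained model, per-round-count mean COV/MAT
    across templates, and the final training loss.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(101,))
    data_seed, sample_entropy = [int(s.generate_state(1)[0]) % 2**31 for s in ss.spawn(2)]
    sched = study_schedule()
    dataset = augment_reverse(make_toy_dataset(n_reactions, modes_per_reaction=1, seed=data_seed))
    if model is None:
        model, losses = train(
            dataset, sched, config=study_model_config(), n_steps=n_steps,
            batch_size=batch_size, lr=lr, seed=seed, log_every=0,
        )
        final_loss = losses[-1]
    else:
        final_loss = None

    max_rounds = max(rounds)
    cov_by_rounds: dict[int, list[float]] = {r: [] for r in rounds}
    mat_by_rounds: dict[int, list[float]] = {r: [] for r in rounds}
    for k, template in enumerate(TEMPLATES):
        graph = template.graph()
        reference = [template.geometry(0)]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=sample_entropy, spawn_key=(k,))
        )
        samples = generate(graph, model, sched, max_rounds, rng)
        for r in rounds:
            s = SampleSet(s_gen=samples[:r], s_ref=reference, graph=graph, delta=delta)
            cov_by_rounds[r].append(coverage(s))
            mat_by_rounds[r].append(matching(s))
    return {
        "model": model,
        "final_loss": final_loss,
        "delta": delta,
        "rounds": list(rounds),
        "cov": {r: float(np.mean(v)) for r, v in cov_by_rounds.items()},
        "mat": {r: float(np.mean(v)) for r, v in mat_by_rounds.items()},
    }
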