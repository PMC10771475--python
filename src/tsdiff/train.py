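"""Score-matching training of the denoiser.

Each step draws a mini-batch of (reaction graph, reference geometry)
records, a uniform time step per record, and a forward-noised geometry.
The model's per-edge (distance-coordinate) scores are projected to per-atom
vectors by the chain rule, and that projection eps_theta is regressed
directly onto the standardized Cartesian noise eps drawn in the forward
sample: loss = ||eps - eps_theta||^2, squared error summed over xyz and
averaged over atoms.

Regressing the projected output onto the Cartesian noise (rather than
projecting a per-edge distance target first) keeps the training target on
the same scale as the drift the reverse kernel applies at sampling time.
The per-edge distance target sums many edge contributions into each atom,
which inflates the magnitude of the projected field by an edge-multiplicity
factor; a reverse process driven by that field is over-contractive and
collapses minor conformational modes.  Optimization is plain Adam; batches
are disjoint unions of the individual geometric graphs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .denoiser import (
    DenoiserModel,
    ModelConfig,
    build_geometric_graph,
    edge_to_atom_tensor,
    save_checkpoint,
)
from .diffusion import NoiseSchedule, forward_sample, zero_center

__all__ = ["Adam", "TrainingDiverged", "training_batch_loss", "train"]


class TrainingDiverged(RuntimeError):
    """The loss became non-finite; training is aborted with diagnostics."""


class Adam:
    """Adam optimizer over the model's parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.step_count = 0

    def step(self) -> None:
        self.step_count += 1
        b1c = 1.0 - self.beta1 ** self.step_count
        b2c = 1.0 - self.beta2 ** self.step_count
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state(self) -> dict:
        return {"m": self.m, "v": self.v, "step_count": self.step_count}

    def load_state(self, state: dict) -> None:
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
        self.step_count = int(state["step_count"])


def _record_graph_and_conf(rec):
    if isinstance(rec, tuple):
        return rec[0], rec[1]
    return rec.graph, rec.conformation


def training_batch_loss(
    model: DenoiserModel,
    records: list,
    sched: NoiseSchedule,
    rng: np.random.Generator,
) -> Tensor:
    """Loss of one mini-batch as a scalar autodiff node.

    The individual geometric graphs (built from the noisy positions, so
    radius edges reflect C_t) are concatenated into one disjoint-union graph;
    each record gets its own uniform time step in [1, T].
    """
    node_feats, edge_feats, dists, edge_idx, t_nodes, targets, positions = (
        [], [], [], [], [], [], []
    )
    offset = 0
    for rec in records:
        g, c0 = _record_graph_and_conf(rec)
        t = int(rng.integers(1, sched.T + 1))
        c0 = zero_center(c0)
        ct, z = forward_sample(c0, t, sched, rng)
        gg = build_geometric_graph(g, ct, t, cutoff=model.config.cutoff)
        targets.append(z)
        node_feats.append(g.node_features)
        edge_feats.append(gg.edge_features)
        dists.append(gg.distances)
        edge_idx.append(gg.edge_index + offset)
        t_nodes.append(np.full(g.n_atoms, t))
        positions.append(ct)
        offset += g.n_atoms
    edge_idx_all = np.concatenate(edge_idx)
    dists_all = np.concatenate(dists)
    pos_all = np.concatenate(positions)
    scores = model.edge_scores(
        np.concatenate(node_feats),
        edge_idx_all,
        np.concatenate(edge_feats),
        dists_all,
        np.concatenate(t_nodes),
    )
    pred = edge_to_atom_tensor(scores, edge_idx_all, pos_all, dists_all, offset)
    diff = pred - Tensor(np.concatenate(targets))
    return diff.square().sum() / offset


def train(
    dataset: list,
    sched: NoiseSchedule,
    config: ModelConfig | None = None,
    n_steps: int = 1000,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
    model: DenoiserModel | None = None,
    optimizer: Adam | None = None,
    start_step: int = 0,
    checkpoint_path=None,
    log_every: int = 100,
) -> tuple[DenoiserModel, list[float]]:
    """Seeded, resumable training loop; returns the model and per-step losses.

    Resuming: pass the loaded ``model``/``optimizer`` and ``start_step``; with
    the same seed the batch draws are re-derived per step index, so a resumed
    run reproduces the uninterrupted trajectory.
    """
    if model is None:
        model = DenoiserModel(config or ModelConfig(), np.random.default_rng(seed))
    if optimizer is None:
        optimizer = Adam(model.params, lr=lr)
    losses: list[float] = []
    for step in range(start_step, n_steps):
        # per-step child seed: reproducible regardless of interruption point
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(step,)))
        idx = rng.choice(len(dataset), size=min(batch_size, len(dataset)), replace=False)
        loss = training_batch_loss(model, [dataset[i] for i in idx], sched, rng)
        if not np.isfinite(loss.value):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: {loss.value!r} "
                f"(lr={lr}, batch={len(idx)})"
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(float(loss.value))
        if log_every and (step + 1) % log_every == 0:
            recent = float(np.mean(losses[-log_every:]))
            print(f"step {step + 1}/{n_steps}  loss {recent:.4f}")
    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path,
            model,
            extra={"n_steps": n_steps, "seed": seed, "final_loss": losses[-1] if losses else None},
        )
    return model, losses
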