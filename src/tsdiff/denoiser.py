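"""Graph neural score network on condensed reaction graphs.

The network predicts the score of the noising process *in distance
coordinates*: one scalar per edge of the geometric graph.  Because positions
enter only through interatomic distances, edge scores are invariant to
global rotations, translations and reflections; the chain-rule projection

    atom_i  <-  sum_{edges (i,j)}  s_ij * (x_i - x_j) / d_ij

is translation-invariant and rotation-equivariant, which makes the implied
generative distribution SE(3)-invariant.

Architecture: node/edge embeddings, then ``n_layers`` modified SchNet
interaction blocks

    m_ij^l     = MLP2^l(h_j^l) * ( W_rbf^l rbf(d_ij)  ⊙  pi_edge(f_ij) )
    h_i^{l+1}  = MLP1^l( MLP2^l(h_i^l) + sum_j m_ij^l )

followed by a symmetric per-edge head on ``[h_i, h_j, rbf(d_ij),
pi_edge(f_ij)]``.  Diffusion time enters as a sinusoidal embedding
concatenated to the input node features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .autodiff import Tensor, concat, gather_rows, segment_sum, shifted_softplus
from .rxn_graph import ReactionGraph

__all__ = [
    "ModelConfig",
    "GeometricGraph",
    "DenoiserModel",
    "DegenerateGeometryError",
    "build_geometric_graph",
    "edge_to_atom_scores",
    "save_checkpoint",
    "load_checkpoint",
]


class DegenerateGeometryError(ValueError):
    """Two atoms connected by an edge coincide (zero distance)."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the score network."""

    hidden: int = 256
    n_layers: int = 7
    n_rbf: int = 64
    rbf_max: float = 10.0  # Å; Gaussian centers span [0, rbf_max]
    cutoff: float = 10.0  # Å; radius edges added below this distance
    time_dim: int = 16
    node_feat_dim: int = 26
    edge_feat_dim: int = 16

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class GeometricGraph:
    """A reaction graph dressed with current 3D positions.

    Edges are the union of reaction-graph edges (kept at any distance) and
    radius edges (non-graph pairs closer than the cutoff, carrying the
    all-zero reaction feature).
    """

    base: ReactionGraph
    positions: np.ndarray  # (N, 3)
    t: int
    edge_index: np.ndarray  # (E, 2), i < j
    edge_features: np.ndarray  # (E, edge_feat_dim)
    distances: np.ndarray  # (E,)
    n_atoms: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_atoms = self.base.n_atoms


def build_geometric_graph(
    g: ReactionGraph, positions: np.ndarray, t: int, cutoff: float = 10.0
) -> GeometricGraph:
    """Attach positions to a reaction graph and add radius edges below ``cutoff``."""
    positions = np.asarray(positions, dtype=np.float64)
    if positions.shape != (g.n_atoms, 3):
        raise ValueError(f"positions shape {positions.shape} != ({g.n_atoms}, 3)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = g.n_atoms
    dmat = squareform(pdist(positions)) if n > 1 else np.zeros((n, n))
    graph_pairs = set(g.edges)
    pairs: list[tuple[int, int]] = list(g.edges)
    feats = [g.edge_features[k] for k in range(len(g.edges))]
    zero = np.zeros(g.edge_features.shape[1] if g.edge_features.size else 16)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in graph_pairs and dmat[i, j] < cutoff:
                pairs.append((i, j))
                feats.append(zero)
    edge_index = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    dists = (
        dmat[edge_index[:, 0], edge_index[:, 1]] if len(pairs) else np.zeros(0)
    )
    if np.any(dists <= 0.0):
        raise DegenerateGeometryError("coincident atoms on an edge (d_ij = 0)")
    return GeometricGraph(
        base=g,
        positions=positions,
        t=t,
        edge_index=edge_index,
        edge_features=np.asarray(feats).reshape(len(pairs), -1),
        distances=dists,
    )


# -- featurization helpers ----------------------------------------------------


def rbf_expand(d: np.ndarray, n_rbf: int, rbf_max: float) -> np.ndarray:
    """Gaussian radial basis expansion of distances, centers on [0, rbf_max]."""
    centers = np.linspace(0.0, rbf_max, n_rbf)
    gamma = 1.0 / (centers[1] - centers[0]) ** 2 if n_rbf > 1 else 1.0
    return np.exp(-gamma * (np.asarray(d)[:, None] - centers[None, :]) ** 2)


def time_embedding(t: int | np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of the diffusion step (transformer convention)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


# -- the model ----------------------------------------------------------------


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


class DenoiserModel:
    """The score network eps_theta; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        c = config
        p: dict[str, Tensor] = {}

        def lin(name: str, n_in: int, n_out: int) -> None:
            p[f"{name}.W"] = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
            p[f"{name}.b"] = Tensor(np.zeros(n_out), requires_grad=True)

        lin("node_embed", c.node_feat_dim + c.time_dim, c.hidden)
        lin("edge_embed", c.edge_feat_dim, c.hidden)
        for l in range(c.n_layers):
            lin(f"layer{l}.rbf", c.n_rbf, c.hidden)
            lin(f"layer{l}.mlp1.0", c.hidden, c.hidden)
            lin(f"layer{l}.mlp1.1", c.hidden, c.hidden)
            lin(f"layer{l}.mlp2.0", c.hidden, c.hidden)
            lin(f"layer{l}.mlp2.1", c.hidden, c.hidden)
        head_in = 2 * c.hidden + c.n_rbf + c.hidden
        lin("head.0", head_in, c.hidden)
        lin("head.1", c.hidden, 1)
        self.params = p

    # ------------------------------------------------------------------

    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _mlp(self, name: str, x: Tensor) -> Tensor:
        return self._linear(f"{name}.1", shifted_softplus(self._linear(f"{name}.0", x)))

    def edge_scores(
        self,
        node_features: np.ndarray,
        edge_index: np.ndarray,
        edge_features: np.ndarray,
        distances: np.ndarray,
        t_per_node: np.ndarray,
    ) -> Tensor:
        """Per-edge scalar scores for a (possibly batched) geometric graph.

        Positions enter only through ``distances``, so the output is invariant
        under rigid motions; the head averages both edge orientations, so it
        is symmetric in (i, j).
        """
        c = self.config
        n = node_features.shape[0]
        temb = time_embedding(t_per_node, c.time_dim)
        h = shifted_softplus(
            self._linear("node_embed", Tensor(np.concatenate([node_features, temb], axis=1)))
        )
        e_emb = shifted_softplus(self._linear("edge_embed", Tensor(edge_features)))
        rbf = rbf_expand(distances, c.n_rbf, c.rbf_max)

        if len(edge_index):
            src = np.concatenate([edge_index[:, 1], edge_index[:, 0]])  # j of j->i
            dst = np.concatenate([edge_index[:, 0], edge_index[:, 1]])
        else:
            src = dst = np.zeros(0, dtype=np.int64)

        for l in range(c.n_layers):
            filt_half = shifted_softplus(self._linear(f"layer{l}.rbf", Tensor(rbf))) * e_emb
            h2 = self._mlp(f"layer{l}.mlp2", h)
            if len(edge_index):
                filt = concat([filt_half, filt_half], axis=0)
                msgs = gather_rows(h2, src) * filt
                agg = segment_sum(msgs, dst, n)
            else:
                agg = Tensor(np.zeros((n, c.hidden)))
            h = self._mlp(f"layer{l}.mlp1", h2 + agg)

        if not len(edge_index):
            return Tensor(np.zeros((0, 1)))
        hi = gather_rows(h, edge_index[:, 0])
        hj = gather_rows(h, edge_index[:, 1])
        rbf_t = Tensor(rbf)
        s_ij = self._mlp("head", concat([hi, hj, rbf_t, e_emb], axis=1))
        s_ji = self._mlp("head", concat([hj, hi, rbf_t, e_emb], axis=1))
        return (s_ij + s_ji) * 0.5

    def predict_edge_scores(self, gg: GeometricGraph) -> np.ndarray:
        """Numpy convenience wrapper over :meth:`edge_scores` for one graph."""
        t_per_node = np.full(gg.n_atoms, gg.t)
        out = self.edge_scores(
            gg.base.node_features, gg.edge_index, gg.edge_features, gg.distances, t_per_node
        )
        return out.value.ravel()

    def eps_theta(self, gg: GeometricGraph) -> np.ndarray:
        """Per-atom Cartesian score prediction for one geometric graph."""
        return edge_to_atom_scores(self.predict_edge_scores(gg), gg)


def edge_to_atom_scores(edge_scores: np.ndarray, gg: GeometricGraph) -> np.ndarray:
    """Chain-rule projection of per-edge scores to per-atom 3-vectors.

    ``atom_i += s_ij (x_i - x_j)/d_ij`` and the opposite for ``j``; internal
    pairwise contributions cancel, so the vectors sum to zero.
    """
    s = np.asarray(edge_scores, dtype=np.float64).ravel()
    if s.shape[0] != len(gg.edge_index):
        raise ValueError("edge scores not aligned with graph edges")
    out = np.zeros((gg.n_atoms, 3))
    if not len(gg.edge_index):
        return out
    i, j = gg.edge_index[:, 0], gg.edge_index[:, 1]
    if np.any(gg.distances <= 0):
        raise DegenerateGeometryError("zero-length edge")
    u = (gg.positions[i] - gg.positions[j]) / gg.distances[:, None]
    np.add.at(out, i, s[:, None] * u)
    np.add.at(out, j, -s[:, None] * u)
    return out


def edge_to_atom_tensor(
    edge_scores: Tensor, edge_index: np.ndarray, positions: np.ndarray,
    distances: np.ndarray, n_atoms: int,
) -> Tensor:
    """Differentiable (w.r.t. scores) version of :func:`edge_to_atom_scores`."""
    if not len(edge_index):
        return Tensor(np.zeros((n_atoms, 3)))
    i, j = edge_index[:, 0], edge_index[:, 1]
    u = (positions[i] - positions[j]) / distances[:, None]
    contrib = edge_scores * Tensor(u)
    return segment_sum(contrib, i, n_atoms) + segment_sum(contrib * -1.0, j, n_atoms)


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(path, model: DenoiserModel, extra: dict | None = None) -> None:
    """Write parameters + config (and its hash) to a single ``.npz`` file."""
    meta = {"config": asdict(model.config), "hash": model.config.hash()}
    if extra:
        meta["extra"] = extra
    arrays = {k: v.value for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> DenoiserModel:
    """Load a checkpoint; verifies the stored config hash."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    config = ModelConfig(**meta["config"])
    if config.hash() != meta["hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = DenoiserModel(config)
    for k in model.params:
        model.params[k].value = data[k]
    return model
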