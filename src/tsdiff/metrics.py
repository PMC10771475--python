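"""Evaluation metrics for generated conformer ensembles.

The base metric is the mean absolute error of interatomic distances,

    D-MAE(C, C') = 2 / (N (N - 1)) * sum_{i<j} |d_ij - d'_ij|,

which depends only on the two distance sets and is therefore blind to rigid
motions and reflections.  Atoms that are indistinguishable on the molecular
graph (e.g. the hydrogens of a methyl group) make the raw value
permutation-dependent, so the aligned variant minimizes over the
automorphisms of the condensed reaction graph — relabelings that preserve
both sides' bonds and all atom features, i.e. the atom identities the
reaction itself cannot distinguish.

On top of D-MAE sit the ensemble scores: coverage COV (fraction of
references within ``delta`` of some generated sample) and matching MAT (mean
over references of the minimum D-MAE), plus deduplication and reference
matching at the 0.01 Å resolution used to distinguish optimized conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .diffusion import Conformation
from .rxn_graph import ReactionGraph

__all__ = [
    "SampleSet",
    "graph_automorphisms",
    "dmae",
    "coverage",
    "matching",
    "deduplicate",
    "conformer_match",
]


def graph_automorphisms(graph: ReactionGraph) -> list[np.ndarray]:
    """Feature-preserving automorphisms of the condensed reaction graph.

    Built on the 1-hop bond skeleton (union of both sides) with node labels =
    full concatenated node features and edge labels = the (reactant, product)
    bond-type pair; any such automorphism preserves 3-hop distances too.
    Atoms distinguishable on either side are never swapped.
    """
    n = graph.n_atoms
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, label=tuple(graph.node_features[i]))
    r_bonds = {(i, j): t for i, j, t in graph.reactant.bonds}
    p_bonds = {(i, j): t for i, j, t in graph.product.bonds}
    for ij in set(r_bonds) | set(p_bonds):
        g.add_edge(*ij, label=(r_bonds.get(ij), p_bonds.get(ij)))
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perm = np.empty(n, dtype=np.int64)
        for src, dst in mapping.items():
            perm[src] = dst
        perms.append(perm)
    return perms


def _dmae_raw(c: Conformation, c_hat: Conformation) -> float:
    c = np.asarray(c, dtype=np.float64)
    c_hat = np.asarray(c_hat, dtype=np.float64)
    if c.shape != c_hat.shape:
        raise ValueError(f"atom-count mismatch: {c.shape} vs {c_hat.shape}")
    n = c.shape[0]
    if n < 2:
        return 0.0
    return float(np.mean(np.abs(pdist(c) - pdist(c_hat))))


def dmae(
    c: Conformation,
    c_hat: Conformation,
    align: bool = False,
    graph: ReactionGraph | None = None,
) -> float:
    """D-MAE between two geometries, in Å.

    With ``align=True`` (requires ``graph``) the value is minimized over the
    graph's automorphisms, applied to ``c_hat``'s atom indices.
    """
    if not align:
        return _dmae_raw(c, c_hat)
    if graph is None:
        raise ValueError("align=True requires the reaction graph")
    c_hat = np.asarray(c_hat, dtype=np.float64)
    return min(_dmae_raw(c, c_hat[perm]) for perm in graph_automorphisms(graph))


@dataclass
class SampleSet:
    """Generated and reference conformations for one reaction graph."""

    s_gen: list[Conformation]
    s_ref: list[Conformation]
    graph: ReactionGraph
    delta: float = 0.1  # Å; COV threshold
    _autos: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        n = self.graph.n_atoms
        for c in list(self.s_gen) + list(self.s_ref):
            if np.shape(c) != (n, 3):
                raise ValueError("conformation shape does not match the graph")

    def aligned_dmae(self, c: Conformation, c_hat: Conformation) -> float:
        if self._autos is None:
            self._autos = graph_automorphisms(self.graph)
        c_hat = np.asarray(c_hat, dtype=np.float64)
        return min(_dmae_raw(c, c_hat[perm]) for perm in self._autos)


def coverage(s: SampleSet) -> float:
    """COV score in percent: references with some sample at D-MAE < delta."""
    if not s.s_ref:
        raise ValueError("COV undefined for an empty reference set")
    if not s.s_gen:
        return 0.0
    covered = sum(
        1
        for ref in s.s_ref
        if any(s.aligned_dmae(ref, gen) < s.delta for gen in s.s_gen)
    )
    return 100.0 * covered / len(s.s_ref)


def matching(s: SampleSet) -> float:
    """MAT score in Å: mean over references of the minimum aligned D-MAE."""
    if not s.s_ref or not s.s_gen:
        raise ValueError("MAT undefined for empty sample sets")
    return float(
        np.mean(
            [min(s.aligned_dmae(ref, gen) for gen in s.s_gen) for ref in s.s_ref]
        )
    )


def deduplicate(
    samples: list[Conformation],
    graph: ReactionGraph,
    threshold: float = 0.01,
) -> list[list[int]]:
    """Cluster geometries that agree within ``threshold`` aligned D-MAE.

    Single-linkage: clusters are the connected components of the pairwise
    at-or-below-threshold graph, so the result is independent of input order
    up to cluster labeling; clusters are returned ordered by their smallest
    member index.
    """
    n = len(samples)
    if n == 0:
        return []
    ss = SampleSet(s_gen=[], s_ref=[], graph=graph, delta=max(threshold, 1e-12))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if ss.aligned_dmae(samples[i], samples[j]) <= threshold:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def conformer_match(
    gen: Conformation,
    refs: list[Conformation],
    graph: ReactionGraph,
    threshold: float = 0.01,
) -> int | None:
    """Index of the reference matching ``gen`` within ``threshold`` (< strict).

    Among references inside the threshold the smallest aligned D-MAE wins,
    ties broken by the lower index; ``None`` if no reference is close enough.
    """
    ss = SampleSet(s_gen=[], s_ref=[], graph=graph, delta=max(threshold, 1e-12))
    best: tuple[float, int] | None = None
    for k, ref in enumerate(refs):
        d = ss.aligned_dmae(ref, gen)
        if d < threshold and (best is None or d < best[0]):
            best = (d, k)
    return None if best is None else best[1]
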