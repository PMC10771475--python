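"""Score network: geometric graphs, symmetry properties, checkpointing."""

import numpy as np
import pytest

from conftest import random_rotation
from tsdiff.denoiser import (
    DegenerateGeometryError,
    DenoiserModel,
    ModelConfig,
    build_geometric_graph,
    edge_to_atom_scores,
    load_checkpoint,
    rbf_expand,
    save_checkpoint,
    time_embedding,
)


@pytest.fixture(scope="module")
def small_model():
    cfg = ModelConfig(hidden=32, n_layers=2, n_rbf=16, node_feat_dim=26, edge_feat_dim=16)
    return DenoiserModel(cfg, np.random.default_rng(0))


# -- featurization -------------------------------------------------------------


def test_rbf_expand():
    out = rbf_expand(np.array([0.0, 5.0, 10.0]), n_rbf=8, rbf_max=10.0)
    assert out.shape == (3, 8)
    assert out[0, 0] == pytest.approx(1.0)  # d=0 on the first center
    assert np.all(out > 0) and np.all(out <= 1)


def test_time_embedding():
    e = time_embedding(np.array([1, 7, 7]), dim=8)
    assert e.shape == (3, 8)
    assert np.allclose(e[1], e[2])
    assert not np.allclose(e[0], e[1])
    assert np.all(np.abs(e) <= 1.0)


# -- geometric graph -----------------------------------------------------------


def test_geometric_graph_keeps_reaction_edges(methanol_co):
    g, c0 = methanol_co
    far = c0.copy()
    far[1] += 50.0  # O moved far away: graph edges persist, no radius edges to it
    gg = build_geometric_graph(g, far, t=1, cutoff=5.0)
    pairs = {tuple(e) for e in gg.edge_index}
    assert set(g.edges) <= pairs


def test_geometric_graph_radius_edges_zero_featured(ethane):
    g, c0 = ethane
    gg = build_geometric_graph(g, c0, t=1, cutoff=10.0)
    graph_pairs = set(g.edges)
    extra = [k for k, e in enumerate(gg.edge_index) if tuple(e) not in graph_pairs]
    # ethane within 3 hops is complete, unless a pair is >3 hops: check both ways
    for k in extra:
        assert np.allclose(gg.edge_features[k], 0.0)
    assert gg.distances.shape == (len(gg.edge_index),)
    i, j = gg.edge_index[:, 0], gg.edge_index[:, 1]
    assert np.allclose(gg.distances, np.linalg.norm(c0[i] - c0[j], axis=1))


def test_geometric_graph_rejects_coincident_atoms(methanol_co):
    g, c0 = methanol_co
    bad = c0.copy()
    bad[2] = bad[3]
    with pytest.raises(DegenerateGeometryError):
        build_geometric_graph(g, bad, t=1)


def test_geometric_graph_shape_check(methanol_co):
    g, c0 = methanol_co
    with pytest.raises(ValueError):
        build_geometric_graph(g, c0[:-1], t=1)
    with pytest.raises(ValueError):
        build_geometric_graph(g, c0, t=1, cutoff=0.0)


# -- symmetry ------------------------------------------------------------------


def test_edge_scores_invariant_eps_equivariant(small_model, methanol_co):
    g, c0 = methanol_co
    rng = np.random.default_rng(11)
    c = c0 + 0.1 * rng.standard_normal(c0.shape)
    gg = build_geometric_graph(g, c, t=5)
    s0 = small_model.predict_edge_scores(gg)
    e0 = small_model.eps_theta(gg)
    for _ in range(10):
        r = random_rotation(rng)
        tvec = rng.standard_normal(3) * 10
        c2 = c @ r.T + tvec
        gg2 = build_geometric_graph(g, c2, t=5)
        assert np.allclose(small_model.predict_edge_scores(gg2), s0, atol=1e-9)
        assert np.allclose(small_model.eps_theta(gg2), e0 @ r.T, atol=1e-9)
    # reflection: edge scores depend on distances only, so still invariant
    refl = c * np.array([-1.0, 1.0, 1.0])
    gg3 = build_geometric_graph(g, refl, t=5)
    assert np.allclose(small_model.predict_edge_scores(gg3), s0, atol=1e-9)


def test_eps_theta_sums_to_zero(small_model, ethane):
    g, c0 = ethane
    gg = build_geometric_graph(g, c0, t=3)
    eps = small_model.eps_theta(gg)
    assert eps.shape == (g.n_atoms, 3)
    assert np.allclose(eps.sum(axis=0), 0.0, atol=1e-10)


def test_edge_head_is_symmetric(small_model, methanol_co):
    # flipping every edge orientation must not change the scores
    g, c0 = methanol_co
    gg = build_geometric_graph(g, c0, t=2)
    s = small_model.edge_scores(
        g.node_features, gg.edge_index, gg.edge_features, gg.distances,
        np.full(g.n_atoms, 2),
    ).value
    flipped = gg.edge_index[:, ::-1].copy()
    s2 = small_model.edge_scores(
        g.node_features, flipped, gg.edge_features, gg.distances,
        np.full(g.n_atoms, 2),
    ).value
    assert np.allclose(s, s2, atol=1e-10)


def test_chain_rule_matches_pseudo_energy_gradient(methanol_co):
    """Projecting s_ij = (d_ij - r_ij) equals the analytic gradient of the
    quadratic distance pseudo-energy E = 0.5 sum (d_ij - r_ij)^2."""
    g, c0 = methanol_co
    rng = np.random.default_rng(4)
    c = c0 + 0.05 * rng.standard_normal(c0.shape)
    gg = build_geometric_graph(g, c, t=1)
    r_ref = gg.distances - rng.uniform(0.1, 0.3, size=len(gg.distances))
    s = gg.distances - r_ref
    grad = edge_to_atom_scores(s, gg)

    def energy(x):
        i, j = gg.edge_index[:, 0], gg.edge_index[:, 1]
        d = np.linalg.norm(x[i] - x[j], axis=1)
        return 0.5 * np.sum((d - r_ref) ** 2)

    h = 1e-6
    num = np.zeros_like(c)
    for idx in np.ndindex(c.shape):
        xp, xm = c.copy(), c.copy()
        xp[idx] += h
        xm[idx] -= h
        num[idx] = (energy(xp) - energy(xm)) / (2 * h)
    assert np.allclose(grad, num, atol=1e-6)


def test_edge_to_atom_scores_validates(small_model, methanol_co):
    g, c0 = methanol_co
    gg = build_geometric_graph(g, c0, t=1)
    with pytest.raises(ValueError):
        edge_to_atom_scores(np.zeros(len(gg.edge_index) + 1), gg)


# -- checkpointing -------------------------------------------------------------


def test_checkpoint_round_trip(tmp_path, small_model, methanol_co):
    g, c0 = methanol_co
    path = tmp_path / "model.npz"
    save_checkpoint(path, small_model, extra={"note": "unit"})
    loaded = load_checkpoint(path)
    assert loaded.config == small_model.config
    gg = build_geometric_graph(g, c0, t=4)
    assert np.allclose(loaded.eps_theta(gg), small_model.eps_theta(gg))


def test_checkpoint_hash_guard(tmp_path, small_model):
    import json

    path = tmp_path / "model.npz"
    save_checkpoint(path, small_model)
    data = dict(np.load(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    meta["config"]["hidden"] = 999  # tamper without refreshing the hash
    data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **data)
    with pytest.raises(ValueError, match="hash"):
        load_checkpoint(path)
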