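"""Ensemble metrics: D-MAE, alignment, COV/MAT, deduplication."""

import itertools

import numpy as np
import pytest

from conftest import random_rotation
from tsdiff.metrics import (
    SampleSet,
    conformer_match,
    coverage,
    deduplicate,
    dmae,
    graph_automorphisms,
    matching,
)


def brute_force_aligned_dmae(c, c_hat, graph):
    """Exhaustive minimum of raw D-MAE over all permutations that preserve
    node features and the full condensed-graph edge features."""
    n = graph.n_atoms
    classes: dict[tuple, list[int]] = {}
    for i in range(n):
        classes.setdefault(tuple(graph.node_features[i]), []).append(i)
    edge_map = {
        tuple(e): tuple(graph.edge_features[k]) for k, e in enumerate(graph.edges)
    }

    def edge_key(i, j):
        return edge_map.get((min(i, j), max(i, j)))

    best = np.inf
    members = list(classes.values())
    for parts in itertools.product(*(itertools.permutations(m) for m in members)):
        perm = np.empty(n, dtype=np.int64)
        for orig, new in zip(members, parts):
            for a, b in zip(orig, new):
                perm[a] = b
        ok = all(
            edge_key(i, j) == edge_key(perm[i], perm[j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        if ok:
            best = min(best, dmae(c, np.asarray(c_hat)[perm]))
    return best


def test_dmae_hand_example(methanol_co):
    # collinear points at 0,1,2 vs 0,1,3: distance errors (0, 1, 1) -> 2/3
    a = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    b = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
    assert dmae(a, b) == pytest.approx(2.0 / 3.0)
    assert dmae(a, a) == 0.0


def test_dmae_rigid_motion_invariant(methanol_co):
    g, c0 = methanol_co
    rng = np.random.default_rng(0)
    other = c0 + 0.3 * rng.standard_normal(c0.shape)
    moved = other @ random_rotation(rng).T + rng.standard_normal(3) * 4
    assert dmae(c0, moved) == pytest.approx(dmae(c0, other), abs=1e-10)


def test_dmae_validation(methanol_co):
    g, c0 = methanol_co
    with pytest.raises(ValueError):
        dmae(c0, c0[:-1])
    with pytest.raises(ValueError, match="graph"):
        dmae(c0, c0, align=True)


def test_automorphisms_include_identity_and_preserve_elements(ethane):
    g, _ = ethane
    autos = graph_automorphisms(g)
    assert any(np.array_equal(p, np.arange(g.n_atoms)) for p in autos)
    for p in autos:
        assert np.array_equal(g.atomic_nums[p], g.atomic_nums)
    # ethane: each methyl's 3 H interchange and the two CH3 groups swap
    assert len(autos) == 2 * 6 * 6


def test_aligned_dmae_methyl_rotation(methanol_co):
    # rotating a methyl group's hydrogens is invisible after alignment
    g, c0 = methanol_co
    rotated = c0.copy()
    # map ids 3,4,5 are the C hydrogens (indices 2,3,4)
    rotated[[2, 3, 4]] = rotated[[3, 4, 2]]
    assert dmae(c0, rotated) > 1e-3  # raw metric sees the relabeling
    assert dmae(c0, rotated, align=True, graph=g) == pytest.approx(0.0, abs=1e-12)


def test_aligned_dmae_matches_brute_force(templates_by_id):
    rng = np.random.default_rng(12)
    for t in templates_by_id.values():
        g = t.graph()
        for _ in range(5):
            c = t.geometry(0) + 0.3 * rng.standard_normal((g.n_atoms, 3))
            c_hat = t.geometry(0) + 0.3 * rng.standard_normal((g.n_atoms, 3))
            got = dmae(c, c_hat, align=True, graph=g)
            want = brute_force_aligned_dmae(c, c_hat, g)
            assert got == pytest.approx(want, abs=1e-12)


def _noisy_set(template, n_gen, n_ref, rng, spread=0.05):
    g = template.graph()
    base = template.geometry(0)
    gen = [base + spread * rng.standard_normal(base.shape) for _ in range(n_gen)]
    ref = [base + spread * rng.standard_normal(base.shape) for _ in range(n_ref)]
    return g, gen, ref


def test_coverage_monotone_in_delta(templates_by_id):
    t = templates_by_id["methanol_co_cleavage"]
    rng = np.random.default_rng(3)
    g, gen, ref = _noisy_set(t, 4, 6, rng, spread=0.08)
    covs = [
        coverage(SampleSet(s_gen=gen, s_ref=ref, graph=g, delta=d))
        for d in (0.01, 0.05, 0.1, 0.2, 0.5)
    ]
    assert covs == sorted(covs)
    assert covs[-1] == 100.0


def test_matching_non_increasing_in_samples(templates_by_id):
    t = templates_by_id["ethane_homolysis"]
    rng = np.random.default_rng(9)
    g, gen, ref = _noisy_set(t, 8, 3, rng)
    mats = [
        matching(SampleSet(s_gen=gen[:k], s_ref=ref, graph=g))
        for k in range(1, len(gen) + 1)
    ]
    assert all(b <= a + 1e-12 for a, b in zip(mats, mats[1:]))


def test_coverage_edge_cases(methanol_co):
    g, c0 = methanol_co
    s = SampleSet(s_gen=[], s_ref=[c0], graph=g, delta=0.1)
    assert coverage(s) == 0.0
    with pytest.raises(ValueError):
        coverage(SampleSet(s_gen=[c0], s_ref=[], graph=g, delta=0.1))
    with pytest.raises(ValueError):
        matching(SampleSet(s_gen=[], s_ref=[c0], graph=g, delta=0.1))
    with pytest.raises(ValueError):
        SampleSet(s_gen=[c0], s_ref=[c0], graph=g, delta=0.0)
    with pytest.raises(ValueError):
        SampleSet(s_gen=[c0[:-1]], s_ref=[c0], graph=g, delta=0.1)


def test_deduplicate_clusters(templates_by_id):
    t = templates_by_id["methanol_co_cleavage"]
    g = t.graph()
    a = t.geometry(0)
    b = t.geometry(1)
    rng = np.random.default_rng(1)
    tiny = 0.001 * rng.standard_normal(a.shape)
    clusters = deduplicate([a, b, a + tiny, b.copy()], g, threshold=0.01)
    assert clusters == [[0, 2], [1, 3]]
    assert deduplicate([], g) == []


def test_deduplicate_single_linkage_chain(methanol_co):
    # a-b within threshold and b-c within threshold chain into one cluster
    g, c0 = methanol_co
    step = np.zeros_like(c0)
    step[0, 0] = 0.045  # consecutive pairs within threshold, endpoints beyond
    chain = [c0, c0 + step, c0 + 2 * step]
    assert len(deduplicate([chain[0], chain[2]], g, threshold=0.01)) == 2
    clusters = deduplicate(chain, g, threshold=0.01)
    assert len(clusters) == 1


def test_conformer_match(templates_by_id):
    t = templates_by_id["ethane_homolysis"]
    g = t.graph()
    refs = [t.geometry(k) for k in range(3)]
    assert conformer_match(refs[1].copy(), refs, g) == 1
    far = refs[0] + 1.0
    far[0] += 5.0
    assert conformer_match(far, refs, g) is None
    # strict threshold: exactly-at-threshold distance does not match
    assert conformer_match(refs[2], refs, g, threshold=1e-15) == 2  # exact copy: d = 0 < eps
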