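"""Condensed reaction graph construction, features and serialization."""

import numpy as np
import pytest

from tsdiff.rxn_graph import (
    BOND_TYPES,
    EDGE_FEATURE_DIM,
    AtomMappingError,
    MolGraph,
    ReactionGraph,
    ReactionParseError,
    build_condensed_graph,
    count_connectivity_changes,
    khop_extend,
    parse_reaction,
    read_reaction_file,
)

H2O_SPLIT = "[O:1]([H:2])[H:3]>>[O:1][H:2].[H:3]"


def test_parse_node_order_is_map_order():
    r, p = parse_reaction(H2O_SPLIT)
    assert [a.atomic_num for a in r.atoms] == [8, 1, 1]
    assert [a.map_id for a in r.atoms] == [1, 2, 3]
    assert r.bond_set() == {(0, 1), (0, 2)}
    assert p.bond_set() == {(0, 1)}


def test_parse_auto_maps_implicit_hydrogens():
    # methane written without explicit H: the 4 hydrogens get map ids 2..5
    r, p = parse_reaction("[CH4:1]>>[CH4:1]")
    assert r.n_atoms == 5
    assert sorted(a.map_id for a in r.atoms) == [1, 2, 3, 4, 5]
    assert [a.atomic_num for a in r.atoms] == [6, 1, 1, 1, 1]
    assert r.bond_set() == p.bond_set() == {(0, k) for k in range(1, 5)}


@pytest.mark.parametrize(
    "bad",
    [
        "not a reaction",
        "[O:1][H:2]",  # no >>
        "C>>C",  # unmapped heavy atoms
        "[O:1]([H:2])[H:2]>>[O:1][H:2].[H:2]",  # duplicate map id
        "[O:1]([H:2])[H:3]>>[N:1]([H:2])[H:3]",  # element change under one map id
        "[C:1]([H:2])([H:3])([H:4])[H:5]>>[C:1]([H:2])[H:3]",  # unbalanced
    ],
)
def test_parse_rejects_malformed(bad):
    with pytest.raises((ReactionParseError, AtomMappingError)):
        parse_reaction(bad)


def test_parse_rejects_explicit_unmapped_h():
    with pytest.raises(AtomMappingError):
        parse_reaction("[O:1]([H])[H:2]>>[O:1]([H])[H:2]")


def test_khop_extend_path_graph():
    # linear chain 0-1-2-3-4: exact shortest-path distances up to 3 hops
    from tsdiff.rxn_graph import Atom

    g = MolGraph(
        atoms=[Atom(atomic_num=6, map_id=k + 1) for k in range(5)],
        bonds=[(k, k + 1, "SINGLE") for k in range(4)],
    )
    ext = khop_extend(g, k=3)
    assert (0, 1, 1) in ext and (0, 2, 2) in ext and (0, 3, 3) in ext
    assert all(not (i == 0 and j == 4) for i, j, _ in ext)  # 4 hops: excluded


def test_khop_no_cross_component_pairs():
    from tsdiff.rxn_graph import Atom

    g = MolGraph(
        atoms=[Atom(atomic_num=6, map_id=k + 1) for k in range(4)],
        bonds=[(0, 1, "SINGLE"), (2, 3, "SINGLE")],
    )
    ext = khop_extend(g)
    assert ext == {(0, 1, 1), (2, 3, 1)}


def test_edge_features_one_hot_structure():
    g = build_condensed_graph(*parse_reaction(H2O_SPLIT))
    assert g.edge_features.shape[1] == 2 * EDGE_FEATURE_DIM
    for row, (i, j) in zip(g.edge_features, g.edges):
        for half in (row[:EDGE_FEATURE_DIM], row[EDGE_FEATURE_DIM:]):
            bond_block, dist_block = half[: len(BOND_TYPES) + 1], half[len(BOND_TYPES) + 1 :]
            if np.allclose(half, 0.0):
                continue  # pair absent from this side
            assert bond_block.sum() == 1.0  # exactly one bond slot (incl. "none")
            assert dist_block.sum() == 1.0  # exactly one graph-distance slot


def test_edge_union_covers_both_sides():
    g = build_condensed_graph(*parse_reaction(H2O_SPLIT))
    pairs = set(g.edges)
    # H2-H3 are 2 hops apart on the reactant side only
    assert (1, 2) in pairs
    row = g.edge_features[g.edges.index((1, 2))]
    assert not np.allclose(row[:EDGE_FEATURE_DIM], 0.0)  # present in reactant
    assert np.allclose(row[EDGE_FEATURE_DIM:], 0.0)  # absent in product


def test_swap_sides_is_involution(methanol_co):
    g, _ = methanol_co
    gg = g.swap_sides().swap_sides()
    assert np.allclose(gg.node_features, g.node_features)
    assert np.allclose(gg.edge_features, g.edge_features)
    assert gg.edges == g.edges


def test_swap_sides_swaps_halves(methanol_co):
    g, _ = methanol_co
    s = g.swap_sides()
    f = g.node_features.shape[1] // 2
    assert np.allclose(s.node_features[:, :f], g.node_features[:, f:])
    assert np.allclose(s.node_features[:, f:], g.node_features[:, :f])


def test_connectivity_changes():
    r, p = parse_reaction(H2O_SPLIT)
    assert count_connectivity_changes(r, p) == 1  # one O-H broken
    r, p = parse_reaction(
        "[C:1]([H:2])([H:3])([H:4])[O:5][H:6]>>[C:1]([H:3])([H:4])=[O:5].[H:2][H:6]"
    )
    # C-H2 broken, O-H6 broken, H2-H6 formed; C-O order change does not count
    assert count_connectivity_changes(r, p) == 3


def test_json_round_trip(methanol_co):
    g, _ = methanol_co
    g2 = ReactionGraph.from_json(g.to_json())
    assert g2.n_atoms == g.n_atoms
    assert np.allclose(g2.node_features, g.node_features)
    assert np.allclose(g2.edge_features, g.edge_features)
    assert g2.edges == g.edges
    assert g2.reactant.bonds == g.reactant.bonds


def test_json_rejects_unknown_schema(methanol_co):
    g, _ = methanol_co
    with pytest.raises(ValueError, match="schema"):
        ReactionGraph.from_json(g.to_json().replace("reaction_graph/1", "x/9"))


def test_read_reaction_file(tmp_path):
    p = tmp_path / "r.smi"
    p.write_text(
        "# comment\n"
        "rxn_a\t[O:1]([H:2])[H:3]>>[O:1][H:2].[H:3]\n"
        "\n"
        "[C:1]>>[C:1]\n"
    )
    recs = read_reaction_file(p)
    assert recs == [
        ("rxn_a", "[O:1]([H:2])[H:3]>>[O:1][H:2].[H:3]"),
        ("4", "[C:1]>>[C:1]"),
    ]


def test_spectator_warning():
    with pytest.warns(UserWarning, match="spectator"):
        parse_reaction(
            "[O:1]([H:2])[H:3].[C:4]>>[O:1][H:2].[H:3].[C:4]"
        )
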