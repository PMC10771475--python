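"""Condensed reaction graphs from atom-mapped reaction SMILES/SMARTS.

A reaction ``reactants>>products`` with a complete atom mapping defines two
molecular graphs over the same atom set.  Concatenating reactant-side and
product-side node/edge features through the atom mapping yields a single
*condensed reaction graph*: the sole conditioning input of the generative
model.  Edges are extended to all atom pairs within a 3-hop graph distance
on either side, with the graph distance one-hot encoded; a pair present on
only one side carries that side's all-zero feature vector.

Hydrogens are explicit nodes throughout: generated geometries are full 3D
structures, so the graph must carry every atom.  Node order is atom-map
order (node ``k`` holds map id ``k + 1``), which aligns the two sides by
construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "MolGraph",
    "ReactionGraph",
    "ReactionParseError",
    "AtomMappingError",
    "parse_reaction",
    "khop_extend",
    "build_condensed_graph",
    "count_connectivity_changes",
    "read_reaction_file",
]


class ReactionParseError(ValueError):
    """The reaction string is not parseable SMILES/SMARTS."""


class AtomMappingError(ValueError):
    """The atom mapping is missing, duplicated, or unbalanced."""


# -- feature vocabularies -----------------------------------------------------

#: Elements covered by the one-hot atomic-number block; extend for new chemistry.
ELEMENTS: tuple[int, ...] = (1, 6, 7, 8)  # H, C, N, O

HYBRIDIZATIONS: tuple[str, ...] = ("SP", "SP2", "SP3", "OTHER")

BOND_TYPES: tuple[str, ...] = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")

#: One-hot slots per side for an edge: 4 bond types + "no bond" + 3 graph distances.
EDGE_FEATURE_DIM: int = len(BOND_TYPES) + 1 + 3

_RDKIT_BOND = {
    "SINGLE": "SINGLE",
    "DOUBLE": "DOUBLE",
    "TRIPLE": "TRIPLE",
    "AROMATIC": "AROMATIC",
}


@dataclass(frozen=True)
class Atom:
    """One atom record; ``map_id`` is the 1-based atom-map number."""

    atomic_num: int
    map_id: int
    aromatic: bool = False
    formal_charge: int = 0
    hybridization: str = "SP3"
    valency: int = 0
    chirality: bool = False  # parity flag: any specified chiral tag
    in_ring: bool = False


@dataclass
class MolGraph:
    """One side of a reaction: atoms plus covalent bonds, in atom-map order."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, str]]  # (i, j, bond type), i < j, node indices

    def __post_init__(self) -> None:
        maps = [a.map_id for a in self.atoms]
        if len(set(maps)) != len(maps):
            raise AtomMappingError("duplicate atom-map ids within one side")
        for i, j, bt in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on node {i}")
            if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
                raise ValueError(f"bond ({i}, {j}) out of range")
            if bt not in BOND_TYPES:
                raise ValueError(f"unknown bond type {bt!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bond_set(self) -> set[tuple[int, int]]:
        """Unordered 1-hop connectivity, ignoring bond order."""
        return {(min(i, j), max(i, j)) for i, j, _ in self.bonds}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def node_feature(self, i: int) -> np.ndarray:
        """Per-atom feature vector for one side of the condensed graph."""
        a = self.atoms[i]
        elem = np.zeros(len(ELEMENTS))
        if a.atomic_num in ELEMENTS:
            elem[ELEMENTS.index(a.atomic_num)] = 1.0
        hyb = np.zeros(len(HYBRIDIZATIONS))
        key = a.hybridization if a.hybridization in HYBRIDIZATIONS else "OTHER"
        hyb[HYBRIDIZATIONS.index(key)] = 1.0
        scalars = np.array(
            [
                float(a.valency),
                float(a.formal_charge),
                float(a.aromatic),
                float(a.in_ring),
                float(a.chirality),
            ]
        )
        return np.concatenate([elem, hyb, scalars])


def _side_edge_feature(bond_type: str | None, graph_distance: int) -> np.ndarray:
    """One side's edge feature: bond-type one-hot (incl. 'none') + distance one-hot.

    The all-zero vector is reserved for pairs absent from this side (and for
    radius edges in the geometric graph), so every in-graph pair sets exactly
    one bond slot — ``none`` for extended non-bonded pairs.
    """
    v = np.zeros(EDGE_FEATURE_DIM)
    if bond_type is None:
        v[len(BOND_TYPES)] = 1.0
    else:
        v[BOND_TYPES.index(bond_type)] = 1.0
    if not 1 <= graph_distance <= 3:
        raise ValueError(f"graph distance {graph_distance} outside 1..3")
    v[len(BOND_TYPES) + 1 + (graph_distance - 1)] = 1.0
    return v


@dataclass
class ReactionGraph:
    """Condensed 2D reaction graph: union of 3-hop-extended sides, features concatenated.

    ``edge_features`` rows are ``[reactant half | product half]`` aligned with
    ``edges``; an all-zero half marks a pair absent from that side.
    """

    n_atoms: int
    atomic_nums: np.ndarray  # (N,) int
    node_features: np.ndarray  # (N, 2 * F_node)
    edges: list[tuple[int, int]]  # unordered pairs, i < j, sorted
    edge_features: np.ndarray  # (E, 2 * EDGE_FEATURE_DIM)
    reactant: MolGraph = field(repr=False)
    product: MolGraph = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index(self) -> np.ndarray:
        """(E, 2) integer array of the edge list."""
        return np.array(self.edges, dtype=np.int64).reshape(-1, 2)

    def swap_sides(self) -> "ReactionGraph":
        """The reverse reaction: swap the R/P halves of every feature.

        The edge set is unchanged (union is symmetric); used for training-set
        augmentation with reverse reactions.
        """
        f = self.node_features.shape[1] // 2
        e = self.edge_features.shape[1] // 2
        return ReactionGraph(
            n_atoms=self.n_atoms,
            atomic_nums=self.atomic_nums.copy(),
            node_features=np.concatenate(
                [self.node_features[:, f:], self.node_features[:, :f]], axis=1
            ),
            edges=list(self.edges),
            edge_features=np.concatenate(
                [self.edge_features[:, e:], self.edge_features[:, :e]], axis=1
            ),
            reactant=self.product,
            product=self.reactant,
        )

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        def _mol(m: MolGraph) -> dict:
            return {
                "atoms": [vars(a) for a in m.atoms],
                "bonds": [[i, j, t] for i, j, t in m.bonds],
            }

        return json.dumps(
            {
                "schema": "tsdiff.reaction_graph/1",
                "n_atoms": self.n_atoms,
                "atomic_nums": self.atomic_nums.tolist(),
                "node_features": self.node_features.tolist(),
                "edges": [[i, j] for i, j in self.edges],
                "edge_features": self.edge_features.tolist(),
                "reactant": _mol(self.reactant),
                "product": _mol(self.product),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionGraph":
        d = json.loads(text)
        if d.get("schema") != "tsdiff.reaction_graph/1":
            raise ValueError(f"unknown schema {d.get('schema')!r}")

        def _mol(md: dict) -> MolGraph:
            return MolGraph(
                atoms=[Atom(**a) for a in md["atoms"]],
                bonds=[(i, j, t) for i, j, t in md["bonds"]],
            )

        return cls(
            n_atoms=d["n_atoms"],
            atomic_nums=np.array(d["atomic_nums"], dtype=np.int64),
            node_features=np.array(d["node_features"], dtype=np.float64),
            edges=[(i, j) for i, j in d["edges"]],
            edge_features=np.array(d["edge_features"], dtype=np.float64),
            reactant=_mol(d["reactant"]),
            product=_mol(d["product"]),
        )


# -- parsing ------------------------------------------------------------------


def _mol_from_side(smiles: str, side: str) -> Chem.Mol:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ReactionParseError(f"cannot parse {side} side: {smiles!r}")
    return mol


def _expand_hydrogens(mol: Chem.Mol, side: str) -> Chem.Mol:
    """Make implicit hydrogens explicit and auto-map them.

    Explicitly written hydrogens must already carry map numbers (a written-but
    -unmapped H is ambiguous and rejected).  Implicit hydrogens are expanded
    and numbered deterministically: for each mapped heavy atom in map order,
    its new hydrogens take consecutive free map ids.  Both sides expand the
    same way, so equal per-heavy-atom H counts yield a consistent bijection.
    """
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1 and atom.GetAtomMapNum() == 0:
            raise AtomMappingError(f"{side} side has an explicit H without a map number")
        if atom.GetAtomicNum() != 1 and atom.GetAtomMapNum() == 0:
            raise AtomMappingError(f"{side} side has an unmapped heavy atom")
    mol = Chem.AddHs(mol)
    used = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}
    next_id = 1
    heavy = sorted(
        (a for a in mol.GetAtoms() if a.GetAtomicNum() != 1),
        key=lambda a: a.GetAtomMapNum(),
    )
    for h_parent in heavy:
        for nbr in h_parent.GetNeighbors():
            if nbr.GetAtomicNum() == 1 and nbr.GetAtomMapNum() == 0:
                while next_id in used:
                    next_id += 1
                nbr.SetAtomMapNum(next_id)
                used.add(next_id)
    return mol


def _mol_to_graph(mol: Chem.Mol, side: str) -> MolGraph:
    maps = [a.GetAtomMapNum() for a in mol.GetAtoms()]
    if len(set(maps)) != len(maps):
        raise AtomMappingError(f"duplicate atom-map ids on {side} side")
    if sorted(maps) != list(range(1, len(maps) + 1)):
        raise AtomMappingError(
            f"{side} side map ids are not a contiguous 1..N set: {sorted(maps)}"
        )
    order = np.argsort(maps)  # node k <- atom with map k+1
    idx_of = {int(order[k]): k for k in range(len(order))}
    atoms: list[Atom] = []
    for k in range(len(order)):
        a = mol.GetAtomWithIdx(int(order[k]))
        hyb = str(a.GetHybridization())
        atoms.append(
            Atom(
                atomic_num=a.GetAtomicNum(),
                map_id=k + 1,
                aromatic=a.GetIsAromatic(),
                formal_charge=a.GetFormalCharge(),
                hybridization=hyb if hyb in HYBRIDIZATIONS else "OTHER",
                valency=a.GetTotalValence(),
                chirality=str(a.GetChiralTag()) != "CHI_UNSPECIFIED",
                in_ring=a.IsInRing(),
            )
        )
    bonds: list[tuple[int, int, str]] = []
    for b in mol.GetBonds():
        i = idx_of[b.GetBeginAtomIdx()]
        j = idx_of[b.GetEndAtomIdx()]
        bt = str(b.GetBondType())
        if bt not in BOND_TYPES:
            raise ReactionParseError(f"unsupported bond type {bt!r} on {side} side")
        bonds.append((min(i, j), max(i, j), bt))
    bonds.sort()
    return MolGraph(atoms=atoms, bonds=bonds)


def parse_reaction(rxn_string: str) -> tuple[MolGraph, MolGraph]:
    """Parse an atom-mapped ``reactants>>products`` string into two aligned graphs.

    Node order on both sides is atom-map order, so node ``k`` is the same
    physical atom throughout the reaction.  Implicit hydrogens are expanded
    and auto-mapped (see :func:`_expand_hydrogens`); the element multiset must
    match between sides.
    """
    parts = rxn_string.strip().split(">>")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ReactionParseError(
            f"expected 'reactants>>products', got {rxn_string!r}"
        )
    mols = []
    for smiles, side in zip(parts, ("reactant", "product")):
        mol = _mol_from_side(smiles, side)
        mol = _expand_hydrogens(mol, side)
        mols.append(_mol_to_graph(mol, side))
    r, p = mols
    if r.n_atoms != p.n_atoms:
        raise AtomMappingError(
            f"atom count differs: {r.n_atoms} reactant vs {p.n_atoms} product"
        )
    for ar, ap in zip(r.atoms, p.atoms):
        if ar.atomic_num != ap.atomic_num:
            raise AtomMappingError(
                f"map id {ar.map_id} is element {ar.atomic_num} in reactant "
                f"but {ap.atomic_num} in product"
            )
    if count_connectivity_changes(r, p) == 0 and r.bonds != p.bonds:
        pass  # bond-order-only change: legal, nothing to flag
    _warn_spectators(r, p)
    return r, p


def _warn_spectators(r: MolGraph, p: MolGraph) -> None:
    """Warn on molecules whose bonds are identical on both sides (spectators)."""
    changed = r.bond_set() ^ p.bond_set()
    touched = {i for ij in changed for i in ij}
    for comp in nx.connected_components(r.to_networkx()):
        if r.n_atoms > 1 and not comp & touched and len(changed) > 0:
            warnings.warn(
                "reaction contains a non-reactive spectator molecule; its "
                "graph embedding carries no reaction signal",
                stacklevel=3,
            )
            return


# -- graph operations ---------------------------------------------------------


def khop_extend(g: MolGraph, k: int = 3) -> set[tuple[int, int, int]]:
    """All unordered atom pairs within graph distance ``k`` over covalent bonds.

    Returns ``{(i, j, d)}`` with ``i < j`` and ``d`` the shortest-path length,
    computed per connected component (no cross-component pairs).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nxg = g.to_networkx()
    out: set[tuple[int, int, int]] = set()
    for src, dists in nx.all_pairs_shortest_path_length(nxg, cutoff=k):
        for dst, d in dists.items():
            if src < dst and d >= 1:
                out.add((src, dst, d))
    return out


def build_condensed_graph(r: MolGraph, p: MolGraph) -> ReactionGraph:
    """Combine two aligned sides into the condensed reaction graph.

    Edge set: union of both sides' 3-hop extensions.  Each edge feature is the
    concatenation of per-side vectors (bond type incl. "none" + graph
    distance); a pair outside one side's 3-hop neighbourhood carries that
    side's zero vector.
    """
    if r.n_atoms != p.n_atoms:
        raise AtomMappingError("sides have different atom counts")
    for ar, ap in zip(r.atoms, p.atoms):
        if ar.map_id != ap.map_id or ar.atomic_num != ap.atomic_num:
            raise AtomMappingError("sides are not atom-map aligned")

    n = r.n_atoms
    node_features = (
        np.stack([np.concatenate([r.node_feature(i), p.node_feature(i)]) for i in range(n)])
        if n
        else np.zeros((0, 0))
    )
    r_bonds = {(i, j): t for i, j, t in r.bonds}
    p_bonds = {(i, j): t for i, j, t in p.bonds}
    r_ext = {(i, j): d for i, j, d in khop_extend(r)}
    p_ext = {(i, j): d for i, j, d in khop_extend(p)}
    edges = sorted(set(r_ext) | set(p_ext))
    feats = np.zeros((len(edges), 2 * EDGE_FEATURE_DIM))
    for row, (i, j) in enumerate(edges):
        if (i, j) in r_ext:
            feats[row, :EDGE_FEATURE_DIM] = _side_edge_feature(
                r_bonds.get((i, j)), r_ext[(i, j)]
            )
        if (i, j) in p_ext:
            feats[row, EDGE_FEATURE_DIM:] = _side_edge_feature(
                p_bonds.get((i, j)), p_ext[(i, j)]
            )
    return ReactionGraph(
        n_atoms=n,
        atomic_nums=np.array([a.atomic_num for a in r.atoms], dtype=np.int64),
        node_features=node_features,
        edges=edges,
        edge_features=feats,
        reactant=r,
        product=p,
    )


def count_connectivity_changes(r: MolGraph, p: MolGraph) -> int:
    """Number of bonds broken plus bonds formed, ignoring bond-order changes."""
    return len(r.bond_set() ^ p.bond_set())


def read_reaction_file(path) -> list[tuple[str, str]]:
    """Read a ``.smi``-style file: one reaction per line, optional leading
    tab-separated id column.  Returns ``[(id, reaction_string)]``; blank lines
    and ``#`` comments are skipped and missing ids become line numbers.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                rid, rxn = line.split("\t", 1)
            else:
                rid, rxn = str(lineno), line
            records.append((rid.strip(), rxn.strip()))
    return records
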