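"""Synthetic toy reactions with reproducible 3D reference geometries.

Real training data pairs an atom-mapped gas-phase reaction with one
DFT-optimized transition-state geometry.  The toy generator emulates that
signal at desk scale: a handful of templated bond-cleavage reactions over
C, H, O, N (each ≤ 10 atoms), whose "transition-state" geometries are built
internally from idealized bond lengths and angles — no chemistry engine, so
the fixtures are dependency-free and bit-reproducible.

Each template owns several conformational *modes* (different extensions of
the breaking bond, i.e. early vs late transition states, plus torsional
variants).  Modes are kept ≥ 0.3 Å apart in aligned D-MAE so that coverage,
matching, and deduplication are all exercised meaningfully; per-sample
positional noise stays well below a third of that separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import Conformation
from .rxn_graph import ReactionGraph, build_condensed_graph, parse_reaction

__all__ = [
    "Template",
    "ToyRecord",
    "TEMPLATES",
    "template_modes",
    "make_toy_dataset",
    "split_dataset",
    "augment_reverse",
    "PUBLISHED_SPLIT_SIZES",
]

#: Default per-coordinate positional noise of a reference geometry, in Å.
DEFAULT_NOISE = 0.02


# -- internal z-matrix geometry construction ----------------------------------


def _place(
    coords: list[np.ndarray],
    a: int,
    b: int,
    c: int,
    r: float,
    theta: float,
    phi: float,
) -> np.ndarray:
    """NeRF placement: new atom at distance ``r`` from ``a``, angle ``theta``
    (deg) to ``b``, dihedral ``phi`` (deg) about the a-b axis relative to ``c``."""
    theta = np.deg2rad(theta)
    phi = np.deg2rad(phi)
    pa, pb, pc = coords[a], coords[b], coords[c]
    ab = pa - pb
    ab /= np.linalg.norm(ab)
    cb = pa - pc
    n = np.cross(cb, ab)
    n /= np.linalg.norm(n)
    m = np.cross(n, ab)
    d = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    rot = np.stack([ab, m, n], axis=1)
    return pa + rot @ d


def _build_zmat(rows: list[tuple]) -> np.ndarray:
    """Build Cartesian coordinates from z-matrix rows.

    Row formats (atom indices refer to earlier rows): ``()`` for the first
    atom at the origin, ``(a, r)`` along +x from ``a``, ``(a, b, r, theta)``
    in the xy-plane, ``(a, b, c, r, theta, phi)`` general.
    """
    coords: list[np.ndarray] = []
    for row in rows:
        if len(row) == 0:
            coords.append(np.zeros(3))
        elif len(row) == 2:
            a, r = row
            coords.append(coords[a] + np.array([r, 0.0, 0.0]))
        elif len(row) == 4:
            a, b, r, theta = row
            ab = coords[b] - coords[a]
            ab /= np.linalg.norm(ab)
            th = np.deg2rad(theta)
            perp = np.array([-ab[1], ab[0], 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords.append(coords[a] + r * (np.cos(th) * ab + np.sin(th) * perp))
        else:
            a, b, c, r, theta, phi = row
            coords.append(_place(coords, a, b, c, r, theta, phi))
    return np.stack(coords)


@dataclass(frozen=True)
class Template:
    """A toy reaction plus a parametric geometry generator.

    ``zmat_fn(mode)`` returns z-matrix rows in *build order* together with the
    map ids they correspond to; mode 0 is the canonical geometry.
    """

    template_id: str
    reaction: str
    n_modes: int

    def modes(self) -> list[Conformation]:
        return [self.geometry(k) for k in range(self.n_modes)]

    def geometry(self, mode: int) -> Conformation:
        if not 0 <= mode < self.n_modes:
            raise ValueError(f"template {self.template_id} has no mode {mode}")
        rows, map_ids = _TEMPLATE_ZMATS[self.template_id](mode)
        built = _build_zmat(rows)
        out = np.zeros_like(built)
        for pos, map_id in enumerate(map_ids):
            out[map_id - 1] = built[pos]
        return out

    def graph(self) -> ReactionGraph:
        return build_condensed_graph(*parse_reaction(self.reaction))


# Breaking-bond extensions per mode, in Å: "early" vs "late" transition states.
_STRETCH = (1.9, 3.2, 2.55)


def _zmat_methanol_h2(mode: int):
    # C:1 H:2(migrating) H:3 H:4 O:5 H:6; H2 migrates from C toward H6 to
    # form H-H.  Modes are early/mid/late positions of the migrating H along
    # that path (both half-bonds change), keeping the geometry consistent
    # with the graph's bonding on each side.
    r_ch, theta = ((1.15, 100.0), (2.45, 45.0))[mode]
    rows = [
        (),  # C1
        (0, 1.40),  # O5
        (1, 0, 0.97, 105.0),  # H6
        (0, 1, 2, r_ch, theta, 0.0),  # H2 (in the C-O-H6 plane)
        (0, 1, 2, 1.09, 112.0, 120.0),  # H3
        (0, 1, 2, 1.09, 112.0, -120.0),  # H4
    ]
    return rows, [1, 5, 6, 2, 3, 4]


def _zmat_ethane(mode: int):
    # C:1 C:2 H:3..5 on C1, H:6..8 on C2; C-C homolysis.
    r_cc = _STRETCH[mode]
    twist = 60.0 if mode == 1 else 0.0
    rows = [
        (),  # C1
        (0, r_cc),  # C2
        (0, 1, 1.09, 111.0),  # H3
        (0, 1, 2, 1.09, 111.0, 120.0),  # H4
        (0, 1, 2, 1.09, 111.0, 240.0),  # H5
        (1, 0, 2, 1.09, 111.0, 60.0 + twist),  # H6
        (1, 0, 2, 1.09, 111.0, 180.0 + twist),  # H7
        (1, 0, 2, 1.09, 111.0, 300.0 + twist),  # H8
    ]
    return rows, [1, 2, 3, 4, 5, 6, 7, 8]


def _zmat_methylamine(mode: int):
    # C:1 N:2 H:3..5 on C, H:6..7 on N; C-N cleavage.
    r_cn = _STRETCH[mode]
    rows = [
        (),  # C1
        (0, r_cn),  # N2
        (0, 1, 1.09, 110.0),  # H3
        (0, 1, 2, 1.09, 110.0, 120.0),  # H4
        (0, 1, 2, 1.09, 110.0, 240.0),  # H5
        (1, 0, 2, 1.01, 108.0, 60.0),  # H6
        (1, 0, 2, 1.01, 108.0, 300.0),  # H7
    ]
    return rows, [1, 2, 3, 4, 5, 6, 7]


def _zmat_methanol_co(mode: int):
    # C:1 O:2 H:3..5 on C, H:6 on O; C-O cleavage.
    r_co = _STRETCH[mode]
    rows = [
        (),  # C1
        (0, r_co),  # O2
        (0, 1, 1.09, 110.0),  # H3
        (0, 1, 2, 1.09, 110.0, 120.0),  # H4
        (0, 1, 2, 1.09, 110.0, 240.0),  # H5
        (1, 0, 2, 0.97, 107.0, 180.0),  # H6
    ]
    return rows, [1, 2, 3, 4, 5, 6]


_TEMPLATE_ZMATS = {
    "methanol_h2_elimination": _zmat_methanol_h2,
    "ethane_homolysis": _zmat_ethane,
    "methylamine_cn_cleavage": _zmat_methylamine,
    "methanol_co_cleavage": _zmat_methanol_co,
}

TEMPLATES: tuple[Template, ...] = (
    Template(
        "methanol_h2_elimination",
        "[C:1]([H:2])([H:3])([H:4])[O:5][H:6]>>[C:1]([H:3])([H:4])=[O:5].[H:2][H:6]",
        n_modes=2,
    ),
    Template(
        "ethane_homolysis",
        "[C:1]([H:3])([H:4])([H:5])[C:2]([H:6])([H:7])[H:8]"
        ">>[C:1]([H:3])([H:4])[H:5].[C:2]([H:6])([H:7])[H:8]",
        n_modes=3,
    ),
    Template(
        "methylamine_cn_cleavage",
        "[C:1]([H:3])([H:4])([H:5])[N:2]([H:6])[H:7]"
        ">>[C:1]([H:3])([H:4])[H:5].[N:2]([H:6])[H:7]",
        n_modes=3,
    ),
    Template(
        "methanol_co_cleavage",
        "[C:1]([H:3])([H:4])([H:5])[O:2][H:6]>>[C:1]([H:3])([H:4])[H:5].[O:2][H:6]",
        n_modes=3,
    ),
)


def template_modes(template_id: str) -> list[Conformation]:
    """Noise-free mode geometries of a template, in atom-map order."""
    for t in TEMPLATES:
        if t.template_id == template_id:
            return t.modes()
    raise KeyError(template_id)


@dataclass
class ToyRecord:
    """One training/evaluation record: a reaction graph and its reference."""

    reaction_id: str
    template_id: str
    mode: int
    reaction: str
    graph: ReactionGraph
    conformation: Conformation


def make_toy_dataset(
    n_reactions: int,
    modes_per_reaction: int = 1,
    seed: int = 0,
    noise: float = DEFAULT_NOISE,
    templates: tuple[Template, ...] = TEMPLATES,
) -> list[ToyRecord]:
    """Deterministic toy dataset: templates cycled, one reference each.

    Each record's reference geometry is one of the template's first
    ``modes_per_reaction`` modes (drawn at random when > 1, mirroring the
    single-reference-per-reaction training regime of the real data) plus
    isotropic positional noise.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if modes_per_reaction < 1:
        raise ValueError("modes_per_reaction must be >= 1")
    rng = np.random.default_rng(seed)
    graphs = {t.template_id: t.graph() for t in templates}
    records: list[ToyRecord] = []
    for k in range(n_reactions):
        t = templates[k % len(templates)]
        m = modes_per_reaction
        if m > t.n_modes:
            raise ValueError(
                f"template {t.template_id} has only {t.n_modes} modes, "
                f"{m} requested"
            )
        mode = int(rng.integers(m)) if m > 1 else 0
        ref = t.geometry(mode) + noise * rng.standard_normal((graphs[t.template_id].n_atoms, 3))
        records.append(
            ToyRecord(
                reaction_id=f"{t.template_id}:{k}",
                template_id=t.template_id,
                mode=mode,
                reaction=t.reaction,
                graph=graphs[t.template_id],
                conformation=ref,
            )
        )
    return records


#: Published partition of the curated 11,959-reaction gas-phase database.
PUBLISHED_SPLIT_SIZES = {11959: (9566, 1196, 1197)}


def split_dataset(
    records: list,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rule: str = "floor",
    seed: int = 0,
) -> tuple[list, list, list]:
    """Random disjoint train/valid/test partition.

    ``rule="floor"``: valid and test sizes are ``floor(N * ratio)``, train
    takes the rest.  ``rule="published"``: explicit published sizes — for
    N = 11,959 at 8:1:1 this is (9,566, 1,196, 1,197), which no standard
    rounding of the ratios produces; sizes are pinned, not derived.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(records)
    if rule == "floor":
        n_valid = int(np.floor(n * ratios[1]))
        n_test = int(np.floor(n * ratios[2]))
        n_train = n - n_valid - n_test
    elif rule == "published":
        if n not in PUBLISHED_SPLIT_SIZES or tuple(ratios) != (0.8, 0.1, 0.1):
            raise ValueError(
                f"rule 'published' pins explicit sizes; none known for N={n}, ratios={ratios}"
            )
        n_train, n_valid, n_test = PUBLISHED_SPLIT_SIZES[n]
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    perm = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    valid = [records[i] for i in perm[n_train : n_train + n_valid]]
    test = [records[i] for i in perm[n_train + n_valid :]]
    return train, valid, test


def augment_reverse(train: list) -> list:
    """Double a training list by appending each record's reverse reaction.

    The reverse swaps the reactant/product halves of every node and edge
    feature; the reference geometry is shared (the transition state of the
    reverse reaction is the same saddle point).  Accepts ``ToyRecord`` lists
    or ``(ReactionGraph, Conformation)`` tuples.
    """
    out = list(train)
    for rec in train:
        if isinstance(rec, ToyRecord):
            out.append(
                ToyRecord(
                    reaction_id=rec.reaction_id + ":rev",
                    template_id=rec.template_id,
                    mode=rec.mode,
                    reaction=rec.reaction,
                    graph=rec.graph.swap_sides(),
                    conformation=rec.conformation,
                )
            )
        else:
            g, c = rec
            out.append((g.swap_sides(), c))
    return out
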