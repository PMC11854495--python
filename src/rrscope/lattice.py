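"""Rough-set lattices of thresholded weight relations and their logic class.

A weight matrix thresholded at theta yields a binary relation
I subset of U1 x U2 (row i related to column j iff w_ij >= theta).  The
relation induces a closure on subsets X of U1:

    r*(X) = { q in U2 : p I q for some p in X }       (union of row images)
    R*(Y) = U1 - { p : p I q for some q not in Y }    (rows whose whole
                                                       image lies in Y)
    Cl(X) = R*(r*(X))

Cl is extensive, monotone and idempotent; its fixed points ordered by
inclusion form the rough-set lattice.  A diagonal relation gives the
full powerset (a Boolean algebra); a relation made of diagonal
sub-blocks surrounded by related cells gives a horizontal sum of
Boolean algebras sharing only their least and greatest elements — a
non-distributive orthomodular lattice, i.e. quantum logic.  `classify`
recognizes these two shapes structurally and returns ``other`` whenever
the block decomposition fails.

Subsets are passed and returned as frozensets of element labels
(defaults: ``A, B, C, ...`` for U1 and ``a, b, c, ...`` for U2).
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass

import numpy as np

from .network import WeightMatrix

__all__ = [
    "BinaryRelation",
    "RoughSetLattice",
    "LogicClass",
    "relation_from_weights",
    "r_star",
    "R_star",
    "closure",
    "enumerate_fixed_points",
    "classify",
    "relation_to_tsv",
    "relation_from_tsv",
    "lattice_to_json",
]

ENUMERATION_LIMIT = 20


def default_labels(n: int, lowercase: bool = False) -> tuple[str, ...]:
    letters = string.ascii_lowercase if lowercase else string.ascii_uppercase
    if n <= len(letters):
        return tuple(letters[:n])
    prefix = "x" if lowercase else "X"
    return tuple(f"{prefix}{i}" for i in range(n))


@dataclass(frozen=True)
class BinaryRelation:
    """A boolean |U1| x |U2| matrix with element labels."""

    matrix: np.ndarray
    u1_labels: tuple[str, ...] = ()
    u2_labels: tuple[str, ...] = ()
    threshold: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("relation matrix must be two-dimensional")
        if not self.u1_labels:
            object.__setattr__(self, "u1_labels", default_labels(m.shape[0]))
        if not self.u2_labels:
            object.__setattr__(self, "u2_labels", default_labels(m.shape[1], True))
        if len(self.u1_labels) != m.shape[0] or len(self.u2_labels) != m.shape[1]:
            raise ValueError("label counts do not match the matrix shape")

    @property
    def n1(self) -> int:
        return self.matrix.shape[0]

    @property
    def n2(self) -> int:
        return self.matrix.shape[1]

    # --- label/bitmask conversion helpers -------------------------------
    def _mask1(self, X) -> int:
        idx = {lab: i for i, lab in enumerate(self.u1_labels)}
        m = 0
        for lab in X:
            m |= 1 << idx[lab]
        return m

    def _mask2(self, Y) -> int:
        idx = {lab: i for i, lab in enumerate(self.u2_labels)}
        m = 0
        for lab in Y:
            m |= 1 << idx[lab]
        return m

    def _unmask1(self, m: int) -> frozenset:
        return frozenset(lab for i, lab in enumerate(self.u1_labels) if m >> i & 1)

    def _unmask2(self, m: int) -> frozenset:
        return frozenset(lab for i, lab in enumerate(self.u2_labels) if m >> i & 1)

    def row_images(self) -> list[int]:
        """Bitmask over U2 of each row's related columns."""
        return [int(sum(1 << j for j in np.flatnonzero(row)))
                for row in self.matrix]


def relation_from_weights(weights: WeightMatrix | np.ndarray, theta: float) -> BinaryRelation:
    """Relate (i, j) iff w_ij >= theta."""
    w = weights.entries if isinstance(weights, WeightMatrix) else np.asarray(weights)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    return BinaryRelation(matrix=w >= theta, threshold=float(theta))


def _r_star_mask(maskX: int, images: list[int]) -> int:
    out = 0
    for i, img in enumerate(images):
        if maskX >> i & 1:
            out |= img
    return out


def _R_star_mask(maskY: int, images: list[int]) -> int:
    out = 0
    for i, img in enumerate(images):
        if img & ~maskY == 0:
            out |= 1 << i
    return out


def r_star(X, rel: BinaryRelation) -> frozenset:
    """Columns related to at least one element of X."""
    return rel._unmask2(_r_star_mask(rel._mask1(X), rel.row_images()))


def R_star(Y, rel: BinaryRelation) -> frozenset:
    """Rows whose entire image lies inside Y."""
    return rel._unmask1(_R_star_mask(rel._mask2(Y), rel.row_images()))


def closure(X, rel: BinaryRelation) -> frozenset:
    """Cl(X) = R*(r*(X)): extensive, monotone, idempotent."""
    images = rel.row_images()
    return rel._unmask1(_R_star_mask(_r_star_mask(rel._mask1(X), images), images))


@dataclass(frozen=True)
class RoughSetLattice:
    """All fixed points of the closure, ordered by inclusion."""

    elements: tuple[frozenset, ...]
    universe: frozenset
    atoms: tuple[frozenset, ...]
    least: frozenset


@dataclass(frozen=True)
class LogicClass:
    """Structural classification of a rough-set lattice.

    ``blocks`` lists, per Boolean block, the tuple of its atoms.
    """

    kind: str
    blocks: tuple[tuple[frozenset, ...], ...] = ()


def enumerate_fixed_points(rel: BinaryRelation) -> RoughSetLattice:
    """Exhaustive enumeration of { X : Cl(X) = X } over all 2^|U1| subsets."""
    n = rel.n1
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"|U1| = {n} exceeds the exhaustive enumeration limit "
            f"({ENUMERATION_LIMIT})")
    images = rel.row_images()
    fixed: list[int] = []
    for m in range(1 << n):
        if _R_star_mask(_r_star_mask(m, images), images) == m:
            fixed.append(m)
    elements = sorted((rel._unmask1(m) for m in fixed),
                      key=lambda s: (len(s), sorted(s)))
    universe = frozenset(rel.u1_labels)
    least = min(elements, key=len)
    non_least = [e for e in elements if e != least]
    atoms = tuple(e for e in non_least
                  if not any(o < e for o in non_least))
    return RoughSetLattice(elements=tuple(elements), universe=universe,
                           atoms=atoms, least=least)


def _join(lattice: RoughSetLattice, parts) -> frozenset:
    """Lattice join: the smallest fixed point containing the union.

    Fixed-point families of a Galois-connection closure are closed under
    intersection, so the minimum over all containing elements exists.
    """
    union: frozenset = lattice.least
    for p in parts:
        union = union | p
    candidates = [e for e in lattice.elements if union <= e]
    return min(candidates, key=len)


def classify(lattice: RoughSetLattice) -> LogicClass:
    """Boolean algebra, quantum logic (horizontal sum), or other.

    boolean: the lattice is the 2^k powerset of its atoms (one block).
    quantum: the non-extremal elements split into >= 2 groups, each of
    which together with the least and greatest elements forms a Boolean
    sub-algebra, with no order relations across groups except through
    the extremes.
    other: any failure of that decomposition.
    """
    L = list(lattice.elements)
    if len(L) == 1:
        return LogicClass(kind="boolean", blocks=())
    least = lattice.least
    greatest = max(L, key=len)
    if greatest != lattice.universe and any(not (e <= greatest) for e in L):
        return LogicClass(kind="other")
    atoms = list(lattice.atoms)

    def atoms_of(x: frozenset) -> frozenset:
        return frozenset(i for i, a in enumerate(atoms) if a <= x)

    # every element must be the join of the atoms below it
    for x in L:
        if x in (least,):
            continue
        if _join(lattice, [atoms[i] for i in atoms_of(x)]) != x:
            return LogicClass(kind="other")

    mid = [x for x in L if x != least and x != greatest]
    # union-find over atoms via co-occurrence below a common mid element
    parent = list(range(len(atoms)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for x in mid:
        ax = sorted(atoms_of(x))
        for i, j in zip(ax, ax[1:]):
            union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(atoms)):
        groups.setdefault(find(i), []).append(i)
    blocks = sorted(groups.values(), key=lambda g: (-len(g), g))

    # Lone atoms arise from 2x2 diagonal sub-relations whose pairwise
    # join is the greatest element; each pair of them forms one 2^2
    # Boolean block.  Pair them up; an unpaired leftover defeats the
    # decomposition.
    singles = [g[0] for g in blocks if len(g) == 1]
    blocks = [g for g in blocks if len(g) > 1]
    while len(singles) >= 2:
        blocks.append([singles.pop(0), singles.pop(0)])
    if singles and blocks:
        return LogicClass(kind="other")
    if singles:  # a single atom overall: chain {least, a, greatest}
        if len(L) == 2:  # least and greatest only, greatest is the atom
            return LogicClass(kind="boolean",
                              blocks=((atoms[singles[0]],),))
        return LogicClass(kind="other")

    # verify each block is a Boolean sub-algebra sharing the extremes
    for g in blocks:
        members = [x for x in mid if atoms_of(x) and atoms_of(x) <= set(g)]
        if len(members) != 2 ** len(g) - 2:
            return LogicClass(kind="other")
        if _join(lattice, [atoms[i] for i in g]) != greatest:
            return LogicClass(kind="other")
        if 2 ** len(g) <= 4096:
            # joins of proper nonempty atom subsets must be distinct
            # mid elements realizing exactly those atoms
            seen = set()
            for k in range(1, len(g)):
                for comb in itertools.combinations(g, k):
                    j = _join(lattice, [atoms[i] for i in comb])
                    if j == greatest or atoms_of(j) != frozenset(comb):
                        return LogicClass(kind="other")
                    seen.add(j)
            if len(seen) != 2 ** len(g) - 2:
                return LogicClass(kind="other")
    block_atoms = tuple(tuple(atoms[i] for i in sorted(g)) for g in blocks)
    kind = "boolean" if len(blocks) == 1 else "quantum"
    return LogicClass(kind=kind, blocks=block_atoms)


# ---------------------------------------------------------------------------
# serialization


def relation_to_tsv(rel: BinaryRelation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(rel.u2_labels) + "\n")
        for lab, row in zip(rel.u1_labels, rel.matrix):
            fh.write(lab + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")


def relation_from_tsv(path) -> BinaryRelation:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    u2 = tuple(lines[0].split("\t")[1:])
    u1, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        u1.append(parts[0])
        rows.append([c == "1" for c in parts[1:]])
    return BinaryRelation(matrix=np.array(rows, dtype=bool),
                          u1_labels=tuple(u1), u2_labels=u2)


def lattice_to_json(lattice: RoughSetLattice, logic: LogicClass | None = None) -> str:
    elems = [sorted(e) for e in lattice.elements]
    covers = []
    for i, x in enumerate(lattice.elements):
        for j, y in enumerate(lattice.elements):
            if x < y and not any(x < z < y for z in lattice.elements):
                covers.append([i, j])
    payload = {
        "elements": elems,
        "cover_relations": covers,
        "atoms": [sorted(a) for a in lattice.atoms],
        "least": sorted(lattice.least),
    }
    if logic is not None:
        payload["logic"] = {
            "kind": logic.kind,
            "blocks": [[sorted(a) for a in blk] for blk in logic.blocks],
        }
    return json.dumps(payload, indent=2)
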