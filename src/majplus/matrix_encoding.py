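"""MRP-style matrix representation of a profile and fill-in semantics.

M(P) is an n x m matrix over {0, 1, ?} with one row per taxon of L(P) and
one column per nontrivial split of each input tree.  For a column coming
from tree t_j, rows of taxa outside L(t_j) hold '?'.  A *fill-in* replaces
every '?' by 0 or 1; when the filled columns of each tree are pairwise
compatible, the fill-in is exactly the matrix representation of a
restricted representative selection: each input split grows into a distinct
plenary split, no polytomy is refined.

Encoding conventions (the optimization is invariant to them):
  * rooted: taxa on the root-containing side get 1, cluster members get 0;
  * unrooted: the side holding the lexicographically smallest taxon of
    L(t_j) gets 1.
Columns appear in profile order; within a tree, splits are sorted by their
canonical form so matrices are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .phylo_core import (
    IncompatibleSplitsError,
    PhyloError,
    Split,
    Tree,
    tree_from_splits,
)
from .consensus_plus import Profile, RepresentativeSelection

__all__ = [
    "QMARK",
    "SplitMatrix",
    "FillIn",
    "build_matrix",
    "decode",
    "enumerate_fillins",
    "columns_compatible",
]

QMARK = -1  # '?' entries


def _split_sort_key(s: Split):
    return (tuple(sorted(s.side_a)), tuple(sorted(s.side_b)))


@dataclass(frozen=True)
class SplitMatrix:
    """Matrix representation M(P) with the column provenance map."""

    entries: np.ndarray            # int8, values {0, 1, QMARK}
    row_taxa: tuple                # sorted taxa of L(P)
    col_map: tuple                 # column -> (tree index, source Split)
    rooted: bool
    profile: Profile

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        return self.entries.shape[1]

    @property
    def k(self) -> int:
        return self.profile.k

    @property
    def num_questions(self) -> int:
        """U: the number of '?' entries."""
        return int(np.sum(self.entries == QMARK))

    @property
    def percent_questions(self) -> float:
        """%U = U / (n * m) as a percentage."""
        if self.m == 0:
            return 0.0
        return 100.0 * self.num_questions / (self.n * self.m)

    def tree_columns(self, j: int) -> list:
        return [i for i, (tj, _) in enumerate(self.col_map) if tj == j]

    def to_tsv(self) -> str:
        lines = ["\t".join(["taxon"] + [f"c{i}" for i in range(self.m)])]
        for r, tx in enumerate(self.row_taxa):
            vals = [
                "?" if v == QMARK else str(int(v)) for v in self.entries[r]
            ]
            lines.append("\t".join([tx] + vals))
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        rows = []
        for r, tx in enumerate(self.row_taxa):
            chars = "".join(
                "?" if v == QMARK else str(int(v)) for v in self.entries[r]
            )
            rows.append(f"    {tx}  {chars}")
        body = "\n".join(rows)
        return (
            "#NEXUS\nBEGIN DATA;\n"
            f"  DIMENSIONS NTAX={self.n} NCHAR={self.m};\n"
            '  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";\n'
            "  MATRIX\n" + body + "\n  ;\nEND;\n"
        )


@dataclass(frozen=True)
class FillIn:
    """A complete 0/1 assignment agreeing with M(P) off the '?' cells."""

    entries: np.ndarray
    parent: SplitMatrix

    def __post_init__(self):
        mx = self.parent.entries
        known = mx != QMARK
        if not np.array_equal(self.entries[known], mx[known]):
            raise PhyloError("fill-in disagrees with a fixed matrix entry")


def _encode_column(split: Split, row_index: dict, n: int, rooted: bool):
    col = np.full(n, QMARK, dtype=np.int8)
    if rooted:
        ones, zeros = split.side_b, split.side_a
    else:
        tree_leaves = split.universe
        pivot = min(tree_leaves)
        if pivot in split.side_a:
            ones, zeros = split.side_a, split.side_b
        else:
            ones, zeros = split.side_b, split.side_a
    for tx in ones:
        col[row_index[tx]] = 1
    for tx in zeros:
        col[row_index[tx]] = 0
    return col


def build_matrix(p: Profile) -> SplitMatrix:
    """Build M(P).  Trees without nontrivial splits contribute no columns
    (they still count toward k in the downstream tallies)."""
    taxa = tuple(sorted(p.union_leaves))
    row_index = {tx: r for r, tx in enumerate(taxa)}
    n = len(taxa)
    cols, col_map = [], []
    for j, t in enumerate(p.trees):
        for s in sorted(t.splits, key=_split_sort_key):
            cols.append(_encode_column(s, row_index, n, p.rooted))
            col_map.append((j, s))
    entries = (
        np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.int8)
    )
    return SplitMatrix(entries, taxa, tuple(col_map), p.rooted, p)


def column_split(entries: np.ndarray, col: int, row_taxa, rooted: bool) -> Split:
    """Interpret a fully filled column as a plenary split."""
    zeros = frozenset(tx for r, tx in enumerate(row_taxa) if entries[r, col] == 0)
    ones = frozenset(tx for r, tx in enumerate(row_taxa) if entries[r, col] == 1)
    if rooted:
        return Split(zeros, ones, rooted=True)
    return Split(zeros, ones, rooted=False)


def columns_compatible(colp: np.ndarray, colq: np.ndarray, rooted: bool) -> bool:
    """Four-gametes test on two filled 0/1 columns.

    In rooted mode the implicit root taxon contributes a (1,1) row, so the
    pattern 11 is always considered present.
    """
    pats = set(zip(colp.tolist(), colq.tolist()))
    if rooted:
        pats.add((1, 1))
    return not {(0, 0), (0, 1), (1, 0), (1, 1)} <= pats


def decode(f: FillIn) -> RepresentativeSelection:
    """Turn a fill-in into the restricted representative selection it encodes.

    For each tree the filled columns become plenary splits; pairwise
    incompatibility within a tree is an error naming the offending columns.
    Distinctness within a tree is automatic: two columns of one tree
    restrict to distinct source splits, hence their fills differ.
    """
    mx = f.parent
    leaves = frozenset(mx.row_taxa)
    trees = []
    for j, src in enumerate(mx.profile.trees):
        cols = mx.tree_columns(j)
        for a, b in itertools.combinations(cols, 2):
            if not columns_compatible(
                f.entries[:, a], f.entries[:, b], mx.rooted
            ):
                raise IncompatibleSplitsError(
                    f"fill-in columns {a} and {b} of tree {j} are incompatible"
                )
        sps = [
            column_split(f.entries, c, mx.row_taxa, mx.rooted) for c in cols
        ]
        trees.append(tree_from_splits(sps, leaves, mx.rooted))
    return RepresentativeSelection(tuple(trees), mx.profile)


def _tree_fill_variants(mx: SplitMatrix, j: int):
    """All compatible 0/1 assignments to the '?' cells of tree j's columns.

    Returned as (positions, [assignment tuples]) in deterministic binary
    counting order (position list sorted by (row, col), bit value 0 first).
    """
    cols = mx.tree_columns(j)
    positions = [
        (r, c)
        for c in cols
        for r in range(mx.n)
        if mx.entries[r, c] == QMARK
    ]
    positions.sort()
    variants = []
    base = mx.entries[:, :].copy()
    for bits in itertools.product((0, 1), repeat=len(positions)):
        for (r, c), v in zip(positions, bits):
            base[r, c] = v
        ok = all(
            columns_compatible(base[:, a], base[:, b], mx.rooted)
            for a, b in itertools.combinations(cols, 2)
        )
        if ok:
            variants.append(bits)
    return positions, variants


def enumerate_fillins(mx: SplitMatrix, max_questions: int = 20):
    """Yield every fill-in whose per-tree columns are pairwise compatible.

    Enumeration is exact and deterministic; the '?' budget guards against
    accidentally launching a 2^U sweep on an instance meant for the ILP.
    """
    U = mx.num_questions
    if U > max_questions:
        raise PhyloError(
            f"{U} question marks exceed the enumeration bound "
            f"{max_questions}; brute force is infeasible here -- use the ILP"
        )
    per_tree = [_tree_fill_variants(mx, j) for j in range(mx.k)]
    for combo in itertools.product(*(v for _, v in per_tree)):
        entries = mx.entries.copy()
        for (positions, _), bits in zip(per_tree, combo):
            for (r, c), v in zip(positions, bits):
                entries[r, c] = v
        yield FillIn(entries, mx)
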