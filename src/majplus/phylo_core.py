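"""Tree and split algebra.

Phylogenetic trees are represented purely by their leaf sets and the
bipartitions (splits) they display: an unrooted tree on a fixed leaf set is
uniquely determined by its set of nontrivial full splits, and a rooted tree
by its set of nontrivial clusters.  Working at this level makes restriction,
compatibility testing, consensus and Robinson-Foulds distances set
operations, which is all the supertree machinery needs -- branch lengths and
node geometry play no role.

Rooted trees are handled natively as cluster sets: a split of a rooted tree
is stored as (cluster | rest-of-leaves), with the root understood to sit on
the second side.  This is equivalent to viewing the rooted tree as an
unrooted tree with an extra shared root taxon, without materializing that
taxon.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "PhyloError",
    "NewickError",
    "LeafSetError",
    "IncompatibleSplitsError",
    "Split",
    "Tree",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "splits",
    "restrict",
    "displays",
    "displays_tree",
    "compatible",
    "split_compatible_with_tree",
    "rf_distance",
    "tree_from_splits",
]


class PhyloError(ValueError):
    """Base error for tree/split operations."""


class NewickError(PhyloError):
    """Malformed Newick input."""


class LeafSetError(PhyloError):
    """An operation received trees/splits over the wrong leaf set."""


class IncompatibleSplitsError(PhyloError):
    """A set of splits admits no common tree."""


@dataclass(frozen=True)
class Split:
    """A bipartition of a taxon set.

    For unrooted splits the orientation is canonical: ``side_a`` is the side
    containing the lexicographically smallest taxon of the universe.  For
    rooted splits ``side_a`` is the cluster (the side *not* containing the
    root) and ``side_b`` the remaining taxa; equality is therefore cluster
    equality in rooted mode and bipartition equality in unrooted mode.
    """

    side_a: frozenset
    side_b: frozenset
    rooted: bool = False

    def __post_init__(self):
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if a & b:
            raise PhyloError(f"split sides overlap: {sorted(a & b)}")
        if not a and not b:
            raise PhyloError("empty split")
        if not self.rooted:
            # canonical orientation: smallest taxon of the universe first
            if not a or (b and min(b) < min(a)):
                a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @classmethod
    def cluster(cls, members: Iterable, universe: Iterable) -> "Split":
        members = frozenset(members)
        universe = frozenset(universe)
        if not members <= universe:
            raise LeafSetError("cluster not contained in universe")
        return cls(members, universe - members, rooted=True)

    @property
    def universe(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def is_nontrivial(self) -> bool:
        if self.rooted:
            # with the implicit root on side_b, the split is nontrivial as
            # soon as the cluster has >= 2 taxa and is a proper subset
            return len(self.side_a) >= 2 and len(self.side_b) >= 1
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restricted(self, taxa: Iterable) -> "Split | None":
        """Restriction to ``taxa``; None when one side disappears."""
        taxa = frozenset(taxa)
        a, b = self.side_a & taxa, self.side_b & taxa
        if not a or (not b and not self.rooted):
            return None
        return Split(a, b, self.rooted)

    def compatible_with(self, other: "Split") -> bool:
        """Four-gametes test for two full splits over one universe."""
        if self.rooted != other.rooted:
            raise PhyloError("cannot mix rooted and unrooted splits")
        if self.universe != other.universe:
            raise LeafSetError("splits over different universes")
        if self.rooted:
            a, c = self.side_a, other.side_a
            return not (a & c) or a <= c or c <= a
        a, b = self.side_a, self.side_b
        c, d = other.side_a, other.side_b
        return not (a & c) or not (a & d) or not (b & c) or not (b & d)

    def extends(self, other: "Split") -> bool:
        """True when this (larger-universe) split extends ``other``."""
        if self.rooted != other.rooted:
            raise PhyloError("cannot mix rooted and unrooted splits")
        if self.rooted:
            return other.side_a <= self.side_a and other.side_b <= self.side_b
        return (other.side_a <= self.side_a and other.side_b <= self.side_b) or (
            other.side_a <= self.side_b and other.side_b <= self.side_a
        )

    def __repr__(self):  # pragma: no cover - debugging aid
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        tag = "r" if self.rooted else "u"
        return f"Split[{tag}]({a}|{b})"


@dataclass(frozen=True)
class Tree:
    """A leaf-labeled phylogenetic tree given by its nontrivial splits.

    Two trees are equal iff they have the same leaf set, rootedness and
    split set, i.e. iff they are isomorphic as phylogenies.
    """

    leaves: frozenset
    splits: frozenset = field(default_factory=frozenset)
    rooted: bool = False

    def __post_init__(self):
        object.__setattr__(self, "leaves", frozenset(self.leaves))
        object.__setattr__(self, "splits", frozenset(self.splits))
        if not self.leaves:
            raise PhyloError("tree must have at least one leaf")
        sps = sorted(self.splits, key=_split_key)
        for s in sps:
            if s.rooted != self.rooted:
                raise PhyloError("split rootedness does not match tree")
            if s.universe != self.leaves:
                raise LeafSetError(
                    f"split {s!r} is not plenary on the tree's leaf set"
                )
            if not s.is_nontrivial:
                raise PhyloError(f"trivial split {s!r} stored in tree")
        for i, s in enumerate(sps):
            for t in sps[i + 1:]:
                if not s.compatible_with(t):
                    raise IncompatibleSplitsError(
                        f"incompatible splits {s!r} and {t!r}"
                    )

    @property
    def is_star(self) -> bool:
        return not self.splits

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tree({self.newick()!r}, rooted={self.rooted})"


def _split_key(s: Split):
    return (tuple(sorted(s.side_a)), tuple(sorted(s.side_b)))


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; deterministic writer)
# ---------------------------------------------------------------------------

_LABEL_SAFE = re.compile(r"^[A-Za-z0-9_.\-|]+$")


def parse_newick(text: str, rooted: bool = False) -> Tree:
    """Parse one Newick tree string.

    Branch lengths and internal labels are discarded (the methods here are
    topology-only); degree-two chains collapse automatically because only
    distinct leaf-set bipartitions are retained.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    labels = [
        lf.taxon.label if lf.taxon is not None else None
        for lf in dt.leaf_node_iter()
    ]
    if not labels or any(lb is None or lb == "" for lb in labels):
        raise NewickError("tree is empty or contains an unlabeled leaf")
    if len(set(labels)) != len(labels):
        dup = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise NewickError(f"duplicate leaf labels: {dup}")
    leaves = frozenset(labels)
    sps = set()
    for node in dt.preorder_node_iter():
        if node is dt.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if rooted:
            s = Split.cluster(below, leaves)
        else:
            s = Split(below, leaves - below, rooted=False)
        if s.is_nontrivial:
            sps.add(s)
    return Tree(leaves, frozenset(sps), rooted)


def parse_newick_list(text: str, rooted: bool = False) -> list:
    """Parse several trees: one per line and/or ';'-separated."""
    trees = []
    for chunk in io.StringIO(text).read().replace(";", ";\n").splitlines():
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk, rooted=rooted))
    return trees


def _quote(label: str) -> str:
    if _LABEL_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _nest(universe: frozenset, clades: list) -> str:
    """Serialize ``universe`` with the laminar family ``clades`` inside it."""
    top = [c for c in clades if not any(c < d for d in clades)]
    parts = []
    covered = frozenset().union(*top) if top else frozenset()
    for c in sorted(top, key=lambda c: min(c)):
        parts.append(_nest(c, [d for d in clades if d < c]))
    for leaf in sorted(universe - covered):
        parts.append(_quote(leaf))
    parts.sort()
    return "(" + ",".join(parts) + ")"


def write_newick(t: Tree) -> str:
    """Deterministic Newick serialization (children sorted)."""
    if len(t.leaves) == 1:
        return _quote(next(iter(t.leaves))) + ";"
    if t.rooted:
        clades = [s.side_a for s in t.splits]
        return _nest(t.leaves, clades) + ";"
    pivot = min(t.leaves)
    rest = t.leaves - {pivot}
    clades = [s.side_a if pivot not in s.side_a else s.side_b for s in t.splits]
    if len(rest) == 1:
        return f"({_quote(pivot)},{_quote(next(iter(rest)))});"
    return f"({_quote(pivot)},{_nest(rest, clades)});"


# ---------------------------------------------------------------------------
# Split extraction, restriction, display, compatibility
# ---------------------------------------------------------------------------

def splits(t: Tree, include_trivial: bool = False) -> frozenset:
    """Spl(t) -- or Spl0(t) when ``include_trivial`` is set.

    Spl0 contains every full split displayed by ``t``, including the trivial
    leaf splits and the degenerate split L(t)|(empty set); the latter cannot
    be represented as a :class:`Split` and is instead implied by
    :func:`witness sides <majplus.reduction.is_reducible>` handling.
    """
    if not include_trivial:
        return t.splits
    out = set(t.splits)
    for leaf in t.leaves:
        if t.rooted:
            if len(t.leaves) >= 2:
                out.add(Split.cluster({leaf}, t.leaves))
        else:
            if len(t.leaves) >= 2:
                out.add(Split({leaf}, t.leaves - {leaf}, rooted=False))
    if t.rooted and len(t.leaves) >= 1:
        # the cluster below the root: all leaves vs (implicit) root
        out.add(Split(t.leaves, frozenset(), rooted=True))
    return frozenset(out)


def restrict(t: Tree, taxa: Iterable) -> Tree:
    """T|S: the restriction of ``t`` to a subset of its leaves."""
    taxa = frozenset(taxa)
    if not taxa <= t.leaves:
        raise LeafSetError(
            f"restriction set is not a subset of the leaf set: "
            f"{sorted(taxa - t.leaves)}"
        )
    if not taxa:
        raise PhyloError("cannot restrict to an empty taxon set")
    new = set()
    for s in t.splits:
        r = s.restricted(taxa)
        if r is not None and r.is_nontrivial:
            new.add(r)
    return Tree(taxa, frozenset(new), t.rooted)


def displays(t: Tree, x: Split) -> bool:
    """True when some edge of ``t`` separates the two sides of ``x``."""
    if x.rooted != t.rooted:
        raise PhyloError("cannot mix rooted and unrooted objects")
    if not x.universe <= t.leaves:
        raise LeafSetError("split mentions taxa outside the tree")
    if not x.is_nontrivial:
        return True
    r = restrict(t, x.universe) if x.universe != t.leaves else t
    return x in r.splits


def displays_tree(t: Tree, t2: Tree) -> bool:
    """True when Spl(t2) is a subset of Spl(t | L(t2))."""
    if t.rooted != t2.rooted:
        raise PhyloError("cannot mix rooted and unrooted trees")
    if not t2.leaves <= t.leaves:
        raise LeafSetError("displayed tree has taxa outside the display tree")
    return t2.splits <= restrict(t, t2.leaves).splits


def compatible(xs: Iterable) -> bool:
    """Joint compatibility of full splits over one universe.

    For full splits on a common universe, pairwise compatibility (the
    four-gametes condition) is equivalent to the existence of a single tree
    displaying them all, so a pairwise sweep decides the set.
    """
    xs = list(xs)
    if not xs:
        return True
    uni, rooted = xs[0].universe, xs[0].rooted
    for s in xs:
        if s.universe != uni:
            raise LeafSetError("splits over mixed universes")
        if s.rooted != rooted:
            raise PhyloError("cannot mix rooted and unrooted splits")
    return all(
        xs[i].compatible_with(xs[j])
        for i in range(len(xs))
        for j in range(i + 1, len(xs))
    )


def split_compatible_with_tree(x: Split, t: Tree) -> bool:
    """Is there a tree displaying both ``t`` and the (possibly partial) ``x``?

    A single split is compatible with a tree iff it is compatible with the
    restriction of the tree to the split's universe, which reduces to the
    pairwise four-gametes test on that universe.
    """
    if x.rooted != t.rooted:
        raise PhyloError("cannot mix rooted and unrooted objects")
    if not x.universe <= t.leaves:
        raise LeafSetError("split mentions taxa outside the tree")
    if not x.is_nontrivial:
        return True
    r = restrict(t, x.universe) if x.universe != t.leaves else t
    return all(x.compatible_with(s) for s in r.splits)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds (symmetric-difference) distance on nontrivial splits."""
    if t1.leaves != t2.leaves:
        raise LeafSetError("Robinson-Foulds distance needs equal leaf sets")
    if t1.rooted != t2.rooted:
        raise PhyloError("cannot mix rooted and unrooted trees")
    return len(t1.splits ^ t2.splits)


def tree_from_splits(xs: Iterable, leaves: Iterable, rooted: bool = False) -> Tree:
    """The unique tree whose nontrivial split set is ``xs``.

    Trivial members of ``xs`` are dropped; incompatible input raises
    :class:`IncompatibleSplitsError` (via the Tree invariant check).
    """
    leaves = frozenset(leaves)
    keep = frozenset(s for s in xs if s.is_nontrivial)
    return Tree(leaves, keep, rooted)
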