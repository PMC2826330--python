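"""Consensus-setting machinery for majority-rule (+) supertrees.

Given a profile of trees over one leaf set, the majority-rule (+) consensus
displays exactly the plenary splits X whose number of displaying trees
exceeds the number of trees incompatible with X.  This module implements
that characterization together with the supporting notions the supertree
optimization is built on: representative selections, their completions, and
the adjusted score

    s~(R) = sum over distinct splits X in R of
              |K-X(R)|  if |K_X(R)| > |K-X(R)|   (majority-qualified X)
              |K_X(R)|  otherwise,

where K_X is the set of trees displaying X and K-X the set of trees
incompatible with X.  The adjusted score equals the Robinson-Foulds
distance from the Maj+ consensus of R to the completion of R, and both
routes are computed and cross-checked in :func:`adjusted_score`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .phylo_core import (
    LeafSetError,
    PhyloError,
    Split,
    Tree,
    displays_tree,
    rf_distance,
    split_compatible_with_tree,
    tree_from_splits,
)

__all__ = [
    "Profile",
    "SplitTally",
    "RepresentativeSelection",
    "ScoredSelection",
    "strict_consensus",
    "majority_consensus",
    "profile_distance",
    "median_score",
    "tally_split",
    "majority_plus_consensus",
    "completion",
    "adjusted_score",
    "score_selection",
]


@dataclass(frozen=True)
class Profile:
    """An ordered tuple of input trees with a shared rootedness flag."""

    trees: tuple
    rooted: bool = False

    def __post_init__(self):
        trees = tuple(self.trees)
        if not trees:
            raise PhyloError("a profile needs at least one tree")
        for t in trees:
            if t.rooted != self.rooted:
                raise PhyloError("all trees in a profile share one rootedness")
        object.__setattr__(self, "trees", trees)

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def union_leaves(self) -> frozenset:
        out = frozenset()
        for t in self.trees:
            out |= t.leaves
        return out

    @property
    def is_consensus_profile(self) -> bool:
        return all(t.leaves == self.trees[0].leaves for t in self.trees)


@dataclass(frozen=True)
class SplitTally:
    """Per-split display/incompatibility counts across a profile."""

    split: Split
    n_display: int
    n_incompatible: int
    k: int

    @property
    def n_irrelevant(self) -> int:
        return self.k - self.n_display - self.n_incompatible

    @property
    def qualifies(self) -> bool:
        """Theorem-1 condition: strictly more displayers than conflicters."""
        return self.n_display > self.n_incompatible


@dataclass(frozen=True)
class RepresentativeSelection:
    """One plenary tree per input tree, each displaying its input tree."""

    trees: tuple
    source: Profile | None = None

    def __post_init__(self):
        trees = tuple(self.trees)
        if not trees:
            raise PhyloError("empty selection")
        leaves = trees[0].leaves
        for t in trees:
            if t.leaves != leaves:
                raise LeafSetError("selection trees must share one leaf set")
        if self.source is not None:
            if len(self.source.trees) != len(trees):
                raise PhyloError("selection length differs from profile")
            for t, src in zip(trees, self.source.trees):
                if not displays_tree(t, src):
                    raise PhyloError(
                        "selection tree does not display its input tree"
                    )
        object.__setattr__(self, "trees", trees)

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def leaves(self) -> frozenset:
        return self.trees[0].leaves


@dataclass(frozen=True)
class ScoredSelection:
    """A selection with its completion, Maj+ tree and adjusted score."""

    selection: RepresentativeSelection
    completion: RepresentativeSelection
    adjusted_score: int
    candidate_tree: Tree


def _require_equal_leaves(trees: Sequence[Tree]):
    leaves = trees[0].leaves
    for t in trees:
        if t.leaves != leaves:
            raise LeafSetError("operation requires equal leaf sets")
    return leaves


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """The tree displaying exactly the splits present in every tree."""
    trees = list(trees)
    if not trees:
        raise PhyloError("strict consensus of an empty collection")
    leaves = _require_equal_leaves(trees)
    common = frozenset.intersection(*(t.splits for t in trees))
    return Tree(leaves, common, trees[0].rooted)


def majority_consensus(p: Profile) -> Tree:
    """Maj(P): all plenary splits displayed by more than k/2 trees."""
    if not p.is_consensus_profile:
        raise LeafSetError("majority consensus requires equal leaf sets")
    leaves = p.trees[0].leaves
    counts: dict = {}
    for t in p.trees:
        for s in t.splits:
            counts[s] = counts.get(s, 0) + 1
    keep = frozenset(s for s, c in counts.items() if 2 * c > p.k)
    return Tree(leaves, keep, p.rooted)


def profile_distance(t: Tree, p: Profile) -> int:
    """dist(T, P) = sum of Robinson-Foulds distances to the profile trees."""
    if any(t.leaves != ti.leaves for ti in p.trees):
        raise LeafSetError("tree leaf set differs from the profile's")
    return sum(rf_distance(t, ti) for ti in p.trees)


def median_score(p: Profile) -> int:
    """s(P) = dist(Maj(P), P); Maj(P) is a median tree for P."""
    return profile_distance(majority_consensus(p), p)


def _tally(x: Split, trees: Sequence[Tree]) -> tuple:
    nd = ni = 0
    for t in trees:
        if x in t.splits:
            nd += 1
        elif not split_compatible_with_tree(x, t):
            ni += 1
    return nd, ni


def tally_split(x: Split, p: Profile) -> SplitTally:
    """Count displayers and incompatible trees for a plenary split."""
    _require_equal_leaves(p.trees)
    if x.universe != p.trees[0].leaves:
        raise LeafSetError("tally_split needs a plenary split")
    nd, ni = _tally(x, p.trees)
    return SplitTally(x, nd, ni, p.k)


def _candidate_splits(trees: Sequence[Tree]) -> set:
    """Union of nontrivial splits over the trees.

    A split displayed by no tree has |K_X| = 0 and can never satisfy the
    strict Theorem-1 inequality, so this restriction is lossless.
    """
    out: set = set()
    for t in trees:
        out |= t.splits
    return out


def _maj_plus_splits(trees: Sequence[Tree]) -> frozenset:
    keep = []
    for x in _candidate_splits(trees):
        nd, ni = _tally(x, trees)
        if nd > ni:
            keep.append(x)
    return frozenset(keep)


def majority_plus_consensus(p: Profile | Sequence[Tree]) -> Tree:
    """Maj+(P) in the consensus setting.

    Returns the tree displaying exactly the plenary splits X with
    |K_X(P)| > |K-X(P)|.  These splits are pairwise compatible (two
    incompatible qualifying splits would force |K_X| > |K-X| >= |K_Y| >
    |K-Y| >= |K_X|); the Tree invariant re-asserts this.
    """
    trees = list(p.trees) if isinstance(p, Profile) else list(p)
    leaves = _require_equal_leaves(trees)
    return Tree(leaves, _maj_plus_splits(trees), trees[0].rooted)


def _completion_trees(trees: Sequence[Tree]) -> tuple:
    qualified = _maj_plus_splits(trees)
    out = []
    for t in trees:
        add = {
            x
            for x in qualified
            if x not in t.splits and split_compatible_with_tree(x, t)
        }
        out.append(Tree(t.leaves, t.splits | add, t.rooted) if add else t)
    return tuple(out)


def completion(r: RepresentativeSelection) -> RepresentativeSelection:
    """Insert every compatible majority-qualified split into each tree.

    Idempotent: qualified splits remain qualified after insertion (they
    gain displayers and lose no compatible trees) and no new split can
    start qualifying, so a second pass adds nothing.
    """
    return RepresentativeSelection(_completion_trees(r.trees), r.source)


def _lemma_score(trees: Sequence[Tree]) -> int:
    """Adjusted score computed directly from tallies (Lemma-1 route)."""
    total = 0
    for x in _candidate_splits(trees):
        nd, ni = _tally(x, trees)
        total += ni if nd > ni else nd
    return total


def adjusted_score(r: RepresentativeSelection | Sequence[Tree]) -> int:
    """s~(R), computed two ways and cross-checked.

    The tally route sums, per distinct split, the conflicting trees (for
    majority-qualified splits) or the displaying trees (otherwise).  The
    distance route sums Robinson-Foulds distances from the Maj+ consensus
    of R to the trees of the completion of R.  A mismatch would falsify
    the Lemma-1 / distance-identity bookkeeping and raises.
    """
    trees = list(r.trees) if isinstance(r, RepresentativeSelection) else list(r)
    _require_equal_leaves(trees)
    by_tally = _lemma_score(trees)
    maj_plus = majority_plus_consensus(trees)
    completed = _completion_trees(trees)
    by_dist = sum(rf_distance(maj_plus, t) for t in completed)
    if by_tally != by_dist:
        raise AssertionError(
            f"adjusted-score identity violated: tallies give {by_tally}, "
            f"distance to completion gives {by_dist}"
        )
    return by_tally


def score_selection(r: RepresentativeSelection) -> ScoredSelection:
    """Bundle a selection with completion, Maj+ tree and adjusted score."""
    comp = completion(r)
    tree = majority_plus_consensus(r.trees)
    score = adjusted_score(r)
    return ScoredSelection(r, comp, score, tree)
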