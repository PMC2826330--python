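"""Reducible-set data reduction for large supertree problems.

A taxon set S (1 < |S| < |L(P)|-1) is *reducible* when every input tree has
a full split -- trivial ones included -- whose one side is exactly
S intersect L(t).  Such an S behaves like a supertaxon: the profile splits
into a *reduced profile* (the subtree spanning S contracted to a fresh leaf
beta_S) and a *satellite profile* (everything outside S contracted to an
attachment leaf rho_S).  Optimal candidate trees for the two subproblems
splice into an optimal S-restricted candidate supertree, and the scores
add.  The result is the S-restricted majority-rule (+) supertree, which
need not equal Maj+(P): optimal candidate trees do not always display
reducible sets, so this is a heuristic trade of exactness for size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .phylo_core import (
    LeafSetError,
    PhyloError,
    Split,
    Tree,
    tree_from_splits,
)
from .consensus_plus import Profile
from .ilp_engine import SupertreeResult, majority_plus_supertree

__all__ = [
    "ReducibleSet",
    "is_reducible",
    "find_reducible_sets",
    "reduce_profile",
    "satellite_profile",
    "compress_satellite",
    "combine",
    "reduced_supertree",
    "DecompositionReport",
]


@dataclass(frozen=True)
class ReducibleSet:
    """A validated reducible taxon set with its per-tree witness sides."""

    taxa: frozenset
    witnesses: tuple = ()        # per tree: the side equal to S & L(t)

    def __post_init__(self):
        object.__setattr__(self, "taxa", frozenset(self.taxa))


def _witness_sides(t: Tree) -> set:
    """Sides of Spl0(t) that can match S & L(t).

    For rooted trees these are the clusters of every node -- singletons,
    internal clusters, and L(t) itself (the side below the root) -- plus
    the empty set; the root-containing sides can never equal a subset of
    L(P).  For unrooted trees both sides of every full split qualify.
    """
    sides = {frozenset(), t.leaves}
    for leaf in t.leaves:
        sides.add(frozenset({leaf}))
    for s in t.splits:
        sides.add(s.side_a)
        if not t.rooted:
            sides.add(s.side_b)
    if not t.rooted:
        for leaf in t.leaves:
            sides.add(t.leaves - {leaf})
    return sides


def _missing_witness(p: Profile, taxa: frozenset):
    """Index of the first tree without a witness split, or None."""
    for j, t in enumerate(p.trees):
        if (taxa & t.leaves) not in _witness_sides(t):
            return j
    return None


def is_reducible(s, p: Profile):
    """Check reducibility of ``s`` in ``p``; returns (bool, witnesses)."""
    s = frozenset(s)
    n = len(p.union_leaves)
    if not (1 < len(s) < n - 1):
        raise PhyloError(
            f"reducible-set size must satisfy 1 < |S| < {n - 1}; got {len(s)}"
        )
    if not s <= p.union_leaves:
        raise LeafSetError("candidate set contains unknown taxa")
    if _missing_witness(p, s) is not None:
        return False, None
    return True, tuple(s & t.leaves for t in p.trees)


def find_reducible_sets(p: Profile, user_sets=()) -> list:
    """Greedy selection of pairwise-disjoint reducible sets.

    Candidates are the nontrivial clusters of the (rooted) input trees,
    visited by decreasing size with canonical (sorted-label) tie-breaking.
    User-supplied sets are validated first and take precedence.
    """
    if not p.rooted:
        raise PhyloError(
            "greedy reducible-set search uses clusters; profile must be rooted"
        )
    n = len(p.union_leaves)
    accepted: list = []
    taken: frozenset = frozenset()
    for s in user_sets:
        s = frozenset(s)
        ok, wit = is_reducible(s, p)
        if not ok:
            raise PhyloError(f"user-supplied set {sorted(s)} is not reducible")
        if s & taken:
            raise PhyloError("user-supplied sets must be pairwise disjoint")
        accepted.append(ReducibleSet(s, wit))
        taken |= s
    candidates = {s.side_a for t in p.trees for s in t.splits}
    ordered = sorted(candidates, key=lambda c: (-len(c), tuple(sorted(c))))
    for cand in ordered:
        if not (1 < len(cand) < n - 1) or cand & taken:
            continue
        ok, wit = is_reducible(cand, p)
        if ok:
            accepted.append(ReducibleSet(cand, wit))
            taken |= cand
    return accepted


def _contract(t: Tree, region: frozenset, marker: str) -> Tree:
    """Contract the minimal subtree spanning ``region & L(t)`` to ``marker``.

    Valid when some full split of t has one side exactly the intersection;
    splits separating the region vanish, all others survive with the
    region replaced by the marker leaf.
    """
    inside = region & t.leaves
    if not inside:
        return t
    if marker in t.leaves:
        raise PhyloError(f"marker label {marker!r} collides with a taxon")
    new_leaves = (t.leaves - inside) | {marker}
    new_splits = []
    for s in t.splits:
        if inside <= s.side_a:
            a = (s.side_a - inside) | {marker}
            b = s.side_b
        elif not (s.side_a & inside):
            a = s.side_a
            b = (s.side_b - inside) | {marker}
        else:
            continue                      # the split separates the region
        ns = Split(a, b, t.rooted)
        if ns.is_nontrivial:
            new_splits.append(ns)
    return tree_from_splits(new_splits, new_leaves, t.rooted)


def reduce_profile(p: Profile, s: ReducibleSet, supertaxon: str) -> Profile:
    """Contract S to the supertaxon in every tree; drop degenerate trees.

    Trees left with fewer than two leaves (e.g. trees entirely inside S)
    carry no structure for the reduced problem and are removed.
    """
    j = _missing_witness(p, s.taxa)
    if j is not None:
        raise PhyloError(f"set is not reducible: tree {j} has no witness split")
    trees = []
    for t in p.trees:
        rt = _contract(t, s.taxa, supertaxon)
        if len(rt.leaves) >= 2:
            trees.append(rt)
    if not trees:
        raise PhyloError("reduction left no usable trees")
    return Profile(tuple(trees), p.rooted)


def satellite_profile(p: Profile, s: ReducibleSet, attachment: str) -> Profile:
    """Contract everything outside S to the attachment leaf in every tree.

    Trees disjoint from S collapse to the single leaf rho; trees entirely
    inside S are kept unchanged (there is nothing to contract).
    """
    j = _missing_witness(p, s.taxa)
    if j is not None:
        raise PhyloError(f"set is not reducible: tree {j} has no witness split")
    trees = []
    for t in p.trees:
        inside = s.taxa & t.leaves
        outside = t.leaves - inside
        if not inside:
            trees.append(Tree(frozenset({attachment}), frozenset(), p.rooted))
        elif not outside:
            trees.append(t)
        else:
            trees.append(_contract(t, outside, attachment))
    return Profile(tuple(trees), p.rooted)


def compress_satellite(sat: Profile, attachment: str):
    """Drop satellite trees carrying fewer than two satellite taxa.

    Returns the compressed Profile, or None when nothing informative
    remains (the satellite is then resolved as a star).
    """
    trees = [t for t in sat.trees if len(t.leaves - {attachment}) >= 2]
    return Profile(tuple(trees), sat.rooted) if trees else None


def combine(t_red: Tree, t_sat: Tree, supertaxon: str, attachment: str) -> Tree:
    """Splice a satellite tree into a reduced tree.

    The supertaxon leaf of the reduced tree is identified with the
    attachment leaf of the satellite tree and the degree-two junction is
    suppressed: in split terms the supertaxon expands to the satellite
    taxa and the attachment expands to the reduced-side taxa.  In rooted
    mode the root of the spliced tree is the reduced tree's root, so
    satellite splits are re-oriented relative to it.
    """
    if supertaxon not in t_red.leaves:
        raise PhyloError(f"reduced tree lacks supertaxon {supertaxon!r}")
    if attachment not in t_sat.leaves:
        raise PhyloError(f"satellite tree lacks attachment {attachment!r}")
    if t_red.rooted != t_sat.rooted:
        raise PhyloError("cannot combine rooted with unrooted trees")
    red_side = t_red.leaves - {supertaxon}
    sat_side = t_sat.leaves - {attachment}
    if red_side & sat_side:
        raise LeafSetError("reduced and satellite taxa overlap")
    leaves = red_side | sat_side
    new_splits = []
    for s in t_red.splits:
        if supertaxon in s.side_a:
            a = (s.side_a - {supertaxon}) | sat_side
            b = s.side_b
        else:
            a = s.side_a
            b = (s.side_b - {supertaxon}) | sat_side
        ns = Split(a, b, t_red.rooted)
        if ns.is_nontrivial:
            new_splits.append(ns)
    for s in t_sat.splits:
        if attachment in s.side_a:
            if t_sat.rooted:
                # the expanded side absorbs the reduced tree's root: the
                # cluster of the spliced split is the old root side
                a, b = s.side_b, (s.side_a - {attachment}) | red_side
            else:
                a = (s.side_a - {attachment}) | red_side
                b = s.side_b
        else:
            a = s.side_a
            b = (s.side_b - {attachment}) | red_side
        ns = Split(a, b, t_sat.rooted)
        if ns.is_nontrivial:
            new_splits.append(ns)
    return tree_from_splits(new_splits, leaves, t_red.rooted)


def _fresh_label(base: str, forbidden: frozenset) -> str:
    label = base
    while label in forbidden:
        label += "_"
    return label


def _pad_rooted(t: Tree, leaves: frozenset) -> Tree:
    """Extend a rooted tree to a larger leaf set, new taxa at the root."""
    if t.leaves == leaves:
        return t
    if not t.leaves <= leaves:
        raise LeafSetError("cannot pad: tree has taxa outside the target set")
    new = [Split(s.side_a, leaves - s.side_a, True) for s in t.splits]
    return tree_from_splits(new, leaves, True)


@dataclass
class DecompositionReport:
    """Per-subproblem sizes and scores of a divide-and-conquer run."""

    reduced: dict
    satellites: list = field(default_factory=list)
    total_score: int = 0
    exact: bool = False          # True only when no decomposition happened

    def as_dict(self) -> dict:
        return {
            "reduced": self.reduced,
            "satellites": self.satellites,
            "total_score": self.total_score,
            "s_restricted_only": not self.exact,
        }


def _subproblem_stats(result: SupertreeResult) -> dict:
    mx = result.matrix
    return {
        "n": mx.n,
        "m": mx.m,
        "k": mx.k,
        "U": mx.num_questions,
        "score": result.objective,
        "supertree": result.final_tree.newick(),
    }


def reduced_supertree(
    p: Profile,
    sets=None,
    user_sets=(),
    recursion_depth: int = 2,
    recurse_above_questions: int = 48,
    time_limit: float | None = None,
):
    """Divide-and-conquer pipeline: returns (tree, DecompositionReport).

    The reduced profile and each compressed satellite are solved
    independently through the exact pipeline (satellites whose matrices
    are still large are decomposed recursively), then spliced back.  With
    nonempty sets the output is the S-restricted majority-rule (+)
    supertree for the chosen sets -- a heuristic for Maj+(P) itself; with
    no sets it falls through to the exact pipeline.
    """
    if sets is None:
        sets = find_reducible_sets(p, user_sets=user_sets)
    if not sets:
        direct = majority_plus_supertree(p, time_limit)
        rep = DecompositionReport(
            reduced=_subproblem_stats(direct),
            total_score=direct.objective,
            exact=True,
        )
        return direct.final_tree, rep

    for a, b in itertools.combinations(sets, 2):
        if a.taxa & b.taxa:
            raise PhyloError("reducible sets must be pairwise disjoint")

    all_leaves = p.union_leaves
    markers = []
    forbidden = all_leaves
    for idx, rs in enumerate(sets, start=1):
        beta = _fresh_label(f"SUPERTAXON{idx}", forbidden)
        forbidden |= {beta}
        rho = _fresh_label(f"ATTACH{idx}", forbidden)
        forbidden |= {rho}
        markers.append((beta, rho))

    reduced = p
    for rs, (beta, _) in zip(sets, markers):
        reduced = reduce_profile(reduced, rs, beta)
    red_result = majority_plus_supertree(reduced, time_limit)
    red_leaves = (
        all_leaves - frozenset().union(*(rs.taxa for rs in sets))
    ) | {beta for beta, _ in markers}
    red_tree = red_result.final_tree
    if p.rooted:
        red_tree = _pad_rooted(red_tree, frozenset(red_leaves))
    elif red_tree.leaves != frozenset(red_leaves):
        raise PhyloError("reduction lost taxa; unrooted padding is undefined")

    report = DecompositionReport(reduced=_subproblem_stats(red_result))
    total = red_result.objective
    final = red_tree
    for rs, (beta, rho) in zip(sets, markers):
        sat = satellite_profile(p, rs, rho)
        comp = compress_satellite(sat, rho)
        target_leaves = frozenset(rs.taxa | {rho})
        if comp is None:
            sat_tree = Tree(target_leaves, frozenset(), p.rooted)
            sat_stats = {"n": len(target_leaves), "m": 0, "k": 0, "U": 0,
                         "score": 0, "supertree": sat_tree.newick()}
        else:
            if (
                recursion_depth > 0
                and _matrix_questions(comp) > recurse_above_questions
            ):
                sub_tree, sub_rep = reduced_supertree(
                    comp,
                    recursion_depth=recursion_depth - 1,
                    recurse_above_questions=recurse_above_questions,
                    time_limit=time_limit,
                )
                sat_tree = sub_tree
                sat_stats = {"nested": sub_rep.as_dict(),
                             "score": sub_rep.total_score}
                total += sub_rep.total_score
            else:
                sat_result = majority_plus_supertree(comp, time_limit)
                sat_tree = sat_result.final_tree
                sat_stats = _subproblem_stats(sat_result)
                total += sat_result.objective
            if p.rooted:
                sat_tree = _pad_rooted(sat_tree, target_leaves)
            elif sat_tree.leaves != target_leaves:
                raise PhyloError(
                    "satellite lost taxa; unrooted padding is undefined"
                )
        report.satellites.append({"taxa": sorted(rs.taxa), **sat_stats})
        final = combine(final, sat_tree, beta, rho)
    report.total_score = total
    return final, report


def _matrix_questions(p: Profile) -> int:
    from .matrix_encoding import build_matrix

    return build_matrix(p).num_questions
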