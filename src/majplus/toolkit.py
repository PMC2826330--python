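"""Support/conflict evaluation, property audits, and synthetic profiles.

The support/conflict labels follow the cluster-based reading used for
supertree evaluation: an input tree *supports* a supertree cluster S when
S restricted to the tree's taxa is one of its own nontrivial clusters,
*conflicts* when that restriction cannot coexist with the tree, and is
*irrelevant* otherwise (e.g. when fewer than two of its taxa are present).

The synthetic-profile generator draws a random binary model tree, then
derives each input tree by taxon subsampling (leaf deletion), random edge
contraction, and optional split-replacement perturbations.  With no
perturbations every input tree is a (possibly contracted) restriction of
one model tree, so the profile is compatible and the optimal adjusted
score is provably zero -- the main calibration point for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo_core import (
    PhyloError,
    Split,
    Tree,
    restrict,
    split_compatible_with_tree,
    tree_from_splits,
)
from .consensus_plus import Profile

__all__ = [
    "ProfileRecipe",
    "SupportReport",
    "support_conflict",
    "support_report",
    "cw_audit",
    "generate_profile",
]


# ---------------------------------------------------------------------------
# Support / conflict
# ---------------------------------------------------------------------------

def support_conflict(t: Tree, cluster, p: Profile) -> str:
    """Label one input tree against one supertree cluster.

    Returns "support", "conflict" or "irrelevant".  Defined for rooted
    profiles only (the notion is cluster-based).
    """
    if not p.rooted or not t.rooted:
        raise PhyloError("support/conflict labels are defined for rooted trees")
    cluster = frozenset(cluster)
    s_prime = cluster & t.leaves
    if len(s_prime) <= 1 or s_prime == t.leaves:
        return "irrelevant"
    if any(s.side_a == s_prime for s in t.splits):
        return "support"
    x = Split.cluster(s_prime, t.leaves)
    if not split_compatible_with_tree(x, t):
        return "conflict"
    return "irrelevant"


@dataclass
class SupportReport:
    """Labels for every (input tree, supertree cluster) pair."""

    clusters: list                       # sorted supertree clusters
    labels: list                         # labels[i][j]: tree i vs cluster j

    def marginals(self) -> list:
        out = []
        for j, c in enumerate(self.clusters):
            col = [row[j] for row in self.labels]
            out.append(
                {
                    "cluster": sorted(c),
                    "support": col.count("support"),
                    "conflict": col.count("conflict"),
                    "irrelevant": col.count("irrelevant"),
                }
            )
        return out

    def to_tsv(self) -> str:
        header = ["tree"] + [
            "{" + ",".join(sorted(c)) + "}" for c in self.clusters
        ]
        lines = ["\t".join(header)]
        for i, row in enumerate(self.labels):
            lines.append("\t".join([f"t{i + 1}"] + [lb[0] for lb in row]))
        margin = self.marginals()
        lines.append(
            "\t".join(["support"] + [str(m["support"]) for m in margin])
        )
        lines.append(
            "\t".join(["conflict"] + [str(m["conflict"]) for m in margin])
        )
        return "\n".join(lines) + "\n"


def support_report(supertree: Tree, p: Profile) -> SupportReport:
    clusters = sorted(
        (s.side_a for s in supertree.splits), key=lambda c: tuple(sorted(c))
    )
    labels = [
        [support_conflict(t, c, p) for c in clusters] for t in p.trees
    ]
    return SupportReport(clusters, labels)


# ---------------------------------------------------------------------------
# CW property audits
# ---------------------------------------------------------------------------

def _plenary_compatible(x: Split, t: Tree) -> bool:
    """Plenary split vs a tree on a subset of its taxa."""
    r = x.restricted(t.leaves)
    if r is None or not r.is_nontrivial:
        return True
    return split_compatible_with_tree(r, t)


def cw_audit(supertree: Tree, p: Profile) -> dict:
    """Audit the four display/compatibility guarantees of a supertree.

    cw1: displays every plenary split displayed by a majority of trees;
    cw2: compatible with every majority partial split (audited over the
         input trees' full splits);
    cw3: each supertree split is compatible with a majority of the trees;
    cw4: each supertree split extends some input tree's nontrivial split.
    """
    k = p.k
    trees = p.trees
    leaves = p.union_leaves

    cw1 = True
    plenary_counts: dict = {}
    for t in trees:
        if t.leaves == leaves:
            for s in t.splits:
                plenary_counts[s] = plenary_counts.get(s, 0) + 1
    for s, c in plenary_counts.items():
        if 2 * c > k and s not in supertree.splits:
            cw1 = False

    cw2 = True
    partial_counts: dict = {}
    for t in trees:
        for s in t.splits:
            if s.universe != leaves:
                partial_counts[s] = partial_counts.get(s, 0) + 1
    for s in list(partial_counts):
        # count displayers among all trees able to see the split
        c = sum(
            1
            for t in trees
            if s.universe <= t.leaves
            and s in restrict(t, s.universe).splits
        )
        if 2 * c > k and not split_compatible_with_tree(s, supertree):
            cw2 = False

    cw3 = all(
        2 * sum(1 for t in trees if _plenary_compatible(x, t)) > k
        for x in supertree.splits
    )

    cw4 = all(
        any(x.extends(s) for t in trees for s in t.splits)
        for x in supertree.splits
    )
    return {"cw1": cw1, "cw2": cw2, "cw3": cw3, "cw4": cw4}


# ---------------------------------------------------------------------------
# Synthetic profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileRecipe:
    """Fully-seeded description of a synthetic supertree problem."""

    n_taxa: int
    k_trees: int
    deletion_probability: float = 0.25
    contraction_probability: float = 0.1
    perturbation_count: int = 0
    seed: int = 0
    rooted: bool = True


def _random_binary_clusters(labels, rng) -> set:
    """Clusters of a random binary rooted tree via random joins."""
    nodes = [frozenset({lb}) for lb in labels]
    clusters = set()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)]
        nodes.append(merged)
        clusters.add(merged)
    clusters.discard(frozenset(labels))
    return clusters


def _random_model_tree(n: int, rooted: bool, rng) -> Tree:
    labels = [f"t{i + 1:02d}" for i in range(n)]
    leaves = frozenset(labels)
    clusters = _random_binary_clusters(labels, rng)
    if rooted:
        sps = [Split.cluster(c, leaves) for c in clusters if len(c) >= 2]
    else:
        sps = [
            Split(c, leaves - c, rooted=False)
            for c in clusters
            if 2 <= len(c) <= n - 2
        ]
    return tree_from_splits(sps, leaves, rooted)


def _random_split(leaves: frozenset, rooted: bool, rng) -> Split:
    labels = sorted(leaves)
    n = len(labels)
    hi = n - 1 if rooted else n - 2
    size = int(rng.integers(2, hi + 1))
    chosen = frozenset(rng.choice(labels, size=size, replace=False).tolist())
    if rooted:
        return Split.cluster(chosen, leaves)
    return Split(chosen, leaves - chosen, rooted=False)


def _perturb(t: Tree, count: int, rng) -> Tree:
    """Replace random splits by random alternatives compatible with the rest."""
    current = set(t.splits)
    for _ in range(count):
        if not current:
            break
        victim = sorted(current, key=_canon)[int(rng.integers(len(current)))]
        rest = current - {victim}
        for _attempt in range(30):
            cand = _random_split(t.leaves, t.rooted, rng)
            if not cand.is_nontrivial or cand in current:
                continue
            if all(cand.compatible_with(s) for s in rest):
                current = rest | {cand}
                break
        # on repeated failure the victim is simply kept
    return Tree(t.leaves, frozenset(current), t.rooted)


def _canon(s: Split):
    return (tuple(sorted(s.side_a)), tuple(sorted(s.side_b)))


def generate_profile(r: ProfileRecipe):
    """Draw (Profile, model Tree) deterministically from the recipe."""
    if r.n_taxa < 4:
        raise PhyloError("need at least 4 taxa")
    if r.k_trees < 1:
        raise PhyloError("need at least one tree")
    rng = np.random.default_rng(r.seed)
    model = _random_model_tree(r.n_taxa, r.rooted, rng)
    min_leaves = 3 if r.rooted else 4
    if r.n_taxa < min_leaves:
        raise PhyloError("too few taxa for the requested mode")
    labels = sorted(model.leaves)
    trees = []
    for _ in range(r.k_trees):
        keep = [lb for lb in labels if rng.random() >= r.deletion_probability]
        if len(keep) < min_leaves:
            missing = [lb for lb in labels if lb not in keep]
            extra = rng.choice(
                missing, size=min_leaves - len(keep), replace=False
            ).tolist()
            keep = sorted(keep + extra)
        t = restrict(model, frozenset(keep))
        if r.contraction_probability > 0 and t.splits:
            kept = frozenset(
                s
                for s in sorted(t.splits, key=_canon)
                if rng.random() >= r.contraction_probability
            )
            t = Tree(t.leaves, kept, t.rooted)
        if r.perturbation_count:
            t = _perturb(t, r.perturbation_count, rng)
        trees.append(t)
    return Profile(tuple(trees), r.rooted), model
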