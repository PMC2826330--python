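"""Split algebra: parsing, restriction, display, compatibility, distance."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from majplus import (
    IncompatibleSplitsError,
    LeafSetError,
    NewickError,
    Split,
    Tree,
    compatible,
    displays,
    displays_tree,
    parse_newick,
    restrict,
    rf_distance,
    split_compatible_with_tree,
    splits,
    tree_from_splits,
    write_newick,
)
from conftest import rt, ut


def usplit(a, b):
    return Split(frozenset(a), frozenset(b), rooted=False)


def cluster(c, universe):
    return Split.cluster(frozenset(c), frozenset(universe))


class TestParsing:
    def test_quartet_has_single_split(self):
        t = ut("((a,b),(c,d));")
        assert t.splits == {usplit("ab", "cd")}

    def test_star_has_no_splits(self):
        assert ut("(a,b,c);").is_star

    def test_rooted_cherry_cluster(self):
        t = rt("((a,b),c);")
        assert t.splits == {cluster("ab", "abc")}

    def test_rooted_caterpillar_clusters(self):
        t = rt("((((a,b),c),d),e);")
        expect = {
            cluster("ab", "abcde"),
            cluster("abc", "abcde"),
            cluster("abcd", "abcde"),
        }
        assert t.splits == expect

    def test_unrooted_five_taxon_tree(self):
        t = ut("((a,b),(c,d),e);")
        assert t.splits == {usplit("ab", "cde"), usplit("cd", "abe")}

    def test_branch_lengths_discarded(self):
        assert ut("((a:1,b:2):0.5,(c:1,d:1));") == ut("((a,b),(c,d));")

    def test_degree_two_chain_suppressed(self):
        assert ut("((((a,b)),(c,d)));") == ut("((a,b),(c,d));")

    @pytest.mark.parametrize(
        "bad", ["((a,b),(c,d)", "((a,a),b);", "", "();"]
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_roundtrip_is_deterministic(self):
        t = ut("((e,d),(b,a),c);")
        nw = write_newick(t)
        assert parse_newick(nw) == t
        assert write_newick(parse_newick(nw)) == nw


class TestSplitsAndRestrict:
    def test_spl0_includes_trivial_and_root_split(self):
        t = rt("((a,b),c);")
        full = splits(t, include_trivial=True)
        assert cluster("ab", "abc") in full
        assert cluster("abc", "abc") in full          # L(t) below the root
        assert all(len(s.side_a) >= 1 for s in full)

    def test_unrooted_star_spl_empty(self):
        assert splits(ut("(a,b,c,d,e);")) == frozenset()

    def test_restriction_kills_cut_splits(self):
        t = ut("((a,b),(c,d),e);")
        assert restrict(t, frozenset("abc")).is_star

    def test_restriction_identity(self):
        t = ut("((a,b),(c,d),e);")
        assert restrict(t, t.leaves) == t

    def test_quartet_restriction_to_triple_is_star(self):
        assert restrict(ut("((a,b),(c,d));"), frozenset("acd")).is_star

    def test_restriction_outside_leafset_raises(self):
        with pytest.raises(LeafSetError):
            restrict(ut("((a,b),(c,d));"), frozenset("abx"))

    def test_restrict_commutes_with_split_restriction(self):
        t = rt("(((a,b),(c,d)),((e,f),g));")
        sub = frozenset("abcef")
        direct = restrict(t, sub).splits
        via = {
            r
            for s in t.splits
            for r in [s.restricted(sub)]
            if r is not None and r.is_nontrivial
        }
        assert direct == via


class TestDisplayAndCompatibility:
    def test_displays_own_split(self):
        assert displays(ut("((a,b),(c,d));"), usplit("ab", "cd"))

    def test_does_not_display_crossing_split(self):
        assert not displays(ut("((a,b),(c,d));"), usplit("ac", "bd"))

    def test_displays_partial_split(self):
        t = ut("(((a,b),c),(d,e));")
        assert displays(t, usplit("ab", "de"))

    def test_displays_restrictions_of_itself(self):
        t = ut("(((a,b),c),(d,e));")
        for sub in (frozenset("abde"), frozenset("abc"), t.leaves):
            assert displays_tree(t, restrict(t, sub))

    def test_nested_splits_compatible(self):
        assert compatible({usplit("ab", "cde"), usplit("abc", "de")})

    def test_crossing_splits_incompatible(self):
        assert not compatible({usplit("ab", "cd"), usplit("ac", "bd")})

    def test_mixed_universe_raises(self):
        with pytest.raises(LeafSetError):
            compatible({usplit("ab", "cd"), usplit("ab", "ce")})

    def test_split_vs_tree_four_gametes(self):
        t = ut("((a,c),(b,d),e);")
        assert not split_compatible_with_tree(usplit("ab", "cde"), t)
        assert split_compatible_with_tree(usplit("ac", "bde"), t)

    def test_pairwise_agrees_with_exhaustive_refinement(self):
        """Four-gametes equals 'some binary tree displays both' on 6 taxa."""
        universe = frozenset("abcdef")
        split_sets = list(_all_binary_unrooted_splitsets(sorted(universe)))
        assert len(split_sets) == 105          # (2n-5)!! topologies
        rng = random.Random(20240917)
        sides = [
            frozenset(rng.sample(sorted(universe), rng.randint(2, 4)))
            for _ in range(40)
        ]
        for x_side, y_side in itertools.combinations(sides, 2):
            x = Split(x_side, universe - x_side, rooted=False)
            y = Split(y_side, universe - y_side, rooted=False)
            oracle = any(x in ss and y in ss for ss in split_sets)
            assert x.compatible_with(y) == oracle


def _insert_leaf_everywhere(node, x):
    """All ways of grafting leaf ``x`` onto an edge of a nested-tuple tree."""
    if isinstance(node, str):
        return [(node, x)]
    out = []
    for i, ch in enumerate(node):
        for new_ch in _insert_leaf_everywhere(ch, x):
            out.append(node[:i] + (new_ch,) + node[i + 1:])
        if isinstance(ch, tuple):          # graft onto the edge above ch
            out.append(node[:i] + ((ch, x),) + node[i + 1:])
    return out


def _leafset(node):
    if isinstance(node, str):
        return frozenset({node})
    return frozenset().union(*(_leafset(c) for c in node))


def _structure_splits(root, universe):
    out = set()

    def walk(node):
        if isinstance(node, str):
            return
        below = _leafset(node)
        s = Split(below, universe - below, rooted=False)
        if s.is_nontrivial:
            out.add(s)
        for c in node:
            walk(c)

    for c in root:
        walk(c)
    return frozenset(out)


def _all_binary_unrooted_splitsets(labels):
    """Split sets of every binary unrooted topology on ``labels``."""
    stack = [tuple(labels[:3])]
    for lb in labels[3:]:
        stack = [nt for t in stack for nt in _insert_leaf_everywhere(t, lb)]
    universe = frozenset(labels)
    seen = set()
    for t in stack:
        ss = _structure_splits(t, universe)
        if ss not in seen:
            seen.add(ss)
            yield ss


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t = ut("((a,b),(c,d),e);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets_distance_two(self):
        assert rf_distance(ut("((a,b),(c,d));"), ut("((a,c),(b,d));")) == 2

    def test_binary_vs_star(self):
        t = ut("(((a,b),c),(d,e));")
        star = Tree(t.leaves, frozenset(), rooted=False)
        assert rf_distance(t, star) == len(t.leaves) - 3

    def test_leafset_mismatch_raises(self):
        with pytest.raises(LeafSetError):
            rf_distance(ut("((a,b),(c,d));"), ut("((a,b),(c,e));"))

    def test_metric_on_random_triples(self):
        rng = random.Random(7)
        labels = list("abcdefg")
        trees = list(_sample_trees(labels, rng, 12))
        for t1, t2, t3 in itertools.combinations(trees, 3):
            d12 = rf_distance(t1, t2)
            assert d12 == rf_distance(t2, t1)
            assert (d12 == 0) == (t1 == t2)
            assert d12 <= rf_distance(t1, t3) + rf_distance(t3, t2)


def _sample_trees(labels, rng, count):
    from majplus import ProfileRecipe, generate_profile

    for seed in range(count):
        p, _ = generate_profile(
            ProfileRecipe(
                n_taxa=len(labels),
                k_trees=1,
                deletion_probability=0.0,
                contraction_probability=0.3,
                perturbation_count=1,
                seed=seed,
                rooted=False,
            )
        )
        yield p.trees[0]


class TestTreeFromSplits:
    def test_single_split_quartet(self):
        t = tree_from_splits({usplit("ab", "cd")}, frozenset("abcd"))
        assert t == ut("((a,b),(c,d));")

    def test_empty_set_is_star(self):
        t = tree_from_splits(set(), frozenset("abcde"))
        assert t.is_star

    def test_caterpillar_roundtrip(self):
        xs = {usplit("ab", "cde"), usplit("abc", "de")}
        t = tree_from_splits(xs, frozenset("abcde"))
        assert t.splits == xs

    def test_incompatible_input_raises(self):
        with pytest.raises(IncompatibleSplitsError):
            tree_from_splits(
                {usplit("ab", "cd"), usplit("ac", "bd")}, frozenset("abcd")
            )


@settings(derandomize=True, max_examples=60)
@given(
    st.integers(0, 10_000),
    st.integers(5, 9),
    st.booleans(),
)
def test_newick_roundtrip_random_trees(seed, n, rooted):
    """write_newick . parse_newick is the identity on generated trees."""
    from majplus import ProfileRecipe, generate_profile

    p, model = generate_profile(
        ProfileRecipe(
            n_taxa=n,
            k_trees=1,
            deletion_probability=0.2,
            contraction_probability=0.2,
            seed=seed,
            rooted=rooted,
        )
    )
    for t in (model, p.trees[0]):
        assert parse_newick(write_newick(t), rooted=rooted) == t


@settings(derandomize=True, max_examples=80)
@given(st.data())
def test_split_canonical_orientation(data):
    universe = frozenset("abcdefg")
    side = frozenset(
        data.draw(
            st.sets(st.sampled_from(sorted(universe)), min_size=1, max_size=6)
        )
    )
    if side == universe:
        side = side - {max(side)}
    x = Split(side, universe - side, rooted=False)
    y = Split(universe - side, side, rooted=False)
    assert x == y
    assert min(universe) in x.side_a
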