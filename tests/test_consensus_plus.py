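"""Strict/majority consensus, Maj+ characterization, completion, scoring."""

import itertools

import pytest

from majplus import (
    LeafSetError,
    Profile,
    RepresentativeSelection,
    Split,
    Tree,
    adjusted_score,
    completion,
    majority_consensus,
    majority_plus_consensus,
    median_score,
    profile_distance,
    rf_distance,
    score_selection,
    strict_consensus,
    tally_split,
)
from conftest import rprofile, rt, uprofile, ut


class TestStrictAndMajority:
    def test_strict_of_identical_trees(self):
        t = ut("((a,b),(c,d),e);")
        assert strict_consensus([t, t, t]) == t

    def test_strict_of_conflict_is_star(self, quartet_conflict):
        assert strict_consensus(list(quartet_conflict.trees)).is_star

    def test_strict_single_tree(self):
        t = rt("((a,b),c);")
        assert strict_consensus([t]) == t

    def test_strict_unequal_leafsets_raise(self):
        with pytest.raises(LeafSetError):
            strict_consensus([ut("((a,b),(c,d));"), ut("((a,b),(c,e));")])

    def test_majority_two_of_three(self):
        p = uprofile("((a,b),(c,d));", "((a,b),(c,d));", "(a,b,c,d);")
        assert majority_consensus(p) == ut("((a,b),(c,d));")

    def test_majority_of_total_disagreement_is_star(self, quartet_conflict):
        assert majority_consensus(quartet_conflict).is_star

    def test_majority_all_identical(self):
        p = rprofile("(((a,b),c),d);", "(((a,b),c),d);")
        assert majority_consensus(p) == rt("(((a,b),c),d);")


class TestMedian:
    def test_zero_at_profile_member(self):
        t = ut("((a,b),(c,d));")
        assert profile_distance(t, uprofile("((a,b),(c,d));")) == 0
        assert median_score(uprofile("((a,b),(c,d));")) == 0

    def test_conflicting_quartets_median_two(self, quartet_conflict):
        # exhaustive oracle: all three quartet topologies plus the star
        leaves = frozenset("abcd")
        options = [Tree(leaves, frozenset(), False)]
        for pair in (("a", "b"), ("a", "c"), ("a", "d")):
            side = frozenset(pair)
            options.append(
                Tree(leaves, frozenset({Split(side, leaves - side, False)}), False)
            )
        best = min(
            profile_distance(t, quartet_conflict) for t in options
        )
        assert best == 2
        assert median_score(quartet_conflict) == best


class TestTally:
    def test_displayed_by_all(self):
        p = uprofile("((a,b),(c,d),e);", "((a,b),(c,d),e);")
        x = Split(frozenset("ab"), frozenset("cde"), False)
        tal = tally_split(x, p)
        assert (tal.n_display, tal.n_incompatible) == (2, 0)
        assert tal.qualifies

    def test_mixed_profile_counts(self):
        p = uprofile("((a,b),(c,d),e);", "(a,b,c,d,e);", "((a,c),(b,d),e);")
        x = Split(frozenset("ab"), frozenset("cde"), False)
        tal = tally_split(x, p)
        assert (tal.n_display, tal.n_incompatible, tal.n_irrelevant) == (1, 1, 1)

    def test_star_profile_all_irrelevant(self):
        p = uprofile("(a,b,c,d,e);", "(a,b,c,d,e);")
        x = Split(frozenset("ab"), frozenset("cde"), False)
        tal = tally_split(x, p)
        assert (tal.n_display, tal.n_incompatible) == (0, 0)


class TestMajorityPlus:
    def test_minority_split_survives_irrelevant_trees(self):
        # one resolved tree against two stars: stars are irrelevant, not
        # conflicting, so both clusters qualify 1 > 0
        p = rprofile("(((a,b),c),d);", "(a,b,c,d);", "(a,b,c,d);")
        assert majority_plus_consensus(p) == rt("(((a,b),c),d);")

    def test_conflict_cancels(self, quartet_conflict):
        assert majority_plus_consensus(quartet_conflict).is_star

    def test_identical_trees_returned(self):
        p = uprofile("((a,b),(c,d),e);", "((a,b),(c,d),e);")
        assert majority_plus_consensus(p) == ut("((a,b),(c,d),e);")

    def test_output_splits_pairwise_compatible(self):
        from majplus import ProfileRecipe, compatible, generate_profile

        for seed in range(20):
            p, _ = generate_profile(
                ProfileRecipe(
                    n_taxa=7,
                    k_trees=4,
                    deletion_probability=0.0,
                    contraction_probability=0.3,
                    perturbation_count=2,
                    seed=seed,
                    rooted=bool(seed % 2),
                )
            )
            tree = majority_plus_consensus(p)
            assert compatible(tree.splits)

    def test_displays_all_majority_splits_cw1(self):
        from majplus import ProfileRecipe, generate_profile

        for seed in range(20):
            p, _ = generate_profile(
                ProfileRecipe(
                    n_taxa=6,
                    k_trees=5,
                    deletion_probability=0.0,
                    contraction_probability=0.2,
                    perturbation_count=1,
                    seed=seed,
                    rooted=True,
                )
            )
            out = majority_plus_consensus(p)
            counts = {}
            for t in p.trees:
                for s in t.splits:
                    counts[s] = counts.get(s, 0) + 1
            for s, c in counts.items():
                if 2 * c > p.k:
                    assert s in out.splits


class TestCompletion:
    def test_star_gains_qualifying_cluster(self):
        r = RepresentativeSelection((rt("((a,b),c);"), rt("(a,b,c);")))
        comp = completion(r)
        assert comp.trees[1] == rt("((a,b),c);")
        assert comp.trees[0] == rt("((a,b),c);")

    def test_conflict_left_unchanged(self, quartet_conflict):
        r = RepresentativeSelection(quartet_conflict.trees)
        assert completion(r).trees == r.trees

    def test_idempotent_and_monotone(self):
        from majplus import ProfileRecipe, generate_profile

        for seed in range(15):
            p, _ = generate_profile(
                ProfileRecipe(
                    n_taxa=6,
                    k_trees=3,
                    deletion_probability=0.0,
                    contraction_probability=0.4,
                    perturbation_count=1,
                    seed=seed,
                    rooted=bool(seed % 2),
                )
            )
            r = RepresentativeSelection(p.trees)
            once = completion(r)
            twice = completion(once)
            assert once.trees == twice.trees
            for before, after in zip(r.trees, once.trees):
                assert before.splits <= after.splits


class TestAdjustedScore:
    def test_identical_trees_zero(self):
        t = ut("((a,b),(c,d),e);")
        assert adjusted_score(RepresentativeSelection((t, t, t))) == 0

    def test_conflicting_quartets_two(self, quartet_conflict):
        assert adjusted_score(
            RepresentativeSelection(quartet_conflict.trees)
        ) == 2

    def test_two_against_one_cluster(self):
        r = RepresentativeSelection(
            (rt("((a,b),c);"), rt("((a,b),c);"), rt("((a,c),b);"))
        )
        # {a,b} qualifies (2 > 1) costing its one conflicter; {a,c} fails
        # (1 > 2 is false) costing its one displayer
        assert adjusted_score(r) == 2

    def test_distance_identity_on_random_selections(self):
        from majplus import ProfileRecipe, generate_profile

        for seed in range(15):
            p, _ = generate_profile(
                ProfileRecipe(
                    n_taxa=6,
                    k_trees=4,
                    deletion_probability=0.0,
                    contraction_probability=0.3,
                    perturbation_count=2,
                    seed=seed,
                    rooted=bool(seed % 2),
                )
            )
            scored = score_selection(RepresentativeSelection(p.trees))
            direct = sum(
                rf_distance(scored.candidate_tree, t)
                for t in scored.completion.trees
            )
            assert scored.adjusted_score == direct
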