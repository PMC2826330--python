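# Methods

## The model

A *profile* P = (t₁, …, t_k) is an ordered tuple of phylogenetic trees —
rooted or unrooted, polytomies allowed — whose leaf sets may differ and
partially overlap; ℒ(P) is their union, n = |ℒ(P)|.  Trees are handled
purely as split systems: an unrooted tree is its set of nontrivial full
splits, a rooted tree its set of nontrivial clusters (the root is implicit
and never materialized as a taxon; wherever a four-gametes or
same-split test is needed in rooted mode, the pattern (1,1) is treated as
always present, which is equivalent to carrying a shared root taxon).

The *span* ⟨t⟩ of an input tree is the set of plenary trees on ℒ(P)
displaying t.  A *representative selection* picks one member per input
tree; its *candidate supertree* is the majority-rule consensus of the
selection, and Maj⁺(P) is the strict consensus of the candidate supertrees
of all minimum-score selections.  Two facts drive the implementation:

1. **Consensus characterization.** For equal leaf sets, Maj⁺(P) displays
   exactly the plenary splits X with |K_X| > |K₋X|, where K_X is the set
   of trees displaying X and K₋X the set of trees incompatible with X.
   Any two such splits are automatically compatible (if they crossed,
   each displayer of one would conflict with the other, forcing
   |K_X| > |K₋X| ≥ |K_Y| > |K₋Y| ≥ |K_X|).  `majority_plus_consensus`
   implements this rule in polynomial time, drawing candidates from the
   union of input splits — a split displayed by nobody cannot qualify.

2. **Restricted span.** General spans allow refining polytomies, so the
   number of splits in a selection is unbounded.  It suffices to search
   the *restricted* span: each nontrivial split of t grows into a
   distinct plenary split (zero or more taxa added per side), i.e. a
   0/1 fill-in of the ?-cells of the MRP-style matrix M(P) whose per-tree
   columns remain pairwise compatible.  The *completion* of a selection
   inserts every compatible qualifying split into every tree; the
   *adjusted score* s̃ — the score of the completion — is computable
   directly from tallies (see README formula) and equals the RF distance
   from the Maj⁺ consensus of the selection to its completion.  The
   package always computes the score both ways and raises on any
   disagreement, so the identity is continuously asserted, not assumed.

## The integer program

All variables are binary.  F(r,c) is the fill of cell (r,c); fixed cells
are constants.  For each unordered column pair, indicator chains
Γ(r,p,q,ab) ⇔ (F(r,p)=a ∧ F(r,q)=b) and B(p,q,ab) ⇔ ∃r Γ recognize the
row patterns; C(p,q) ⇔ ¬(B₀₀∧B₀₁∧B₁₀∧B₁₁) is the four-gametes
compatibility test and is *forced* to 1 for same-tree pairs (that
constraint alone makes fills decode to valid trees).  E(p,q) recognizes
"same split": rooted, ¬B₀₁∧¬B₁₀; unrooted, equality or complementation
(δ₁ ∨ δ₂), which also makes the optimum invariant under the arbitrary 0/1
polarity of columns.  D(p) marks repeated splits (first-column convention);
S¹(i,j) = Σ_{ℓ ∈ tree j} E(i,ℓ) counts whether tree j carries split i
(an equality is sound because two columns of one tree can never fill
identically — their fixed rows already differ); S²(i,j) = ∧_ℓ C(i,ℓ) says
split i is compatible with tree j.  For columns of tree j itself both are
constant 1.  Then

    w(i) ⇔ Σ_j (S¹(i,j) + S²(i,j)) ≥ k+1        (⇔ |K_X| > |K₋X|)
    z(i,j) ⇔ w(i) ∧ ¬S²(i,j) ∧ ¬D(i)
    minimize  Σ_i (1 − w(i)) + Σ_{i,j} z(i,j)

A non-qualifying split pays 1 per column occurrence (= per displaying
tree); a qualifying split pays 1 per incompatible tree, once, at its
first column — exactly s̃ of the decoded selection.  Boolean operators are
linearized the standard way (x ⇔ a∧b as x ≤ a, x ≤ b, x ≥ a+b−1; the OR
dual; the threshold via q − k ≤ k·w and q ≥ (k+1)·w, both big-M-free since
q ≤ 2k).  Constant folding happens at emission: conjunctions over fixed
cells collapse before any variable is created, so low-? instances shrink
to (near-)constant models.  Because every auxiliary variable is defined by
a biconditional, the objective equals s̃ at *every* feasible point, not
just the optimum — which the verification step relies on.

**Verification.**  Maj⁺(P) is the strict consensus of all optimal
candidate trees, and every optimal candidate tree's splits come from
matrix columns.  For each nontrivial split A|B of the solved candidate
tree T*, the base model is re-solved with the objective capped at the
optimum, per-column match indicators μ(i) (pattern equality; in unrooted
mode equality or complement), and the prohibition w(i) + μ(i) ≤ 1.
Feasible ⇒ some optimum omits A|B ⇒ excluded; infeasible ⇒ retained.  A
sub-solve hitting the time limit marks the split *undecided* and the
result partial — undecided splits are reported, never silently included.

**Solver.**  Models are held in a small solver-agnostic container and
solved with HiGHS through `scipy.optimize.milp` (single-threaded and
deterministic); LP and free-MPS export is provided for external solvers.
An exhaustive fill-in enumerator (`brute_force_optimal`, bounded by
default at 2²⁰ worst case via a U ≤ 20 guard) serves as an independent
oracle; it shares only the matrix encoding with the ILP path.

## Data reduction

S ⊆ ℒ(P) is *reducible* when every input tree has a full split (trivial
splits and ℒ(t)|∅ included) with one side exactly S ∩ ℒ(t).  The *reduced
profile* contracts each tree's minimal subtree spanning S ∩ ℒ(t) to a
supertaxon leaf β_S; the *satellite profile* contracts everything outside
S to an attachment leaf ρ_S; the *compressed* satellite drops trees left
with fewer than two satellite taxa.  Optimal candidate trees of the two
subproblems splice (β_S and ρ_S identified, the degree-2 junction
suppressed) into an optimal *S-restricted* candidate supertree, and the
scores add.  The greedy search considers input-tree clusters by
decreasing size (ties broken in sorted-label order, a determinism choice
the original description leaves open), accepting disjoint validated sets;
user-specified clades enter first and are validated identically.  The
spliced output is the S-restricted majority-rule (+) supertree, *not*
necessarily Maj⁺(P) — optimal candidate trees need not display reducible
sets — and the run report says so.

Degenerate cases are handled symmetrically: a contracted tree left with
fewer than two leaves is dropped from the reduced profile (the published
description only notes the satellite analogue); taxa of S that survive
only in dropped satellite trees are re-attached at the satellite root in
rooted mode (the only mode the greedy pipeline supports, since its
candidates are clusters).  Nested decomposition recurses on satellites
whose matrices still carry more than `recurse_above_questions` (default
48) ?-cells.  For the S-restricted cross-check, `build_ilp` optionally
constrains every filled column to be four-gametes-compatible with the
fixed split S | rest, which confines the search to selections that can
all display it.

## Synthetic profiles

`generate_profile` emulates the regime the method targets: a uniform
random-join binary model tree on n taxa; per input tree, independent leaf
deletion (default probability 0.25, floored at 3 leaves rooted / 4
unrooted — below that a tree carries no split information), independent
edge contraction (default 0.1, producing the polytomies real consensus
inputs have), and optionally `perturbation_count` split replacements
(a random nontrivial split swapped for a random alternative compatible
with the remainder — deliberately simpler than SPR, but sufficient to
create genuine conflict).  Everything is driven by one seed.  With zero
perturbations every input is a contracted restriction of one model tree,
so the profile is compatible and the true optimum is exactly 0 — the main
external calibration point.  What the generator does *not* emulate:
model-based sequence noise, correlated taxon sampling across loci, or
rogue-taxon behavior; passing tests therefore certify the combinatorial
machinery, not robustness to realistic gene-tree error.

## Numerical and design choices

* Split orientation is canonical (lexicographically smallest taxon on the
  stored first side; clusters stored as-is in rooted mode), so split and
  tree equality are plain set equality and all outputs are reproducible;
  the Newick writer sorts children.
* Column order is input order across trees and canonical within a tree;
  the published formulation leaves it "fixed but arbitrary".
* Majority thresholds are strict (> k/2; tallies tie ⇒ split excluded),
  for even k as well.
* Trees contributing no nontrivial splits stay in the profile — they
  change k and hence the thresholds — but add no columns.
* Test-scale problem sizes: oracle comparisons run on n ≤ 7, k ≤ 4
  profiles with at most 14 ?-cells, where exhaustive enumeration of all
  fill-ins is comfortable; the ILP itself is exercised far beyond that by
  the decomposition tests.

## Known limitations

* Model size grows as O(nm²) in the total split count m; beyond a few
  hundred columns solve times climb quickly, and the reduction heuristic
  becomes the practical path.
* The reduction pipeline's output is exact only relative to the chosen
  reducible sets; no attempt is made to enumerate all optimal ILP
  solutions directly.
* Support/conflict reporting and greedy reducible-set discovery are
  defined for rooted profiles; unrooted decomposition is possible through
  explicitly supplied sets only, and padding lost taxa back in is defined
  only in rooted mode.
* Branch lengths and support values are read and discarded; the method is
  topology-only by construction.
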