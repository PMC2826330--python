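# majplus — majority-rule (+) supertrees by exact integer programming

`majplus` assembles a collection of phylogenetic trees with partially
overlapping taxon sets into a single **majority-rule (+) supertree**.  The
method extends the majority-rule consensus — the median tree under the
Robinson–Foulds (RF) distance — to the supertree setting: each input tree
*t* is expanded to a plenary tree on the full taxon set ℒ(P) by grafting in
its missing taxa, the expansion is chosen to minimize the total RF distance
from the expanded trees to their median, and the returned supertree
Maj⁺(P) is the strict consensus of all *optimal candidate supertrees*
(medians of optimal expansions).  The output inherits strong guarantees:
it displays every majority plenary split, is compatible with every
majority partial split, every one of its splits is compatible with a
majority of the input trees, and every one of its splits extends a split
actually present in some input tree — no unsupported groups, in contrast
to matrix representation with parsimony (MRP).

Finding an optimal candidate supertree is NP-hard, but the search can be
confined to the *restricted span*: fill in the MRP-style 0/1/? matrix
M(P), one column per input split, so that each tree's filled columns stay
pairwise compatible (the four-gametes condition).  Over such fill-ins G
the **adjusted score**

    s̃(G) = Σ_X  |K₋X(G)|  if |K_X(G)| > |K₋X(G)|   else   |K_X(G)|

(K_X = trees displaying split X, K₋X = trees incompatible with X) equals
the RF distance from the Maj⁺ consensus of G to its completion, and its
minimum over the restricted span yields Maj⁺(P).  `majplus` encodes this
minimization as a polynomial-size integer linear program (solved with
HiGHS via SciPy), then certifies each split of the optimal candidate tree
by a per-split feasibility ILP: a split belongs to Maj⁺(P) exactly when no
equally-good solution omits it.  A **reducible-set** decomposition
heuristic splits large profiles into a reduced profile plus independent
satellite profiles whose scores provably add, extending the method's reach
at the cost of restricting the output to supertrees displaying the chosen
clades.

## Worked example

Put three rooted trees in `example.nwk` that agree on the clade
`((a,b),c)` but disagree about how `d…g` attach:

```
(((a,b),c),((d,e),f));
((a,(b,c)),(d,g));
(((a,b),c),(f,g));
```

```sh
$ majplus supertree example.nwk --report report.json
(((a,b),c),(d,e,f,g));
```

The JSON report (also echoed to stderr) shows what happened:

```json
{
  "n": 7, "m": 10, "k": 3, "U": 16, "percent_U": 22.86,
  "objective": 2,
  "candidate_tree": "(((a,b),c),((d,e,g),f));",
  "supertree": "(((a,b),c),(d,e,f,g));",
  "splits_retained": 3, "splits_excluded": 1, "splits_undecided": 0
}
```

The matrix has 10 columns and 16 `?` cells; the best expansion costs an
adjusted score of 2: cluster `{a,b}` qualifies (two trees display it, one
conflicts) and pays 1 for its conflicting tree, while tree 2's minority
cherry `{b,c}` fails its tally and pays 1 for its single displayer.  One
optimal candidate tree
groups `{d,e,g}`, but the verification step finds an equally good solution
without that cluster, so it is excluded and Maj⁺(P) keeps exactly the
three certified clusters `{a,b}`, `{a,b,c}` and `{d,e,f,g}`.

Other entry points:

```sh
majplus consensus trees.nwk          # equal leaf sets: polynomial Maj+ rule
majplus score selection.nwk          # adjusted score of plenary trees
majplus supertree big.nwk --reduce   # reducible-set decomposition heuristic
majplus report-support super.nwk trees.nwk   # support/conflict table
majplus simulate --n-taxa 20 --k-trees 5 --seed 1   # synthetic profiles
```

The same functionality is available as a library (`majplus.Profile`,
`majplus.majority_plus_supertree`, `majplus.reduced_supertree`, …); models
can be exported in LP/MPS format for external solvers.

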