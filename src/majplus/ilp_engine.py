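"""Exact optimization of the adjusted score over the restricted span.

The decision variables are the '?' cells of M(P) (fill-in variables F).
Auxiliary 0/1 variables tie the fill to the objective:

  Gamma(r,p,q,ab) <=> F(r,p) = a and F(r,q) = b
  B(p,q,ab)       <=> some row shows pattern ab in columns p,q
  C(p,q)          <=> columns p,q compatible (four gametes); forced to 1
                      for columns of the same input tree
  E(p,q)          <=> columns p,q carry the same plenary split
                      (rooted: no 01/10 pattern; unrooted: equal via
                      delta1 or complementary via delta2)
  D(p)            <=> column p repeats a split of a smaller-index column
  S1(i,j)         =   number of tree-j columns equal to column i
                      (0 or 1: duplicate fills within a tree are impossible)
  S2(i,j)         <=> column i's split is compatible with tree j
  w(i)            <=> sum_j (S1 + S2) > k, i.e. displayers outnumber
                      incompatible trees for column i's split
  z(i,j)          <=> w(i) and not S2(i,j) and not D(i)

and the objective  minimize  sum_i (1 - w_i) + sum_{i,j} z_ij  equals the
adjusted score of the decoded selection: each non-qualifying split pays one
per occurrence (= per displaying tree), each qualifying split pays one per
incompatible tree, counted once at its first column.

In rooted mode the implicit root contributes a constant (1,1) row, so B11
is treated as always true; no root row is materialized.

Verification of the final supertree re-solves the model once per candidate
split with the objective capped at the optimum and that split forbidden
from qualifying; infeasibility certifies membership in the strict consensus
of all optimal candidate supertrees.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np

from ._model import INF, LinExpr, ModelBuilder, SolveStatus, as_expr, bool_const
from .phylo_core import PhyloError, Split, Tree, tree_from_splits
from .consensus_plus import (
    Profile,
    RepresentativeSelection,
    ScoredSelection,
    adjusted_score,
    majority_plus_consensus,
    score_selection,
    strict_consensus,
    _lemma_score,
)
from .matrix_encoding import (
    QMARK,
    FillIn,
    SplitMatrix,
    build_matrix,
    decode,
    enumerate_fillins,
)

__all__ = [
    "IlpModel",
    "SolveResult",
    "VerificationReport",
    "build_ilp",
    "solve",
    "verify_splits",
    "brute_force_optimal",
    "majority_plus_supertree",
    "SupertreeResult",
    "nominal_variable_counts",
]

_PATTERNS = ((0, 0), (0, 1), (1, 0), (1, 1))


def nominal_variable_counts(m: int, n: int, k: int) -> dict:
    """Variable family sizes before constant propagation."""
    return {
        "F": m * n,
        "Gamma": 2 * m * (m - 1) * n,
        "B": 2 * m * (m - 1),
        "delta": m * (m - 1),          # two per unordered pair (unrooted)
        "E": m * (m - 1) // 2,
        "C": m * (m - 1) // 2,
        "D": m,
        "S1": m * k,
        "S2": m * k,
        "w": m,
        "z": m * k,
    }


@dataclass
class IlpModel:
    """The built model plus handles needed for decoding and augmentation."""

    builder: ModelBuilder
    matrix: SplitMatrix
    F: dict                      # (row, col) -> Bool
    w: list                      # per column Bool
    objective: LinExpr
    same_split: dict = field(default_factory=dict)   # (p,q) p<q -> Bool (E)

    @property
    def num_variables(self) -> int:
        return self.builder.num_vars

    @property
    def num_constraints(self) -> int:
        return self.builder.num_constraints

    def to_lp(self) -> str:
        return self.builder.to_lp(self.objective)

    def to_mps(self) -> str:
        return self.builder.to_mps(self.objective)


@dataclass
class SolveResult:
    status: str
    objective: int | None
    fillin: FillIn | None
    scored: ScoredSelection | None
    solve_seconds: float
    solver_log: str = ""


@dataclass
class VerificationReport:
    """Per-split feasibility outcome and the resulting Maj+(P)."""

    retained: list               # splits proven present in Maj+(P)
    excluded: list               # splits some optimal candidate tree omits
    undecided: list              # sub-ILP timeouts; reported, never included
    final_tree: Tree
    partial: bool
    verify_seconds: float


def _lit(mb: ModelBuilder, b, a: int):
    return b if a == 1 else mb.NOT(b)


def _cell_bool(mb: ModelBuilder, F: dict, entries, r: int, c: int):
    v = entries[r, c]
    if v == QMARK:
        return F[(r, c)]
    return bool(v == 1)


def build_ilp(mx: SplitMatrix, require_compatible_with=()) -> IlpModel:
    """Emit the full model for a split matrix.

    Fixed matrix entries are propagated while building: pattern indicators
    over two fixed cells fold to constants, which in turn collapse B, C, E
    and downstream variables, so consensus-like (low-U) instances shrink to
    almost nothing.

    ``require_compatible_with`` takes taxon subsets S of L(P); for each,
    every filled column is constrained to be compatible (four gametes)
    with the fixed plenary split S | rest.  This restricts the search to
    selections whose trees can all display that split, the S-restricted
    setting of the data-reduction analysis.
    """
    mb = ModelBuilder()
    n, m, k = mx.n, mx.m, mx.k
    rooted = mx.rooted
    entries = mx.entries
    col_tree = [tj for tj, _ in mx.col_map]

    F: dict = {}
    for c in range(m):
        for r in range(n):
            if entries[r, c] == QMARK:
                F[(r, c)] = mb.add_binary(f"F_{r}_{c}")

    cell = lambda r, c: _cell_bool(mb, F, entries, r, c)

    C: dict = {}
    E: dict = {}
    for p, q in itertools.combinations(range(m), 2):
        same_tree = col_tree[p] == col_tree[q]
        B = {}
        for a, b in _PATTERNS:
            gammas = [
                mb.AND(
                    [_lit(mb, cell(r, p), a), _lit(mb, cell(r, q), b)],
                    f"G_{r}_{p}_{q}_{a}{b}",
                )
                for r in range(n)
            ]
            B[(a, b)] = mb.OR(gammas, f"B_{p}_{q}_{a}{b}")
        four = [B[(0, 0)], B[(0, 1)], B[(1, 0)]]
        if not rooted:
            four.append(B[(1, 1)])
        if same_tree:
            # columns of one input tree must stay compatible: C(p,q) = 1
            mb.forbid_all(four, f"compat_{p}_{q}")
            C[(p, q)] = True
        else:
            C[(p, q)] = mb.NOT(mb.AND(four, f"nC_{p}_{q}"))
            if rooted:
                E[(p, q)] = mb.AND(
                    [mb.NOT(B[(0, 1)]), mb.NOT(B[(1, 0)])], f"E_{p}_{q}"
                )
            else:
                d1 = mb.AND(
                    [mb.NOT(B[(0, 1)]), mb.NOT(B[(1, 0)])], f"d1_{p}_{q}"
                )
                d2 = mb.AND(
                    [mb.NOT(B[(0, 0)]), mb.NOT(B[(1, 1)])], f"d2_{p}_{q}"
                )
                E[(p, q)] = mb.OR([d1, d2], f"E_{p}_{q}")

    for si, S in enumerate(require_compatible_with):
        S = frozenset(S)
        in_rows = [r for r, tx in enumerate(mx.row_taxa) if tx in S]
        out_rows = [r for r, tx in enumerate(mx.row_taxa) if tx not in S]
        for i in range(m):
            # four-gametes patterns of column i against the S-indicator
            o_in0 = mb.OR([mb.NOT(cell(r, i)) for r in in_rows], f"R{si}_in0_{i}")
            o_in1 = mb.OR([cell(r, i) for r in in_rows], f"R{si}_in1_{i}")
            o_out0 = mb.OR([mb.NOT(cell(r, i)) for r in out_rows], f"R{si}_out0_{i}")
            four = [o_in0, o_in1, o_out0]
            if not rooted:
                four.append(mb.OR([cell(r, i) for r in out_rows], f"R{si}_out1_{i}"))
            mb.forbid_all(four, f"Scompat_{si}_{i}")

    # D(p): column p repeats the split of an earlier column
    D = []
    for p in range(m):
        prior = [
            E[(q, p)]
            for q in range(p)
            if col_tree[q] != col_tree[p]
        ]
        D.append(mb.OR(prior, f"D_{p}") if prior else False)

    tree_cols = [mx.tree_columns(j) for j in range(k)]

    S1: list = [[None] * k for _ in range(m)]
    S2: list = [[None] * k for _ in range(m)]
    for i in range(m):
        for j in range(k):
            if col_tree[i] == j:
                S1[i][j] = True       # the split sits in its own tree
                S2[i][j] = True
                continue
            es = [E[tuple(sorted((i, l)))] for l in tree_cols[j]]
            S1[i][j] = mb.sum_indicator(es, f"S1_{i}_{j}") if es else False
            cs = [C[tuple(sorted((i, l)))] for l in tree_cols[j]]
            S2[i][j] = mb.AND(cs, f"S2_{i}_{j}") if cs else True

    w = []
    for i in range(m):
        total = LinExpr.constant(0.0)
        for j in range(k):
            total = total + as_expr(S1[i][j]) + as_expr(S2[i][j])
        w.append(mb.threshold(total, k, 2 * k, f"w_{i}"))

    objective = LinExpr.constant(0.0)
    for i in range(m):
        objective = objective + (LinExpr.constant(1.0) - as_expr(w[i]))
        for j in range(k):
            z = mb.AND(
                [w[i], mb.NOT(S2[i][j]), mb.NOT(D[i])], f"z_{i}_{j}"
            )
            objective = objective + as_expr(z)

    return IlpModel(mb, mx, F, w, objective, same_split=E)


def _fill_from_solution(model: IlpModel, x) -> FillIn:
    entries = model.matrix.entries.copy()
    for (r, c), b in model.F.items():
        e = as_expr(b)
        ((i, _),) = e.coeffs
        entries[r, c] = int(x[i])
    return FillIn(entries, model.matrix)


def solve(
    model: IlpModel, time_limit: float | None = None
) -> SolveResult:
    """Minimize the adjusted score; decode and cross-check the optimum.

    The solver objective is recomputed combinatorially from the decoded
    selection; disagreement is a hard internal error (it would mean the
    linearization does not implement the score).
    """
    t0 = time.perf_counter()
    status, x, obj = model.builder.solve(model.objective, time_limit)
    dt = time.perf_counter() - t0
    if status == SolveStatus.TIMEOUT:
        return SolveResult(status, None, None, None, dt)
    if status == SolveStatus.INFEASIBLE:
        raise RuntimeError(
            "base supertree model reported infeasible; this cannot happen "
            "for a valid split matrix"
        )
    fill = _fill_from_solution(model, x)
    selection = decode(fill)
    scored = score_selection(selection)
    objective = int(round(obj))
    if scored.adjusted_score != objective:
        raise RuntimeError(
            f"solver objective {objective} != combinatorial adjusted score "
            f"{scored.adjusted_score}; the model does not encode the score"
        )
    return SolveResult(SolveStatus.OPTIMAL, objective, fill, scored, dt)


def _column_pattern(x: Split, mx: SplitMatrix) -> list:
    """Fixed 0/1 pattern of a plenary split in matrix row order."""
    if mx.rooted:
        return [0 if tx in x.side_a else 1 for tx in mx.row_taxa]
    pivot = min(mx.row_taxa)
    side1 = x.side_a if pivot in x.side_a else x.side_b
    return [1 if tx in side1 else 0 for tx in mx.row_taxa]


def verify_splits(
    model: IlpModel,
    result: SolveResult,
    time_limit: float | None = None,
) -> VerificationReport:
    """Decide, per split of the optimal candidate tree, membership in Maj+(P).

    For each nontrivial split A|B of T* the base model is augmented with
    (a) objective <= optimum, (b) per-column match indicators mu(i) that
    recognize a fill of column i equal to the pattern of A|B (rooted:
    equality; unrooted: equality or complement), and (c) the prohibition
    w(i) + mu(i) <= 1.  Feasibility exhibits an optimal candidate supertree
    omitting A|B; infeasibility proves every optimum displays it.
    """
    if result.status != SolveStatus.OPTIMAL:
        raise PhyloError("verification requires an optimal base solution")
    t0 = time.perf_counter()
    mx = model.matrix
    tstar = result.scored.candidate_tree
    retained, excluded, undecided = [], [], []
    for x in sorted(tstar.splits, key=lambda s: (sorted(s.side_a), sorted(s.side_b))):
        mb = model.builder.copy()
        mb.add_range(model.objective, -INF, float(result.objective))
        pattern = _column_pattern(x, mx)
        for i in range(mx.m):
            cells = [
                _cell_bool(mb, model.F, mx.entries, r, i) for r in range(mx.n)
            ]
            match = mb.AND(
                [_lit(mb, cells[r], pattern[r]) for r in range(mx.n)],
                f"mA_{i}",
            )
            if mx.rooted:
                mu = match
            else:
                comp = mb.AND(
                    [_lit(mb, cells[r], 1 - pattern[r]) for r in range(mx.n)],
                    f"mB_{i}",
                )
                mu = mb.OR([match, comp], f"mu_{i}")
            mb.forbid_all([model.w[i], mu], f"noqual_{i}")
        status, _, _ = mb.solve(LinExpr.constant(0.0), time_limit)
        if status == SolveStatus.INFEASIBLE:
            retained.append(x)
        elif status == SolveStatus.OPTIMAL:
            excluded.append(x)
        else:
            undecided.append(x)
    final = tree_from_splits(retained, tstar.leaves, tstar.rooted)
    return VerificationReport(
        retained,
        excluded,
        undecided,
        final,
        partial=bool(undecided),
        verify_seconds=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_optimal(p: Profile, max_questions: int = 20):
    """Exhaustive optimum over the restricted span.

    Enumerates every fill-in of M(P), scores each decoded selection with
    the tally formula, and returns (minimum adjusted score, all optimal
    selections, Maj+(P) as the strict consensus of their Maj+ trees).
    Only viable for small U; this is the ground truth the ILP is checked
    against.
    """
    mx = build_matrix(p)
    best = None
    argmin: list = []
    for fill in enumerate_fillins(mx, max_questions):
        selection = decode(fill)
        s = _lemma_score(selection.trees)
        if best is None or s < best:
            best = s
            argmin = [selection]
        elif s == best:
            argmin.append(selection)
    maj_trees = [majority_plus_consensus(sel.trees) for sel in argmin]
    final = strict_consensus(maj_trees)
    return best, argmin, final


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class SupertreeResult:
    """Full pipeline output: optimum, candidate tree, verified Maj+(P)."""

    profile: Profile
    matrix: SplitMatrix
    model: IlpModel | None
    solve_result: SolveResult
    verification: VerificationReport
    final_tree: Tree

    @property
    def objective(self) -> int:
        return self.solve_result.objective

    def report(self) -> dict:
        mx = self.matrix
        return {
            "n": mx.n,
            "m": mx.m,
            "k": mx.k,
            "U": mx.num_questions,
            "percent_U": round(mx.percent_questions, 2),
            "variables": self.model.num_variables if self.model else 0,
            "constraints": self.model.num_constraints if self.model else 0,
            "objective": self.objective,
            "candidate_tree": self.solve_result.scored.candidate_tree.newick(),
            "supertree": self.final_tree.newick(),
            "splits_retained": len(self.verification.retained),
            "splits_excluded": len(self.verification.excluded),
            "splits_undecided": len(self.verification.undecided),
            "solve_seconds": round(self.solve_result.solve_seconds, 3),
            "verify_seconds": round(self.verification.verify_seconds, 3),
        }


def majority_plus_supertree(
    p: Profile,
    time_limit: float | None = None,
    require_compatible_with=(),
) -> SupertreeResult:
    """Build M(P), solve the ILP, verify every split, return Maj+(P)."""
    mx = build_matrix(p)
    model = build_ilp(mx, require_compatible_with=require_compatible_with)
    res = solve(model, time_limit)
    if res.status != SolveStatus.OPTIMAL:
        raise RuntimeError("optimization timed out; raise the time limit")
    report = verify_splits(model, res, time_limit)
    return SupertreeResult(p, mx, model, res, report, report.final_tree)
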