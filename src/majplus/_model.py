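"""A small solver-agnostic 0/1 linear model container.

Everything the supertree ILP needs: binary variables, range constraints
``lb <= a.x + c <= ub``, a linear objective, Boolean glue (NOT / AND / OR /
forbid-all / threshold) with constant folding, solving through scipy's
HiGHS interface, and LP / free-MPS text export for external solvers.

Constant folding is what implements the "fixed entries propagate" behavior:
a conjunction over literals with known values collapses to a constant or to
a single literal before any variable or constraint is emitted, so the model
that reaches the solver is already pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

__all__ = ["LinExpr", "ModelBuilder", "SolveStatus"]

INF = float("inf")


@dataclass(frozen=True)
class LinExpr:
    """An affine expression over model variables: sum(coeffs) + const."""

    coeffs: tuple = ()          # tuple of (var_index, coefficient)
    const: float = 0.0

    @staticmethod
    def var(i: int) -> "LinExpr":
        return LinExpr(((i, 1.0),), 0.0)

    @staticmethod
    def constant(c: float) -> "LinExpr":
        return LinExpr((), float(c))

    def _as_dict(self) -> dict:
        d: dict = {}
        for i, c in self.coeffs:
            d[i] = d.get(i, 0.0) + c
        return {i: c for i, c in d.items() if c != 0.0}

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return LinExpr(self.coeffs, self.const + other)
        merged = dict(self._as_dict())
        for i, c in other.coeffs:
            merged[i] = merged.get(i, 0.0) + c
        merged = {i: c for i, c in merged.items() if c != 0.0}
        return LinExpr(tuple(sorted(merged.items())), self.const + other.const)

    __radd__ = __add__

    def __neg__(self):
        return LinExpr(tuple((i, -c) for i, c in self.coeffs), -self.const)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-other)

    def __mul__(self, s: float):
        return LinExpr(tuple((i, c * s) for i, c in self.coeffs), self.const * s)

    __rmul__ = __mul__

    @property
    def is_constant(self) -> bool:
        return not self._as_dict()


Bool = object  # documentation alias: a Bool is True, False, or a 0/1 LinExpr


def as_expr(b) -> LinExpr:
    if b is True:
        return LinExpr.constant(1.0)
    if b is False:
        return LinExpr.constant(0.0)
    return b


def bool_const(b):
    """Return the Python bool when ``b`` is a constant, else None."""
    if isinstance(b, bool):
        return b
    e = as_expr(b)
    if e.is_constant:
        return e.const >= 0.5
    return None


@dataclass
class _Constraint:
    coeffs: dict
    lb: float
    ub: float
    name: str = ""


class InfeasibleConstant(Exception):
    """A constraint with no free variables is violated."""


class SolveStatus:
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    TIMEOUT = "timeout"


class ModelBuilder:
    """Accumulates binary variables and linear constraints."""

    def __init__(self):
        self.var_names: list = []
        self.constraints: list = []
        self.constant_infeasible: bool = False

    def copy(self) -> "ModelBuilder":
        mb = ModelBuilder()
        mb.var_names = list(self.var_names)
        mb.constraints = [
            _Constraint(dict(c.coeffs), c.lb, c.ub, c.name)
            for c in self.constraints
        ]
        mb.constant_infeasible = self.constant_infeasible
        return mb

    @property
    def num_vars(self) -> int:
        return len(self.var_names)

    @property
    def num_constraints(self) -> int:
        return len(self.constraints)

    def add_binary(self, name: str) -> LinExpr:
        self.var_names.append(name)
        return LinExpr.var(len(self.var_names) - 1)

    def add_range(self, expr: LinExpr, lb: float, ub: float, name: str = ""):
        expr = as_expr(expr)
        d = expr._as_dict()
        if not d:
            if not (lb - 1e-9 <= expr.const <= ub + 1e-9):
                self.constant_infeasible = True
            return
        self.constraints.append(
            _Constraint(d, lb - expr.const, ub - expr.const, name)
        )

    # ---- Boolean glue (with constant folding) ----

    def NOT(self, b):
        c = bool_const(b)
        if c is not None:
            return not c
        return LinExpr.constant(1.0) - as_expr(b)

    def AND(self, bools, name: str):
        """y <=> conjunction of 0/1 expressions."""
        keep = []
        for b in bools:
            c = bool_const(b)
            if c is False:
                return False
            if c is None:
                keep.append(as_expr(b))
        if not keep:
            return True
        if len(keep) == 1:
            return keep[0]
        y = self.add_binary(name)
        for b in keep:
            self.add_range(y - b, -INF, 0.0)
        total = LinExpr.constant(0.0)
        for b in keep:
            total = total + b
        self.add_range(y - total, -(len(keep) - 1), INF)
        return y

    def OR(self, bools, name: str):
        """y <=> disjunction of 0/1 expressions."""
        keep = []
        for b in bools:
            c = bool_const(b)
            if c is True:
                return True
            if c is None:
                keep.append(as_expr(b))
        if not keep:
            return False
        if len(keep) == 1:
            return keep[0]
        y = self.add_binary(name)
        total = LinExpr.constant(0.0)
        for b in keep:
            self.add_range(y - b, 0.0, INF)
            total = total + b
        self.add_range(y - total, -INF, 0.0)
        return y

    def forbid_all(self, bools, name: str = ""):
        """Require that not all of ``bools`` are simultaneously 1."""
        keep = []
        for b in bools:
            c = bool_const(b)
            if c is False:
                return
            if c is None:
                keep.append(as_expr(b))
        if not keep:
            self.constant_infeasible = True
            return
        total = LinExpr.constant(0.0)
        for b in keep:
            total = total + b
        self.add_range(total, -INF, len(keep) - 1, name)

    def sum_indicator(self, bools, name: str):
        """y = sum(bools), valid when at most one can be 1 at a time."""
        const_part = 0.0
        keep = []
        for b in bools:
            c = bool_const(b)
            if c is True:
                const_part += 1.0
            elif c is None:
                keep.append(as_expr(b))
        if not keep:
            return const_part >= 0.5
        if not const_part and len(keep) == 1:
            return keep[0]
        y = self.add_binary(name)
        total = LinExpr.constant(const_part)
        for b in keep:
            total = total + b
        self.add_range(y - total, 0.0, 0.0)
        return y

    def threshold(self, expr: LinExpr, k: int, max_value: int, name: str):
        """y <=> (expr >= k + 1), with expr integer-valued in [0, max]."""
        expr = as_expr(expr)
        if expr.is_constant:
            return expr.const >= k + 1 - 1e-9
        y = self.add_binary(name)
        # y = 1 forces expr >= k+1; y = 0 forces expr <= k
        self.add_range(expr - (max_value - k) * y, -INF, k)
        self.add_range(expr - (k + 1) * y, 0.0, INF)
        return y

    # ---- solving ----

    def solve(self, objective: LinExpr, time_limit: float | None = None):
        """Minimize ``objective``; returns (status, values array, obj value).

        Feasibility-only queries pass a constant objective.
        """
        objective = as_expr(objective)
        if self.constant_infeasible:
            return SolveStatus.INFEASIBLE, None, None
        nv = self.num_vars
        if nv == 0:
            return SolveStatus.OPTIMAL, np.zeros(0), objective.const
        c = np.zeros(nv)
        for i, w in objective._as_dict().items():
            c[i] = w
        cons = []
        if self.constraints:
            rows, cols, vals, lbs, ubs = [], [], [], [], []
            for r, con in enumerate(self.constraints):
                for i, w in con.coeffs.items():
                    rows.append(r)
                    cols.append(i)
                    vals.append(w)
                lbs.append(con.lb)
                ubs.append(con.ub)
            A = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(len(self.constraints), nv)
            )
            cons = [LinearConstraint(A, np.array(lbs), np.array(ubs))]
        options = {}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=c,
            constraints=cons,
            integrality=np.ones(nv),
            bounds=(0, 1),
            options=options,
        )
        if res.status == 0:
            x = np.rint(res.x).astype(int)
            return SolveStatus.OPTIMAL, x, float(c @ x) + objective.const
        if res.status == 2:
            return SolveStatus.INFEASIBLE, None, None
        if res.status == 1:
            return SolveStatus.TIMEOUT, None, None
        raise RuntimeError(f"solver failure: {res.message}")

    # ---- text export ----

    def _term_str(self, coeffs: dict) -> str:
        parts = []
        for i in sorted(coeffs):
            w = coeffs[i]
            sign = "+" if w >= 0 else "-"
            parts.append(f"{sign} {abs(w):g} {self.var_names[i]}")
        s = " ".join(parts)
        return s[2:] if s.startswith("+ ") else s

    def to_lp(self, objective: LinExpr) -> str:
        objective = as_expr(objective)
        lines = ["Minimize", f" obj: {self._term_str(objective._as_dict()) or '0'}"]
        lines.append("Subject To")
        for r, con in enumerate(self.constraints):
            body = self._term_str(con.coeffs)
            if con.lb == con.ub:
                lines.append(f" c{r}: {body} = {con.lb:g}")
            else:
                if con.ub < INF:
                    lines.append(f" c{r}u: {body} <= {con.ub:g}")
                if con.lb > -INF:
                    lines.append(f" c{r}l: {body} >= {con.lb:g}")
        lines.append("Binary")
        for nm in self.var_names:
            lines.append(f" {nm}")
        lines.append("End")
        return "\n".join(lines) + "\n"

    def to_mps(self, objective: LinExpr) -> str:
        """Free-format MPS; range constraints become pairs of rows."""
        objective = as_expr(objective)
        rows, rhs = [], []
        row_of_con = []
        for r, con in enumerate(self.constraints):
            if con.lb == con.ub:
                rows.append(("E", f"c{r}", con.coeffs))
                rhs.append((f"c{r}", con.lb))
                row_of_con.append([f"c{r}"])
            else:
                names = []
                if con.ub < INF:
                    rows.append(("L", f"c{r}u", con.coeffs))
                    rhs.append((f"c{r}u", con.ub))
                    names.append(f"c{r}u")
                if con.lb > -INF:
                    rows.append(("G", f"c{r}l", con.coeffs))
                    rhs.append((f"c{r}l", con.lb))
                    names.append(f"c{r}l")
                row_of_con.append(names)
        out = ["NAME majplus", "ROWS", " N obj"]
        for sense, nm, _ in rows:
            out.append(f" {sense} {nm}")
        out.append("COLUMNS")
        out.append(" MARKER MARKER 'MARKER' 'INTORG'")
        obj = objective._as_dict()
        for i, nm in enumerate(self.var_names):
            if i in obj:
                out.append(f" {nm} obj {obj[i]:g}")
            for sense, rnm, coeffs in rows:
                if i in coeffs:
                    out.append(f" {nm} {rnm} {coeffs[i]:g}")
        out.append(" MARKER MARKER 'MARKER' 'INTEND'")
        out.append("RHS")
        for nm, v in rhs:
            out.append(f" RHS {nm} {v:g}")
        out.append("BOUNDS")
        for nm in self.var_names:
            out.append(f" BV BND {nm}")
        out.append("ENDATA")
        return "\n".join(out) + "\n"
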