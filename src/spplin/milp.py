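"""A small solver-agnostic mixed-integer linear program container.

Models are held as named variables with bounds/integrality, named range
constraints ``lb <= a.x <= ub`` and a linear objective.  They can be
exported to the standard LP file format or solved in process through
scipy's HiGHS interface.  Keeping the model neutral lets tests inspect
variables and constraints symbolically and makes solver runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

INF = float("inf")


@dataclass(eq=False)
class Variable:
    name: str
    lb: float
    ub: float
    integer: bool
    index: int


@dataclass
class Constraint:
    name: str
    coeffs: dict[int, float]
    lb: float
    ub: float


class Model:
    """Named-variable MILP with range constraints and a linear objective."""

    def __init__(self, name: str = "model", sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        self.name = name
        self.sense = sense
        self.variables: list[Variable] = []
        self._by_name: dict[str, Variable] = {}
        self.constraints: list[Constraint] = []
        self._objective: dict[int, float] = {}
        self.objective_constant = 0.0

    # -- building ---------------------------------------------------------
    def add_var(
        self, name: str, lb: float = 0.0, ub: float = INF, integer: bool = True
    ) -> Variable:
        if name in self._by_name:
            raise ValueError(f"duplicate variable {name}")
        v = Variable(name, float(lb), float(ub), integer, len(self.variables))
        self.variables.append(v)
        self._by_name[name] = v
        return v

    def binary(self, name: str) -> Variable:
        return self.add_var(name, 0, 1, True)

    def var(self, name: str) -> Variable:
        return self._by_name[name]

    def has_var(self, name: str) -> bool:
        return name in self._by_name

    def fix(self, v: Variable, value: float) -> None:
        v.lb = v.ub = float(value)

    def add_constr(
        self,
        name: str,
        terms: Mapping[Variable, float] | Iterable[tuple[Variable, float]],
        lb: float = -INF,
        ub: float = INF,
    ) -> Constraint:
        items = terms.items() if isinstance(terms, Mapping) else terms
        coeffs: dict[int, float] = {}
        for v, c in items:
            if c:
                coeffs[v.index] = coeffs.get(v.index, 0.0) + float(c)
        con = Constraint(name, coeffs, float(lb), float(ub))
        self.constraints.append(con)
        return con

    def add_objective_term(self, v: Variable, coeff: float) -> None:
        self._objective[v.index] = self._objective.get(v.index, 0.0) + float(coeff)

    def set_objective(
        self, terms: Mapping[Variable, float], constant: float = 0.0
    ) -> None:
        self._objective = {v.index: float(c) for v, c in terms.items()}
        self.objective_constant = float(constant)

    # -- inspection -------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_constrs(self) -> int:
        return len(self.constraints)

    def objective_value(self, assignment: Mapping[str, float]) -> float:
        val = self.objective_constant
        for idx, c in self._objective.items():
            val += c * assignment[self.variables[idx].name]
        return val

    def check_assignment(
        self, assignment: Mapping[str, float], tol: float = 1e-6
    ) -> list[str]:
        """Names of constraints/domains violated by a full assignment."""
        bad: list[str] = []
        x = np.zeros(self.n_vars)
        for v in self.variables:
            if v.name not in assignment:
                bad.append(f"missing value for {v.name}")
                continue
            val = float(assignment[v.name])
            x[v.index] = val
            if val < v.lb - tol or val > v.ub + tol:
                bad.append(f"domain of {v.name}: {val} not in [{v.lb},{v.ub}]")
            if v.integer and abs(val - round(val)) > tol:
                bad.append(f"integrality of {v.name}: {val}")
        for con in self.constraints:
            s = sum(c * x[i] for i, c in con.coeffs.items())
            if s < con.lb - tol or s > con.ub + tol:
                bad.append(f"{con.name}: {s} not in [{con.lb},{con.ub}]")
        return bad

    # -- LP export --------------------------------------------------------
    def to_lp(self) -> str:
        """Serialize in the LP file format (CPLEX dialect)."""

        def term_str(coeffs: dict[int, float]) -> str:
            parts = []
            for idx in sorted(coeffs):
                c = coeffs[idx]
                nm = self.variables[idx].name
                sign = "-" if c < 0 else "+"
                parts.append(f"{sign} {abs(c):.12g} {nm}")
            if not parts:
                return "0"
            out = " ".join(parts)
            return out[2:] if out.startswith("+ ") else out

        lines = [f"\\ {self.name}", "Minimize" if self.sense == "min" else "Maximize"]
        lines.append(" obj: " + term_str(self._objective))
        lines.append("Subject To")
        for con in self.constraints:
            if con.lb == con.ub:
                lines.append(f" {con.name}: {term_str(con.coeffs)} = {con.lb:.12g}")
            else:
                if con.ub < INF:
                    lines.append(
                        f" {con.name}_u: {term_str(con.coeffs)} <= {con.ub:.12g}"
                    )
                if con.lb > -INF:
                    lines.append(
                        f" {con.name}_l: {term_str(con.coeffs)} >= {con.lb:.12g}"
                    )
        lines.append("Bounds")
        for v in self.variables:
            lo = f"{v.lb:.12g}" if v.lb > -INF else "-inf"
            hi = f"{v.ub:.12g}" if v.ub < INF else "+inf"
            lines.append(f" {lo} <= {v.name} <= {hi}")
        ints = [v.name for v in self.variables if v.integer]
        if ints:
            lines.append("Generals")
            for nm in ints:
                lines.append(f" {nm}")
        lines.append("End")
        return "\n".join(lines) + "\n"

    # -- solving ----------------------------------------------------------
    def solve(
        self,
        time_limit: Optional[float] = None,
        mip_gap: float = 0.0,
        verbose: bool = False,
    ) -> "MilpResult":
        """Solve through scipy's HiGHS backend."""
        c = np.zeros(self.n_vars)
        for idx, coeff in self._objective.items():
            c[idx] = coeff
        if self.sense == "max":
            c = -c
        integrality = np.array(
            [1 if v.integer else 0 for v in self.variables], dtype=np.uint8
        )
        lb = np.array([v.lb for v in self.variables])
        ub = np.array([v.ub for v in self.variables])
        constraints = []
        if self.constraints:
            rows, cols, vals = [], [], []
            clb, cub = [], []
            for r, con in enumerate(self.constraints):
                for idx, coeff in con.coeffs.items():
                    rows.append(r)
                    cols.append(idx)
                    vals.append(coeff)
                clb.append(con.lb)
                cub.append(con.ub)
            a = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(len(self.constraints), self.n_vars)
            )
            constraints = [LinearConstraint(a, clb, cub)]
        options: dict = {"disp": verbose}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        if mip_gap:
            options["mip_rel_gap"] = float(mip_gap)
        res = milp(
            c=c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lb, ub),
            options=options,
        )
        status = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "other"}[
            res.status
        ]
        # scipy reports "iteration or time limit" under status 1
        assignment = None
        objective = None
        if res.x is not None:
            assignment = {}
            for v in self.variables:
                val = float(res.x[v.index])
                assignment[v.name] = round(val) if v.integer else val
            objective = self.objective_value(assignment)
        gap = getattr(res, "mip_gap", None)
        bound = getattr(res, "mip_dual_bound", None)
        if bound is not None and self.sense == "max":
            bound = -bound
        return MilpResult(status, assignment, objective, gap, bound, res.message)


@dataclass
class MilpResult:
    status: str
    assignment: Optional[dict[str, float]]
    objective: Optional[float]
    gap: Optional[float]
    bound: Optional[float]
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"
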