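"""Minimal mixed-integer linear programming backend.

A small modelling layer with named variables, sense-tagged linear
constraints and a single linear objective, solved with HiGHS through
:func:`scipy.optimize.milp`.  The optimality gap defaults to 0 (relative
and absolute), so the solver stops only at a proven optimum.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearModel", "SolveResult", "SolverError"]

_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "error"}


class SolverError(RuntimeError):
    """The MILP solver failed in an unexpected way."""


@dataclass(frozen=True)
class SolveResult:
    status: str
    objective: float | None
    values: np.ndarray | None

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


class LinearModel:
    """Incrementally built MILP: max/min c'x s.t. lb <= Ax <= ub, bounds, integrality."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[int] = []
        self._rows: list[list[tuple[int, float]]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._row_family: list[str] = []
        self._obj: dict[int, float] = {}
        self._maximize = True

    # -- variables ------------------------------------------------------------

    def add_variable(self, name: str, lb: float, ub: float, integer: bool) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self.names)
        self.names.append(name)
        self._index[name] = idx
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(1 if integer else 0)
        return idx

    def add_binary(self, name: str) -> int:
        return self.add_variable(name, 0.0, 1.0, integer=True)

    def add_continuous(self, name: str, lb: float = 0.0, ub: float = np.inf) -> int:
        return self.add_variable(name, lb, ub, integer=False)

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_variables(self) -> int:
        return len(self.names)

    # -- constraints ----------------------------------------------------------

    def add_constraint(
        self,
        terms: Iterable[tuple[int, float]],
        sense: str,
        rhs: float,
        family: str = "other",
    ) -> None:
        """Add ``sum(coef * x[idx]) <sense> rhs`` with sense in {'<=', '=', '>='}."""
        if sense == "<=":
            lo, hi = -np.inf, rhs
        elif sense == ">=":
            lo, hi = rhs, np.inf
        elif sense == "=":
            lo = hi = rhs
        else:
            raise ValueError(f"unknown sense {sense!r}")
        self._rows.append(list(terms))
        self._row_lb.append(lo)
        self._row_ub.append(hi)
        self._row_family.append(family)

    @property
    def n_constraints(self) -> int:
        return len(self._rows)

    def family_counts(self) -> Counter:
        """Number of constraint rows per family tag."""
        return Counter(self._row_family)

    # -- objective ------------------------------------------------------------

    def set_objective(self, coeffs: Mapping[int, float], maximize: bool = True) -> None:
        self._obj = dict(coeffs)
        self._maximize = maximize

    # -- solving --------------------------------------------------------------

    def _matrix(self) -> sparse.csr_matrix:
        data, rows, cols = [], [], []
        for i, row in enumerate(self._rows):
            for j, coef in row:
                rows.append(i)
                cols.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self._rows), self.n_variables)
        )

    def solve(
        self,
        mip_gap: float = 0.0,
        time_limit: float | None = None,
        fixed: Mapping[int, float] | None = None,
        presolve: bool = True,
        feasibility_tol: float = 1e-7,
    ) -> SolveResult:
        """Solve the model; ``fixed`` pins variables to values via their bounds.

        ``presolve=False`` disables HiGHS presolve.  This build of HiGHS can
        lose incumbents while mapping them back through presolve (visible as
        ``transformNewIntegerFeasibleSolution`` warnings) and then report a
        suboptimal solution as optimal; presolve-off solves avoid that path
        at some speed cost and are used where proven optimality matters.
        """
        c = np.zeros(self.n_variables)
        for j, coef in self._obj.items():
            c[j] = coef
        if self._maximize:
            c = -c
        lb = np.array(self._lb)
        ub = np.array(self._ub)
        if fixed:
            for j, v in fixed.items():
                lb[j] = ub[j] = v
        options: dict = {
            "mip_rel_gap": mip_gap,
            "mip_abs_gap": mip_gap,
            "presolve": presolve,
            # one decade below the 1e-6 default; tighter settings (1e-9) made
            # this HiGHS build declare large feasible instances infeasible.
            # Knife-edge incumbents that squeeze through the tolerance are
            # rejected downstream by exact re-evaluation, never trusted here.
            "mip_feasibility_tolerance": feasibility_tol,
        }
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        constraints = []
        if self._rows:
            constraints.append(
                LinearConstraint(
                    self._matrix(), np.array(self._row_lb), np.array(self._row_ub)
                )
            )
        with warnings.catch_warnings():
            # scipy forwards mip_abs_gap to HiGHS verbatim and warns about it
            warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                c,
                constraints=constraints,
                integrality=np.array(self._integer),
                bounds=Bounds(lb, ub),
                options=options,
            )
        status = _STATUS.get(res.status, "error")
        if status == "optimal":
            obj = float(res.fun)
            return SolveResult(
                status="optimal",
                objective=-obj if self._maximize else obj,
                values=np.asarray(res.x, dtype=float),
            )
        if status == "limit" and res.x is not None:
            obj = float(res.fun)
            return SolveResult(
                status="limit",
                objective=-obj if self._maximize else obj,
                values=np.asarray(res.x, dtype=float),
            )
        return SolveResult(status=status, objective=None, values=None)
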