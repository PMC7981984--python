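"""Thin deterministic LP/MILP layer on top of ``scipy.optimize.milp`` (HiGHS).

Every optimisation problem in the package (TFA, TVA, steady-state transfer) is
expressed as a :class:`LinearModel`: named variables with bounds and an
integrality mask, plus two-sided linear constraints.  Problems are built
incrementally and solved with HiGHS, which is deterministic for a fixed model,
so all downstream results are reproducible without a solver seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import InfeasibleProblemError, SolverError

INF = float("inf")


@dataclass
class Solution:
    status: int
    message: str
    x: np.ndarray | None
    fun: float | None

    @property
    def ok(self) -> bool:
        return self.status == 0


@dataclass
class LinearModel:
    """A mixed-integer linear model with named variables and constraints."""

    names: list[str] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    integer: list[bool] = field(default_factory=list)
    # each constraint: (name, {var_index: coeff}, row_lb, row_ub)
    constraints: list[tuple[str, dict[int, float], float, float]] = field(
        default_factory=list
    )
    _index: dict[str, int] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_variable(
        self, name: str, lb: float = -INF, ub: float = INF, integer: bool = False
    ) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self.names)
        self.names.append(name)
        self.lb.append(float(lb))
        self.ub.append(float(ub))
        self.integer.append(bool(integer))
        self._index[name] = idx
        return idx

    def add_constraint(
        self, name: str, coeffs: dict[int, float], lb: float = -INF, ub: float = INF
    ) -> int:
        self.constraints.append((name, dict(coeffs), float(lb), float(ub)))
        return len(self.constraints) - 1

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def set_bounds(self, idx: int, lb: float, ub: float) -> None:
        if lb > ub + 1e-12:
            raise ValueError(f"lb > ub for variable {self.names[idx]}")
        self.lb[idx] = float(lb)
        self.ub[idx] = float(ub)

    def fix(self, idx: int, value: float) -> None:
        self.set_bounds(idx, value, value)

    def copy(self) -> "LinearModel":
        return copy.deepcopy(self)

    # -- solving -----------------------------------------------------------
    def _constraint_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        rows, cols, vals = [], [], []
        clb = np.empty(len(self.constraints))
        cub = np.empty(len(self.constraints))
        for i, (_, coeffs, lo, hi) in enumerate(self.constraints):
            clb[i] = lo
            cub[i] = hi
            for j, v in coeffs.items():
                rows.append(i)
                cols.append(j)
                vals.append(v)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.constraints), self.n_vars)
        )
        return A, clb, cub

    def solve(
        self,
        objective: dict[int, float] | np.ndarray | None = None,
        sense: str = "min",
        raise_infeasible: bool = True,
    ) -> Solution:
        """Solve the model; ``objective`` maps variable index to cost."""
        c = np.zeros(self.n_vars)
        if objective is not None:
            if isinstance(objective, dict):
                for j, v in objective.items():
                    c[j] = v
            else:
                c = np.asarray(objective, dtype=float)
        if sense == "max":
            c = -c
        elif sense != "min":
            raise ValueError("sense must be 'min' or 'max'")

        cons = []
        if self.constraints:
            A, clb, cub = self._constraint_matrix()
            cons.append(LinearConstraint(A, clb, cub))
        res = milp(
            c,
            constraints=cons,
            integrality=np.asarray(self.integer, dtype=int),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
        )
        fun = res.fun if res.x is not None else None
        if sense == "max" and fun is not None:
            fun = -fun
        sol = Solution(status=res.status, message=res.message, x=res.x, fun=fun)
        if not sol.ok:
            if res.status == 2 and raise_infeasible:
                raise InfeasibleProblemError(res.message)
            if res.status not in (0, 2):
                raise SolverError(f"solver status {res.status}: {res.message}")
        return sol

    def value(self, sol: Solution, name: str) -> float:
        return float(sol.x[self._index[name]])
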