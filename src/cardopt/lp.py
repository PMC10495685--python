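"""Thin LP-backend abstraction.

Two concrete backends are provided:

* ``"highs"`` — scipy.optimize.linprog with the HiGHS solver (default).
  Each subproblem is solved cold; scipy exposes no warm-start API.
* ``"glpk"`` — GLPK through optlang/swiglpk.  The backend keeps the last
  model alive and, when asked to re-solve a problem with identical
  constraint structure (only objective coefficients changed, as in
  successive DCA iterations), updates the objective in place so GLPK's
  simplex re-starts from the previous basis — an effective warm start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = ["LinearProgram", "LPResult", "LPBackend", "ScipyHighsBackend", "GlpkBackend", "get_backend"]

_INF = float("inf")


@dataclass
class LinearProgram:
    """min c.x  s.t.  A_eq x = b_eq,  A_ub x <= b_ub,  lb <= x <= ub."""

    c: np.ndarray
    A_eq: sp.spmatrix | None = None
    b_eq: np.ndarray | None = None
    A_ub: sp.spmatrix | None = None
    b_ub: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.c)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(self.n, -_INF) if self.lb is None else np.asarray(self.lb, float)
        ub = np.full(self.n, _INF) if self.ub is None else np.asarray(self.ub, float)
        return lb, ub


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: np.ndarray | None = None
    fun: float | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class LPBackend:
    name = "abstract"
    supports_warm_start = False

    def solve(self, lp: LinearProgram, warm: np.ndarray | None = None) -> LPResult:
        raise NotImplementedError


class ScipyHighsBackend(LPBackend):
    name = "highs"
    supports_warm_start = False

    def solve(self, lp: LinearProgram, warm: np.ndarray | None = None) -> LPResult:
        lb, ub = lp.bounds_arrays()
        res = linprog(
            lp.c,
            A_ub=lp.A_ub,
            b_ub=lp.b_ub,
            A_eq=lp.A_eq,
            b_eq=lp.b_eq,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
        return LPResult(status=status, x=res.x if res.status == 0 else None,
                        fun=res.fun if res.status == 0 else None, message=res.message)


class GlpkBackend(LPBackend):
    """GLPK via optlang; persistent model gives basis-reuse warm starts."""

    name = "glpk"
    supports_warm_start = True

    def __init__(self) -> None:
        self._model = None
        self._signature = None
        self._vars = None

    @staticmethod
    def _structure_signature(lp: LinearProgram):
        def key(mat, vec):
            if mat is None:
                return None
            m = sp.csr_matrix(mat)
            return (m.shape, m.nnz, m.indptr.tobytes(), m.indices.tobytes(),
                    m.data.tobytes(), np.asarray(vec, float).tobytes())

        lb, ub = lp.bounds_arrays()
        return (lp.n, key(lp.A_eq, lp.b_eq), key(lp.A_ub, lp.b_ub),
                lb.tobytes(), ub.tobytes())

    def _build(self, lp: LinearProgram):
        from optlang.glpk_interface import Constraint, Model, Objective, Variable

        lb, ub = lp.bounds_arrays()
        variables = [
            Variable(f"x{i}",
                     lb=None if lb[i] == -_INF else lb[i],
                     ub=None if ub[i] == _INF else ub[i])
            for i in range(lp.n)
        ]
        model = Model()
        model.add(variables)
        constraints = []
        for A, b, eq in ((lp.A_eq, lp.b_eq, True), (lp.A_ub, lp.b_ub, False)):
            if A is None:
                continue
            A = sp.csr_matrix(A)
            b = np.asarray(b, float)
            for i in range(A.shape[0]):
                lo = b[i] if eq else None
                con = Constraint(0, lb=lo, ub=b[i], name=f"c{'e' if eq else 'u'}{i}")
                constraints.append((con, A.indices[A.indptr[i]:A.indptr[i + 1]],
                                    A.data[A.indptr[i]:A.indptr[i + 1]]))
        model.add([c for c, _, _ in constraints])
        model.update()
        for con, idx, data in constraints:
            con.set_linear_coefficients({variables[j]: float(v) for j, v in zip(idx, data)})
        model.objective = Objective(0, direction="min")
        model.update()
        self._model, self._vars = model, variables

    def solve(self, lp: LinearProgram, warm: np.ndarray | None = None) -> LPResult:
        sig = self._structure_signature(lp)
        if self._model is None or sig != self._signature:
            self._build(lp)
            self._signature = sig
        model, variables = self._model, self._vars
        model.objective.set_linear_coefficients(
            {v: float(ci) for v, ci in zip(variables, lp.c)})
        status = model.optimize()
        if status == "optimal":
            x = np.array([v.primal for v in variables], dtype=float)
            return LPResult("optimal", x=x, fun=float(lp.c @ x))
        if status in ("infeasible", "undefined"):
            return LPResult("infeasible", message=str(status))
        if status == "unbounded":
            return LPResult("unbounded")
        return LPResult("error", message=str(status))


def get_backend(name: str | LPBackend = "highs") -> LPBackend:
    if isinstance(name, LPBackend):
        return name
    if name == "highs":
        return ScipyHighsBackend()
    if name == "glpk":
        return GlpkBackend()
    raise ValueError(f"unknown LP backend {name!r} (available: highs, glpk)")
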