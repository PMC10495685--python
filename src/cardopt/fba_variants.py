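"""Flux balance analysis, sparse FBA, relaxed FBA and the isolated-ATP-
hydrolysis cycle test.

Sparse FBA minimizes the number of active reactions subject to attaining
the FBA optimum rho* = max{c^T v : S v = b, l <= v <= u}; with the
capped-L1 DCA this takes a handful of LPs even at genome scale.  Relaxed
FBA finds the minimum number of bound or steady-state constraints whose
relaxation renders an infeasible FBA problem feasible.  The cycle test
closes every external reaction, forces flux through an energy-maintenance
(ATP hydrolysis) reaction, and asks for the minimal-cardinality internal
flux pattern — any answer is a stoichiometrically balanced cycle admitting
isolated hydrolysis, a thermodynamically impossible free lunch that should
be repaired by tightening a bound on one of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dc_solver import (CardinalityProblem, CardinalitySolution, DCASettings,
                        solve_cardinality, verify_support_minimality)
from .lp import LinearProgram, LPBackend, get_backend
from .model_io import MetabolicModel, StoichPartition, split_internal_external
from .step_approx import StepApprox

__all__ = [
    "FbaResult",
    "SparseFbaResult",
    "RelaxationSolution",
    "fba",
    "sparse_fba",
    "atp_cycle_test",
    "relaxed_fba",
]


@dataclass
class FbaResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    v: np.ndarray | None


def fba(model: MetabolicModel, backend: str | LPBackend = "highs") -> FbaResult:
    """rho* = max{c^T v : S v = b, l <= v <= u} and a witness flux."""
    res = get_backend(backend).solve(LinearProgram(
        c=-model.c, A_eq=model.S.tocsr(), b_eq=model.b, lb=model.lb, ub=model.ub))
    if res.status == "optimal":
        return FbaResult("optimal", float(model.c @ res.x), res.x)
    return FbaResult(res.status, None, None)


@dataclass
class SparseFbaResult:
    objective: float          # rho*, attained by v
    v: np.ndarray
    support: list[str]
    removable: dict[str, bool]
    outer_lp_count: int
    solution: CardinalitySolution = field(repr=False, default=None)

    @property
    def is_locally_minimal(self) -> bool:
        return not any(self.removable.values())


def _attainment_problem(model: MetabolicModel, rho: float, feas_tol: float,
                        min_idx: np.ndarray, min_weights=1.0) -> CardinalityProblem:
    """Polyhedron {S v = b, l <= v <= u, c^T v >= rho - feas_tol}."""
    A_ub = sp.csr_matrix(-model.c.reshape(1, -1))
    return CardinalityProblem(
        n=model.n, A_eq=model.S.tocsr(), b_eq=model.b,
        A_ub=A_ub, b_ub=np.array([-(rho - feas_tol)]),
        lb=model.lb, ub=model.ub, min_idx=min_idx, min_weights=min_weights)


def sparse_fba(
    model: MetabolicModel,
    approx: StepApprox | None = None,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
    check_minimality: bool = True,
) -> SparseFbaResult:
    """Minimum-support flux attaining the FBA optimum.

    The attainment constraint is imposed as c^T v >= rho* - feas_tol, the
    same tolerance-relaxed re-check used when testing whether the optimum
    survives removal of individual support members.
    """
    settings = settings or DCASettings()
    base = fba(model, backend)
    if base.status != "optimal":
        raise ValueError(f"FBA is {base.status}; relaxed_fba may locate the conflict")
    problem = _attainment_problem(model, base.objective, settings.feas_tol,
                                  np.arange(model.n))
    sol = solve_cardinality(problem, approx=approx, settings=settings, backend=backend)
    if sol.status == "infeasible":  # rho* is attainable by construction
        raise RuntimeError("sparse FBA subproblem unexpectedly infeasible")
    support_idx = sol.support_min
    removable = {}
    if check_minimality:
        flags = verify_support_minimality(problem, support_idx, backend=backend)
        removable = {model.rxn_ids[j]: flag for j, flag in flags.items()}
    return SparseFbaResult(
        objective=base.objective, v=sol.x,
        support=[model.rxn_ids[j] for j in support_idx],
        removable=removable, outer_lp_count=sol.iterations, solution=sol)


def atp_cycle_test(
    model: MetabolicModel,
    hydrolysis_rxn_id: str,
    partition: StoichPartition | None = None,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> list[str] | None:
    """Minimal stoichiometrically balanced cycle admitting isolated ATP
    hydrolysis, or None (the desired state).

    All external reactions are closed (bounds zeroed), the hydrolysis
    reaction is forced (v >= 1; the cycle support is scale-invariant) and
    the cardinality of the internal flux is minimized.  Infeasibility means
    no set of internal reactions, with the bounds supplied, admits an
    arbitrary amount of isolated hydrolysis.
    """
    j_hyd = model.rxn_index(hydrolysis_rxn_id)  # raises KeyError if absent
    partition = partition or split_internal_external(model)
    lb, ub = model.lb.copy(), model.ub.copy()
    lb[partition.external_cols] = 0.0
    ub[partition.external_cols] = 0.0
    lb[j_hyd] = 1.0
    ub[j_hyd] = max(ub[j_hyd], 1.0)
    problem = CardinalityProblem(
        n=model.n, A_eq=model.S.tocsr(), b_eq=model.b, lb=lb, ub=ub,
        min_idx=partition.internal_cols)
    sol = solve_cardinality(problem, settings=settings or DCASettings.robust(),
                            backend=backend)
    if sol.status == "infeasible":
        return None
    return [model.rxn_ids[j] for j in sol.support_min]


@dataclass
class RelaxationSolution:
    """Minimal relaxation rendering FBA feasible: S v + r = b with
    l - p <= v <= u + q and p, q, r >= 0."""

    status: str
    v: np.ndarray | None
    r: np.ndarray | None
    p: np.ndarray | None
    q: np.ndarray | None
    lam: np.ndarray | None = None
    alpha: np.ndarray | None = None
    solution: CardinalitySolution | None = field(repr=False, default=None)

    @property
    def total_cardinality(self) -> int:
        eps = 1e-9
        return sum(int(np.sum(np.abs(x) > eps)) for x in (self.r, self.p, self.q)
                   if x is not None)

    def relaxed_model(self, model: MetabolicModel) -> MetabolicModel:
        out = model.copy()
        out.lb = model.lb - (self.p if self.p is not None else 0.0)
        out.ub = model.ub + (self.q if self.q is not None else 0.0)
        out.b = model.b - (self.r if self.r is not None else 0.0)
        return out

    def to_dict(self) -> dict:
        return {"status": self.status, "total_cardinality": self.total_cardinality}


_RELAX_CAP = 1e6


def relaxed_fba(
    model: MetabolicModel,
    lam: float | np.ndarray = 1.0,
    alpha: float | np.ndarray = 1.0,
    allow_r: bool = False,
    allow_p: bool = True,
    allow_q: bool = True,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> RelaxationSolution:
    """min lam*card(r) + alpha*card(p) + alpha*card(q) over
    {S v + r = b, l - p <= v <= u + q, p, q, r >= 0}.

    The weights trade off relaxing mass balance against relaxing bounds,
    globally or per constraint.  Steady-state relaxation is off by default;
    relaxations below ``feas_tol`` are zeroed and the relaxed model is
    re-verified feasible before returning.
    """
    settings = settings or DCASettings.robust()
    m, n = model.m, model.n
    lam = np.full(m, float(lam)) if np.ndim(lam) == 0 else np.asarray(lam, float)
    alpha = np.full(n, float(alpha)) if np.ndim(alpha) == 0 else np.asarray(alpha, float)
    # variable layout: [v (n), r (m), p (n), q (n)]
    ntot = n + m + 2 * n
    S = model.S.tocsr()
    A_eq = sp.hstack([S, sp.identity(m), sp.csr_matrix((m, 2 * n))], format="csr")
    # l - p <= v  <=>  -v - p <= -l ;  v - q <= u
    A_lb = sp.hstack([-sp.identity(n), sp.csr_matrix((n, m)), -sp.identity(n),
                      sp.csr_matrix((n, n))], format="csr")
    A_ub_ = sp.hstack([sp.identity(n), sp.csr_matrix((n, m + n)), -sp.identity(n)],
                      format="csr")
    lb = np.concatenate([np.full(n, -_RELAX_CAP), np.zeros(m + 2 * n)])
    ub = np.concatenate([np.full(n, _RELAX_CAP),
                         np.full(m, _RELAX_CAP if allow_r else 0.0),
                         np.full(n, _RELAX_CAP if allow_p else 0.0),
                         np.full(n, _RELAX_CAP if allow_q else 0.0)])
    problem = CardinalityProblem(
        n=ntot,
        A_eq=A_eq, b_eq=model.b,
        A_ub=sp.vstack([A_lb, A_ub_]).tocsr(),
        b_ub=np.concatenate([-model.lb, model.ub]),
        lb=lb, ub=ub,
        min_idx=np.arange(n, ntot),
        min_weights=np.concatenate([lam, alpha, alpha]))
    sol = solve_cardinality(problem, settings=settings, backend=backend)
    if sol.status == "infeasible":
        return RelaxationSolution("infeasible", None, None, None, None, lam, alpha, sol)
    x = sol.x
    r, p, q = x[n:n + m].copy(), x[n + m:n + m + n].copy(), x[n + m + n:].copy()
    for vec in (r, p, q):
        vec[np.abs(vec) < settings.feas_tol] = 0.0
    out = RelaxationSolution("optimal", x[:n], r, p, q, lam, alpha, sol)
    relaxed = out.relaxed_model(model)
    check = get_backend(backend).solve(LinearProgram(
        c=np.zeros(n), A_eq=relaxed.S.tocsr(), b_eq=relaxed.b,
        lb=relaxed.lb, ub=relaxed.ub))
    if not check.ok:
        raise RuntimeError("relaxed model failed feasibility re-verification")
    return out
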