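"""Generic cardinality optimization over a polyhedron via DCA.

A :class:`CardinalityProblem` carries a polyhedron (equalities, inequalities
and bounds) whose variables are partitioned into three blocks:

* ``x`` — entries whose (weighted) cardinality is *minimized*,
* ``y`` — entries whose (weighted) cardinality is *maximized*,
* ``z`` — everything else, with an ordinary linear cost.

The zero norm of each block is replaced by a sum of approximate step
functions (:mod:`cardopt.step_approx`) and the resulting difference-of-convex
program is solved by DCA: each outer iteration linearizes the subtracted
convex component at the incumbent and solves the resulting LP.  With the
capped-L1 family every subproblem is an LP in both modes; iteration 1 (taken
at the zero incumbent) coincides with the weighted one-norm relaxation.

A brute-force oracle (:func:`brute_force_min_card`) solves small instances
exactly by enumerating supports, and :func:`verify_support_minimality`
implements the one-by-one removal test for local minimality of a support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .lp import LinearProgram, LPBackend, get_backend
from .step_approx import StepApprox, eval_step

__all__ = [
    "CardinalityProblem",
    "CardinalitySolution",
    "DCASettings",
    "UnboundedProblemError",
    "solve_cardinality",
    "brute_force_min_card",
    "verify_support_minimality",
]

_INF = float("inf")


class UnboundedProblemError(RuntimeError):
    """An LP subproblem was unbounded; cardinality objectives are bounded,
    so this signals a malformed linear-cost block."""


@dataclass
class CardinalityProblem:
    """Weighted cardinality optimization over {A_eq v = b_eq, A_ub v <= b_ub,
    lb <= v <= ub}."""

    n: int
    A_eq: sp.spmatrix | None = None
    b_eq: np.ndarray | None = None
    A_ub: sp.spmatrix | None = None
    b_ub: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    min_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    min_weights: np.ndarray | float = 1.0
    max_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    max_weights: np.ndarray | float = 1.0
    cost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.min_idx = np.asarray(self.min_idx, dtype=int)
        self.max_idx = np.asarray(self.max_idx, dtype=int)
        if np.intersect1d(self.min_idx, self.max_idx).size:
            raise ValueError("min and max cardinality blocks must be disjoint")
        self.min_weights = self._expand(self.min_weights, self.min_idx.size, "min_weights")
        self.max_weights = self._expand(self.max_weights, self.max_idx.size, "max_weights")
        if np.any(self.min_weights < 0) or np.any(self.max_weights < 0):
            raise ValueError("cardinality weights must be nonnegative")
        lb, ub = self.bounds_arrays()
        if np.any(lb > ub):
            raise ValueError("lb > ub on some variable")

    @staticmethod
    def _expand(w, size: int, name: str) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.ndim == 0:
            return np.full(size, float(w))
        if w.size != size:
            raise ValueError(f"{name} has size {w.size}, expected {size}")
        return w.copy()

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(self.n, -_INF) if self.lb is None else np.asarray(self.lb, float).copy()
        ub = np.full(self.n, _INF) if self.ub is None else np.asarray(self.ub, float).copy()
        return lb, ub

    def cost_array(self) -> np.ndarray:
        return np.zeros(self.n) if self.cost is None else np.asarray(self.cost, float)

    def feasibility_lp(self, lb=None, ub=None, cost=None) -> LinearProgram:
        l0, u0 = self.bounds_arrays()
        return LinearProgram(
            c=self.cost_array() if cost is None else cost,
            A_eq=self.A_eq, b_eq=self.b_eq, A_ub=self.A_ub, b_ub=self.b_ub,
            lb=l0 if lb is None else lb, ub=u0 if ub is None else ub)

    def residuals(self, v: np.ndarray) -> float:
        """Max constraint violation of ``v`` (bounds included)."""
        worst = 0.0
        if self.A_eq is not None:
            worst = max(worst, float(np.max(np.abs(self.A_eq @ v - self.b_eq), initial=0.0)))
        if self.A_ub is not None:
            worst = max(worst, float(np.max(self.A_ub @ v - self.b_ub, initial=0.0)))
        lb, ub = self.bounds_arrays()
        worst = max(worst, float(np.max(lb - v, initial=0.0)), float(np.max(v - ub, initial=0.0)))
        return worst


@dataclass
class DCASettings:
    """DCA controls.

    ``restarts``/``backoff`` trade extra LPs for cardinality quality on
    small problems: ``backoff`` tentatively forces individual support
    members to zero and re-runs the DCA (an escape step for local optima);
    ``restarts`` re-runs with seeded random weight perturbations.  Both are
    off by default, which keeps the plain two-to-three-LP DCA sequence used
    for genome-scale work.
    """

    theta0: float = 0.5
    theta_factor: float = 1.5
    theta_max: float = 1e3
    tol: float = 1e-6
    max_outer: int = 50
    eps_supp: float = 1e-6
    feas_tol: float = 1e-6
    polish: bool = True
    restarts: int = 0
    backoff: bool = False
    restart_seed: int = 0

    @classmethod
    def robust(cls, seed: int = 0, restarts: int = 3) -> "DCASettings":
        """Preset for small instances where matching the exact minimum matters."""
        return cls(restarts=restarts, backoff=True, restart_seed=seed)


@dataclass
class CardinalitySolution:
    status: str  # "optimal-approx" | "infeasible" | "iteration-limit"
    x: np.ndarray | None
    support_min: np.ndarray
    support_max: np.ndarray
    iterations: int
    lp_count: int
    trace: list[float]
    descent_pairs: list[tuple[float, float]]
    objective: float | None = None
    message: str = ""

    @property
    def max_descent_violation(self) -> float:
        """Largest DCA descent violation, post - pre under a common theta."""
        if not self.descent_pairs:
            return 0.0
        return max(post - pre for pre, post in self.descent_pairs)


def _fix_to_zero(lb: np.ndarray, ub: np.ndarray, idx) -> bool:
    """Encode x_idx = 0 via bounds; False when impossible (0 outside the box),
    in which case the candidate restriction is infeasible outright."""
    idx = np.atleast_1d(np.asarray(idx, dtype=int))
    if idx.size and (np.any(lb[idx] > 0) or np.any(ub[idx] < 0)):
        return False
    lb[idx] = 0.0
    ub[idx] = 0.0
    return True


def _true_objective(problem: CardinalityProblem, approx: StepApprox, v: np.ndarray) -> float:
    obj = float(problem.cost_array() @ v)
    if problem.min_idx.size:
        obj += float(problem.min_weights @ eval_step(approx, v[problem.min_idx]))
    if problem.max_idx.size:
        obj += float(problem.max_weights @ (1.0 - eval_step(approx, v[problem.max_idx])))
    return obj


def _assemble_lp(problem: CardinalityProblem, J: np.ndarray, K: np.ndarray,
                 theta: float) -> tuple[LinearProgram, slice, slice, slice]:
    """Extended LP layout: [v (n), a_J, a_K, s_K].

    a >= |v| epigraph rows; s_k >= theta*a_k - 1 epigraph rows for the
    capped-L1 co-step in maximize blocks.
    """
    n = problem.n
    nJ, nK = J.size, K.size
    ntot = n + nJ + nK + nK
    aJ = slice(n, n + nJ)
    aK = slice(n + nJ, n + nJ + nK)
    sK = slice(n + nJ + nK, ntot)

    card = np.concatenate([J, K]).astype(int)
    ncard = card.size
    nrows_extra = 2 * ncard + nK
    # epigraph rows: v_j - a <= 0 ; -v_j - a <= 0 ; theta*a_k - s_k <= 1
    rows_i, cols, vals = [], [], []
    aux_idx = n + np.arange(ncard)
    r0 = np.arange(ncard) * 2
    rows_i.extend([r0, r0, r0 + 1, r0 + 1])
    cols.extend([card, aux_idx, card, aux_idx])
    vals.extend([np.ones(ncard), -np.ones(ncard), -np.ones(ncard), -np.ones(ncard)])
    if nK:
        rk = 2 * ncard + np.arange(nK)
        rows_i.extend([rk, rk])
        cols.extend([n + nJ + np.arange(nK), n + nJ + nK + np.arange(nK)])
        vals.extend([np.full(nK, theta), -np.ones(nK)])
    extra = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(cols))),
        shape=(nrows_extra, ntot)) if ncard else None
    rhs = np.concatenate([np.zeros(2 * ncard), np.ones(nK)])

    blocks_ub = []
    if problem.A_ub is not None:
        A = sp.csr_matrix(problem.A_ub)
        blocks_ub.append(sp.hstack([A, sp.csr_matrix((A.shape[0], ntot - n))]))
    if extra is not None:
        blocks_ub.append(extra)
    A_ub = sp.csr_matrix(sp.vstack(blocks_ub)) if blocks_ub else None
    b_ub = np.concatenate([np.asarray(problem.b_ub, float) if problem.A_ub is not None else np.array([]),
                           rhs]) if blocks_ub else None

    A_eq = None
    b_eq = None
    if problem.A_eq is not None:
        A = sp.csr_matrix(problem.A_eq)
        A_eq = sp.csr_matrix(sp.hstack([A, sp.csr_matrix((A.shape[0], ntot - n))]))
        b_eq = np.asarray(problem.b_eq, float)

    lb0, ub0 = problem.bounds_arrays()
    lb = np.concatenate([lb0, np.zeros(ntot - n)])
    ub = np.concatenate([ub0, np.full(ntot - n, _INF)])
    lp = LinearProgram(c=np.zeros(ntot), A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, lb=lb, ub=ub)
    return lp, aJ, aK, sK


def solve_cardinality(
    problem: CardinalityProblem,
    approx: StepApprox | None = None,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> CardinalitySolution:
    """Approximately solve a cardinality problem with DCA over LP subproblems.

    With default settings this runs a single DCA sequence (typically two to
    three LPs).  ``settings.backoff``/``settings.restarts`` additionally run
    an escape local search and weight-perturbed restarts, keeping the best
    (smallest weighted min-cardinality) solution found.
    """
    approx = approx or StepApprox()
    settings = settings or DCASettings()
    be = get_backend(backend)

    best = _solve_dca_once(problem, approx, settings, be)
    use_extras = (settings.backoff or settings.restarts > 0) and problem.min_idx.size \
        and not problem.max_idx.size and best.status != "infeasible"
    if not use_extras:
        return best

    lp_total = best.lp_count
    weight_of = dict(zip(problem.min_idx.tolist(), problem.min_weights))

    def card_of(sol: CardinalitySolution) -> float:
        return sum(weight_of[int(j)] for j in sol.support_min)

    if settings.backoff:
        best, extra = _backoff(problem, best, card_of, approx, settings, be)
        lp_total += extra
    rng = np.random.default_rng(settings.restart_seed)
    for _ in range(settings.restarts):
        if not len(best.support_min):
            break
        perturbed = CardinalityProblem(
            n=problem.n, A_eq=problem.A_eq, b_eq=problem.b_eq,
            A_ub=problem.A_ub, b_ub=problem.b_ub, lb=problem.lb, ub=problem.ub,
            min_idx=problem.min_idx,
            min_weights=problem.min_weights * rng.uniform(0.5, 1.5, problem.min_idx.size),
            cost=problem.cost)
        cand = _solve_dca_once(perturbed, approx, settings, be)
        lp_total += cand.lp_count
        if cand.status != "infeasible" and settings.backoff:
            cand, extra = _backoff(perturbed, cand, card_of, approx, settings, be)
            lp_total += extra
        if cand.status != "infeasible" and card_of(cand) < card_of(best):
            best = cand
    best.lp_count = lp_total
    return best


def _backoff(problem: CardinalityProblem, sol: CardinalitySolution, card_of,
             approx: StepApprox, settings: DCASettings, be: LPBackend,
             ) -> tuple[CardinalitySolution, int]:
    """Escape step: tentatively force support members (weakest first) to zero
    and re-run the DCA; accept any strict weighted-cardinality improvement."""
    plain = DCASettings(**{**settings.__dict__, "restarts": 0, "backoff": False})
    best = sol
    lp_extra = 0
    improved = True
    while improved and len(best.support_min):
        improved = False
        for j in sorted(best.support_min, key=lambda j: abs(best.x[j])):
            lb, ub = problem.bounds_arrays()
            if not _fix_to_zero(lb, ub, j):
                continue
            sub = CardinalityProblem(
                n=problem.n, A_eq=problem.A_eq, b_eq=problem.b_eq,
                A_ub=problem.A_ub, b_ub=problem.b_ub, lb=lb, ub=ub,
                min_idx=problem.min_idx, min_weights=problem.min_weights,
                cost=problem.cost)
            cand = _solve_dca_once(sub, approx, plain, be)
            lp_extra += cand.lp_count
            if cand.status != "infeasible" and card_of(cand) < card_of(best):
                best = cand
                improved = True
                break
    return best, lp_extra


def _solve_dca_once(
    problem: CardinalityProblem,
    approx: StepApprox,
    settings: DCASettings,
    be: LPBackend,
) -> CardinalitySolution:

    # zero-weight cardinality entries carry no objective pressure: treat as z
    J = problem.min_idx[problem.min_weights > 0]
    lamJ = problem.min_weights[problem.min_weights > 0]
    K = problem.max_idx[problem.max_weights > 0]
    delK = problem.max_weights[problem.max_weights > 0]

    if K.size and approx.kind != "cappedL1":
        raise NotImplementedError(
            f"cardinality maximization via LP subproblems is only available for "
            f"the cappedL1 family, not {approx.kind!r}")
    lb0, ub0 = problem.bounds_arrays()
    if K.size and (np.any(np.isinf(lb0[K])) or np.any(np.isinf(ub0[K]))):
        raise ValueError("cardinality-maximized variables require finite bounds")

    cost = problem.cost_array()
    theta = settings.theta0
    incumbent = np.zeros(problem.n)
    trace: list[float] = []
    pairs: list[tuple[float, float]] = []
    prev_supp: tuple[frozenset, frozenset] | None = None
    lp_count = 0
    status = "iteration-limit"

    # preferred drive direction for maximize entries at a zero incumbent
    bias = np.where(ub0 > 0, 1.0, np.where(lb0 < 0, -1.0, 0.0))

    for it in range(1, settings.max_outer + 1):
        ap = approx.with_theta(theta)
        lp, aJ, aK, sK = _assemble_lp(problem, J, K, theta)
        c = lp.c
        c[: problem.n] = cost.copy()
        # minimize block: phi = s0*sum(lam*a); linearized subtracted piece at incumbent
        if J.size:
            c[aJ] = ap.s0 * lamJ
            gJ = np.sign(incumbent[J]) * (ap.s0 - ap._dpsi_u(np.abs(incumbent[J])))
            c[J] -= lamJ * gJ
        # maximize block (cappedL1): phi epigraph via s; subtracted s0*|y| linearized
        if K.size:
            c[sK] = delK
            sgn = np.sign(incumbent[K])
            sgn = np.where(np.abs(incumbent[K]) > settings.eps_supp, sgn, bias[K])
            c[K] -= delK * ap.s0 * sgn

        pre = _true_objective(problem, ap, incumbent)
        res = be.solve(lp, warm=None if it == 1 else incumbent)
        lp_count += 1
        if res.status == "infeasible":
            return CardinalitySolution(
                status="infeasible", x=None,
                support_min=np.array([], int), support_max=np.array([], int),
                iterations=it, lp_count=lp_count, trace=trace, descent_pairs=pairs,
                message=res.message)
        if res.status == "unbounded":
            raise UnboundedProblemError(
                "LP subproblem unbounded — check the linear-cost block and bounds")
        if res.status != "optimal":
            raise RuntimeError(f"LP backend failure: {res.message}")

        v = res.x[: problem.n]
        post = _true_objective(problem, ap, v)
        if it > 1:  # iteration 1 starts from an arbitrary (possibly infeasible) origin
            pairs.append((pre, post))
        trace.append(post)
        incumbent = v

        supp = (frozenset(np.flatnonzero(np.abs(v[J]) > settings.eps_supp)),
                frozenset(np.flatnonzero(np.abs(v[K]) > settings.eps_supp)))
        if prev_supp is not None and supp == prev_supp and abs(post - pre) < settings.tol:
            status = "optimal-approx"
            break
        prev_supp = supp
        theta = min(theta * settings.theta_factor, settings.theta_max)
    else:
        it = settings.max_outer

    v = incumbent
    supp_min = problem.min_idx[np.abs(v[problem.min_idx]) > settings.eps_supp] \
        if problem.min_idx.size else np.array([], int)
    supp_max = problem.max_idx[np.abs(v[problem.max_idx]) > settings.eps_supp] \
        if problem.max_idx.size else np.array([], int)

    if settings.polish and problem.min_idx.size:
        v2 = _polish_min_support(problem, v, supp_min, be)
        if v2 is not None:
            v = v2
            supp_min = problem.min_idx[np.abs(v[problem.min_idx]) > settings.eps_supp]
            supp_max = problem.max_idx[np.abs(v[problem.max_idx]) > settings.eps_supp] \
                if problem.max_idx.size else supp_max
        else:
            # reported support insufficient for feasibility: fall back to the
            # machine-tolerance support so the size never undershoots
            supp_min = problem.min_idx[np.abs(v[problem.min_idx]) > 1e-9]

    return CardinalitySolution(
        status=status, x=v, support_min=supp_min, support_max=supp_max,
        iterations=it, lp_count=lp_count, trace=trace, descent_pairs=pairs,
        objective=_true_objective(problem, approx.with_theta(theta), v))


def _polish_min_support(problem: CardinalityProblem, v: np.ndarray,
                        supp_min: np.ndarray, be: LPBackend) -> np.ndarray | None:
    """Re-solve restricted to the reported support; None if infeasible."""
    lb, ub = problem.bounds_arrays()
    off = np.setdiff1d(problem.min_idx, supp_min)
    if not _fix_to_zero(lb, ub, off):
        return None
    res = be.solve(problem.feasibility_lp(lb=lb, ub=ub))
    return res.x if res.ok else None


def brute_force_min_card(
    problem: CardinalityProblem,
    max_n: int = 20,
    backend: str | LPBackend = "highs",
) -> tuple[int | None, np.ndarray | None]:
    """Exact minimum cardinality by support enumeration (small instances).

    Returns ``(card, witness)`` or ``(None, None)`` when the polyhedron is
    infeasible.  Only pure minimization problems are supported.
    """
    if problem.max_idx.size:
        raise ValueError("brute force oracle handles cardinality minimization only")
    J = problem.min_idx
    if J.size > max_n:
        raise ValueError(f"too many cardinality variables for brute force ({J.size} > {max_n})")
    be = get_backend(backend)
    lb0, ub0 = problem.bounds_arrays()
    for size in range(J.size + 1):
        for support in itertools.combinations(J.tolist(), size):
            lb, ub = lb0.copy(), ub0.copy()
            off = np.setdiff1d(J, np.asarray(support, dtype=int))
            if not _fix_to_zero(lb, ub, off):
                continue
            res = be.solve(problem.feasibility_lp(lb=lb, ub=ub))
            if res.ok:
                return size, res.x
    return None, None


def verify_support_minimality(
    problem: CardinalityProblem,
    support: np.ndarray,
    backend: str | LPBackend = "highs",
) -> dict[int, bool]:
    """One-by-one removal test: can each support member be forced to zero
    while the remaining support alone keeps the problem feasible?

    Returns {index: removable}.  The support is locally minimal iff no
    member is removable.  An empty support is vacuously minimal.
    """
    be = get_backend(backend)
    support = np.asarray(support, dtype=int)
    lb0, ub0 = problem.bounds_arrays()
    off = np.setdiff1d(problem.min_idx, support)
    if not _fix_to_zero(lb0, ub0, off):
        return {int(j): False for j in support}
    removable: dict[int, bool] = {}
    for j in support:
        lb, ub = lb0.copy(), ub0.copy()
        if not _fix_to_zero(lb, ub, j):
            removable[int(j)] = False
            continue
        removable[int(j)] = be.solve(problem.feasibility_lp(lb=lb, ub=ub)).ok
    return removable
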