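"""Flux consistency and thermodynamic flux consistency testing.

A reaction is *flux consistent* when it admits a nonzero steady-state flux
within the given bounds (S v = b, l <= v <= u).  The exact set is found by
amalgamating supports of repeated cardinality-maximization solves, settling
whatever remains ambiguous with per-reaction LPs (maximize then minimize
v_j), so the reported set always equals the 2n-LP oracle.

A reaction is *thermodynamically flux consistent* when it admits a nonzero
steady-state flux whose direction opposes a chemical-potential difference:
there must exist y (proportional to chemical potentials) with
z_j > 0 => N_j^T y < 0 and z_j < 0 => N_j^T y > 0 for every active internal
reaction.  Net flux around a stoichiometrically balanced internal cycle can
never satisfy this, so candidate fluxes are projected to cycle-free ones
(weighted one-norm minimization at fixed exchange flux with sign-restricted
bounds) and certified by a potential-feasibility LP; by a Gordan-type
theorem of the alternative, infeasibility of the potential LP is witnessed
by a sign-concordant internal cycle, and vice versa.  The amalgamated
thermo-consistent set is an underestimate of the (nonconvex) exact set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dc_solver import CardinalityProblem, DCASettings, solve_cardinality
from .lp import LinearProgram, LPBackend, get_backend
from .model_io import DEFAULT_BOUND, MetabolicModel, StoichPartition, split_internal_external

__all__ = [
    "FluxConsistencyResult",
    "ThermoSolution",
    "ThermoConsistencyResult",
    "find_flux_consistent_subset",
    "oracle_flux_consistent",
    "sign_pattern_admits_potentials",
    "find_thermo_flux_consistent_subset",
]

logger = logging.getLogger(__name__)

EPS_POT = 1.0  # potentials are scale-free; strict inequality normalized to <= -1


@dataclass
class FluxConsistencyResult:
    consistent: set[str]
    blocked: set[str]
    forward: set[str]   # reactions seen carrying positive flux
    reverse: set[str]   # reactions seen carrying negative flux
    lp_count: int = 0

    def to_dict(self) -> dict:
        return {"consistent": sorted(self.consistent), "blocked": sorted(self.blocked)}


def _clip_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    return (np.clip(model.lb, -DEFAULT_BOUND, DEFAULT_BOUND),
            np.clip(model.ub, -DEFAULT_BOUND, DEFAULT_BOUND))


def find_flux_consistent_subset(
    model: MetabolicModel,
    eps: float = 1e-6,
    max_rounds: int = 20,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> FluxConsistencyResult:
    """Reactions admitting a nonzero steady-state flux, exactly.

    Repeated cardinality maximization (dropping already-covered reactions
    from the objective each round) amalgamates most of the set cheaply; the
    per-reaction LP pair then settles every reaction the heuristic leaves
    ambiguous, so the result matches the per-reaction oracle.
    """
    be = get_backend(backend)
    lb, ub = _clip_bounds(model)
    covered_f: set[int] = set()
    covered_r: set[int] = set()
    lp_count = 0
    base = CardinalityProblem(n=model.n, A_eq=model.S.tocsr(), b_eq=model.b,
                              lb=lb, ub=ub, max_idx=np.arange(model.n))

    def absorb(v: np.ndarray) -> int:
        before = len(covered_f) + len(covered_r)
        covered_f.update(np.flatnonzero(v > eps).tolist())
        covered_r.update(np.flatnonzero(v < -eps).tolist())
        return len(covered_f) + len(covered_r) - before

    for _ in range(max_rounds):
        uncovered = np.setdiff1d(np.arange(model.n), np.fromiter(covered_f | covered_r, int,
                                                                 len(covered_f | covered_r)))
        if uncovered.size == 0:
            break
        weights = np.zeros(model.n)
        weights[uncovered] = 1.0
        problem = CardinalityProblem(n=model.n, A_eq=base.A_eq, b_eq=base.b_eq,
                                     lb=lb, ub=ub, max_idx=np.arange(model.n),
                                     max_weights=weights)
        sol = solve_cardinality(problem, settings=settings, backend=be)
        lp_count += sol.lp_count
        if sol.status == "infeasible":
            break
        if absorb(sol.x) == 0:
            break

    # settle the remainder exactly: max v_j then min v_j
    for j in range(model.n):
        for direction, seen in ((1.0, covered_f), (-1.0, covered_r)):
            if j in seen:
                continue
            c = np.zeros(model.n)
            c[j] = -direction
            res = be.solve(LinearProgram(c=c, A_eq=base.A_eq, b_eq=base.b_eq, lb=lb, ub=ub))
            lp_count += 1
            if res.ok:
                absorb(res.x)

    covered = covered_f | covered_r
    return FluxConsistencyResult(
        consistent={model.rxn_ids[j] for j in covered},
        blocked={model.rxn_ids[j] for j in range(model.n) if j not in covered},
        forward={model.rxn_ids[j] for j in covered_f},
        reverse={model.rxn_ids[j] for j in covered_r},
        lp_count=lp_count)


def oracle_flux_consistent(
    model: MetabolicModel,
    eps: float = 1e-6,
    backend: str | LPBackend = "highs",
) -> set[str]:
    """Plain 2n-LP oracle: per reaction, maximize then minimize v_j."""
    be = get_backend(backend)
    lb, ub = _clip_bounds(model)
    out: set[str] = set()
    for j in range(model.n):
        for direction in (1.0, -1.0):
            c = np.zeros(model.n)
            c[j] = -direction
            res = be.solve(LinearProgram(c=c, A_eq=model.S.tocsr(), b_eq=model.b, lb=lb, ub=ub))
            if res.ok and direction * res.x[j] > eps:
                out.add(model.rxn_ids[j])
                break
    return out


# ---------------------------------------------------------------------------
# thermodynamic flux consistency
# ---------------------------------------------------------------------------

@dataclass
class ThermoSolution:
    """A certified thermodynamically consistent flux: internal z, external w,
    potentials y, and the internal sign pattern sigma."""

    z: np.ndarray
    w: np.ndarray
    y: np.ndarray
    sigma: np.ndarray


@dataclass
class ThermoConsistencyResult:
    consistent: set[str]
    inconsistent: set[str]
    forward: set[str]
    reverse: set[str]
    witnesses: list[ThermoSolution] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"consistent": sorted(self.consistent),
                "inconsistent": sorted(self.inconsistent), "seed": self.seed}


def sign_pattern_admits_potentials(
    N: sp.spmatrix,
    sigma: np.ndarray,
    eps_pot: float = EPS_POT,
    backend: str | LPBackend = "highs",
) -> tuple[bool, np.ndarray | None, np.ndarray | None]:
    """Does the internal sign pattern sigma admit chemical potentials?

    Feasibility of {sigma_j * (N^T y)_j <= -eps_pot for sigma_j != 0}.
    Returns (feasible, y, cycle): when infeasible, ``cycle`` is the dual
    certificate — a nonzero internal circulation c with N c = 0 and
    sigma_j c_j >= 0, supported on the active reactions (a sign-concordant
    stoichiometrically balanced cycle).
    """
    N = sp.csc_matrix(N)
    m, n = N.shape
    sigma = np.asarray(sigma, float)
    active = np.flatnonzero(np.abs(sigma) > 0)
    be = get_backend(backend)
    if active.size == 0:
        return True, np.zeros(m), None
    rows = sp.diags(sigma[active]) @ N[:, active].T  # (n_act x m)
    res = be.solve(LinearProgram(
        c=np.zeros(m), A_ub=rows.tocsr(), b_ub=np.full(active.size, -eps_pot)))
    if res.ok:
        return True, res.x, None
    # Gordan alternative: c >= 0, sum_j c_j sigma_j N_j = 0, sum c = 1
    Acol = N[:, active] @ sp.diags(sigma[active])
    A_eq = sp.vstack([Acol, np.ones((1, active.size))]).tocsr()
    res2 = be.solve(LinearProgram(
        c=np.zeros(active.size), A_eq=A_eq,
        b_eq=np.concatenate([np.zeros(m), [1.0]]),
        lb=np.zeros(active.size)))
    if not res2.ok:
        raise RuntimeError("theorem-of-the-alternative violated: both the potential "
                           "LP and the cycle LP are infeasible")
    cycle = np.zeros(n)
    cycle[active] = sigma[active] * res2.x
    return False, None, cycle


def _cycle_free_projection(
    model: MetabolicModel,
    internal: np.ndarray,
    external: np.ndarray,
    v: np.ndarray,
    weights: np.ndarray,
    eps: float,
    be: LPBackend,
) -> np.ndarray | None:
    """Weighted one-norm-minimal internal flux z with N z = -B w(fixed),
    sign(z_j) in {0, sign(v_j)}: removes every cycle concordant with its own
    signs, so the projected pattern always admits potentials."""
    n_int = internal.size
    N = model.S[:, internal].tocsr()
    B = model.S[:, external].tocsr() if external.size else None
    rhs = model.b - (B @ v[external] if B is not None else 0.0)
    lb = np.zeros(n_int)
    ub = np.zeros(n_int)
    lbm, ubm = _clip_bounds(model)
    pos = v[internal] > eps
    neg = v[internal] < -eps
    ub[pos] = ubm[internal][pos]
    lb[neg] = lbm[internal][neg]
    # [z, a] with a >= |z|
    A_eq = sp.hstack([N, sp.csr_matrix((N.shape[0], n_int))], format="csr")
    A_abs = sp.hstack([sp.vstack([sp.identity(n_int), -sp.identity(n_int)]),
                       sp.vstack([-sp.identity(n_int), -sp.identity(n_int)])], format="csr")
    res = be.solve(LinearProgram(
        c=np.concatenate([np.zeros(n_int), weights]),
        A_eq=A_eq, b_eq=rhs, A_ub=A_abs, b_ub=np.zeros(2 * n_int),
        lb=np.concatenate([lb, np.zeros(n_int)]),
        ub=np.concatenate([ub, np.full(n_int, np.inf)])))
    return res.x[:n_int] if res.ok else None


def find_thermo_flux_consistent_subset(
    model: MetabolicModel,
    partition: StoichPartition | None = None,
    flux_result: FluxConsistencyResult | None = None,
    max_rounds: int = 20,
    seed: int = 0,
    eps: float = 1e-6,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> ThermoConsistencyResult:
    """Amalgamated thermodynamically flux consistent subset (underestimate).

    Loop: (1) propose a candidate flux by cardinality maximization over the
    not-yet-covered flux-consistent reactions (with seeded random objective
    perturbations for diversity); (2) project it to a cycle-free flux with
    the same exchange part; (3) certify the sign pattern with the potential
    LP and record the witness; (4) amalgamate the support.  When a full
    round adds nothing, remaining reactions are probed one by one (maximize
    |v_j|, project, certify) before being declared thermo-inconsistent —
    any internal reaction with zero flux in every certified vector.
    """
    partition = partition or split_internal_external(model)
    if flux_result is None:
        flux_result = find_flux_consistent_subset(model, eps=eps, backend=backend)
    be = get_backend(backend)
    rng = np.random.default_rng(seed)
    internal = partition.internal_cols
    external = partition.external_cols
    N = model.S[:, internal]
    rid = model.rxn_ids
    fluxcons = np.array([j for j in range(model.n) if rid[j] in flux_result.consistent],
                        dtype=int)
    lb, ub = _clip_bounds(model)
    int_pos = {int(j): k for k, j in enumerate(internal)}

    covered_f: set[int] = set()
    covered_r: set[int] = set()
    witnesses: list[ThermoSolution] = []

    def certify(v: np.ndarray) -> bool:
        """Project v, certify the pattern, absorb the support. True if new."""
        weights = np.ones(internal.size)
        for j in fluxcons:
            if j in int_pos and j not in covered_f and j not in covered_r:
                weights[int_pos[j]] = 1e-2  # prefer keeping uncovered reactions active
        z = _cycle_free_projection(model, internal, external, v, weights, eps, be)
        if z is None:
            return False
        sigma = np.where(z > eps, 1.0, np.where(z < -eps, -1.0, 0.0))
        w = v[external] if external.size else np.zeros(0)
        if not np.any(sigma != 0) and not np.any(np.abs(w) > eps):
            return False
        feasible, y, _ = sign_pattern_admits_potentials(N, sigma, backend=be)
        if not feasible:  # cannot happen for a one-norm-minimal projection
            logger.warning("projected flux failed potential certification; skipped")
            return False
        witnesses.append(ThermoSolution(z=z, w=np.asarray(w), y=y, sigma=sigma))
        before = len(covered_f) + len(covered_r)
        for k, j in enumerate(internal):
            if sigma[k] > 0:
                covered_f.add(int(j))
            elif sigma[k] < 0:
                covered_r.add(int(j))
        for k, j in enumerate(external):
            if abs(w[k]) > eps:
                (covered_f if w[k] > 0 else covered_r).add(int(j))
        return len(covered_f) + len(covered_r) > before

    for _ in range(max_rounds):
        uncovered = [j for j in fluxcons if j not in covered_f and j not in covered_r]
        if not uncovered:
            break
        weights = np.zeros(model.n)
        weights[uncovered] = 1.0 + 0.1 * rng.random(len(uncovered))
        problem = CardinalityProblem(n=model.n, A_eq=model.S.tocsr(), b_eq=model.b,
                                     lb=lb, ub=ub, max_idx=np.arange(model.n),
                                     max_weights=weights)
        sol = solve_cardinality(problem, settings=settings, backend=be)
        if sol.status == "infeasible" or sol.x is None:
            break
        if not certify(sol.x):
            break

    # targeted probe of stragglers, both directions
    for j in [j for j in fluxcons if j not in covered_f and j not in covered_r]:
        for direction in (1.0, -1.0):
            c = np.zeros(model.n)
            c[j] = -direction
            res = be.solve(LinearProgram(c=c, A_eq=model.S.tocsr(), b_eq=model.b, lb=lb, ub=ub))
            if res.ok and direction * res.x[j] > eps:
                certify(res.x)
            if j in covered_f or j in covered_r:
                break

    covered = covered_f | covered_r
    consistent = {rid[j] for j in fluxcons if j in covered}
    return ThermoConsistencyResult(
        consistent=consistent,
        inconsistent=flux_result.consistent - consistent,
        forward={rid[j] for j in covered_f},
        reverse={rid[j] for j in covered_r},
        witnesses=witnesses, seed=seed)
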