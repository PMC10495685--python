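"""Stoichiometric consistency testing and leak/siphon detection.

A set of internal reactions N is stoichiometrically consistent when every
metabolite can be assigned a strictly positive molecular mass l with
N^T l = 0 — no internal reaction creates or destroys mass.  Instead of
maximizing the number of conserved metabolites, consistency is tested here
by *minimizing the number of mass-conservation constraints that must be
relaxed*:

    min card(x)  s.t.  N^T w + x = 0,  w >= 1.

If card(x*) = 0 the internal network is fully consistent; reactions with
x_j* = 0 are consistent.  Reactions still requiring relaxation are of
*unknown* consistency, because omitting some of them may render others
consistent; a sequential loop therefore omits, per round, the relaxed
reactions that are also apparently elementally imbalanced (or, lacking
formulae, those with the most nonzero coefficients — lumped reactions),
and re-solves until the relaxation cardinality stops shrinking.

Leaks (metabolites producible from nothing) and siphons (consumable to
nothing) are found by maximizing the cardinality of a production vector y
over {S v = y, y >= 0, l <= v <= u}, then confirming each candidate — and
every remaining metabolite — with an individual LP, so the reported sets
are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .chem import ReactionBalance, elemental_imbalance
from .dc_solver import CardinalityProblem, CardinalitySolution, DCASettings, solve_cardinality
from .lp import LinearProgram, LPBackend, get_backend
from .model_io import DEFAULT_BOUND, MetabolicModel, StoichPartition, split_internal_external
from .step_approx import StepApprox

__all__ = [
    "ConservationVector",
    "ConsistencyPartition",
    "LeakSiphonResult",
    "check_full_consistency",
    "min_conservation_relaxation",
    "find_stoich_consistent_subset",
    "find_leaks_siphons",
    "minimal_leak_mode",
]

logger = logging.getLogger(__name__)

_W_MAX = 1e6  # upper cap on molecular masses, for LP conditioning


@dataclass
class ConservationVector:
    """Positive masses w (>= 1) and the per-reaction relaxation x."""

    w: np.ndarray
    x: np.ndarray
    solution: CardinalitySolution | None = None

    def support(self, eps: float = 1e-6) -> np.ndarray:
        return np.flatnonzero(np.abs(self.x) > eps)


@dataclass
class ConsistencyPartition:
    """Per-reaction and per-metabolite stoichiometric-consistency labels.

    Reaction labels: stoich_consistent | stoich_inconsistent |
    omitted_unknown | external.  Metabolite labels: stoich_consistent |
    not_consistent | omitted | external.
    """

    rxn_labels: dict[str, str]
    met_labels: dict[str, str]
    rounds: list[dict] = field(default_factory=list)

    def reactions(self, label: str) -> list[str]:
        return [r for r, lab in self.rxn_labels.items() if lab == label]

    def metabolites(self, label: str) -> list[str]:
        return [m for m, lab in self.met_labels.items() if lab == label]

    def to_records(self) -> list[dict]:
        recs = [{"id": r, "kind": "reaction", "label": lab} for r, lab in self.rxn_labels.items()]
        recs += [{"id": m, "kind": "metabolite", "label": lab} for m, lab in self.met_labels.items()]
        return recs


def check_full_consistency(
    N: sp.spmatrix,
    backend: str | LPBackend = "highs",
) -> tuple[bool, np.ndarray | None]:
    """LP feasibility of {N^T l = 0, l >= 1}; returns (ok, l)."""
    N = sp.csc_matrix(N)
    m, n = N.shape
    if n == 0:
        return True, np.ones(m)
    lp = LinearProgram(
        c=np.ones(m),  # smallest total mass certificate
        A_eq=N.T.tocsr(), b_eq=np.zeros(n),
        lb=np.ones(m), ub=np.full(m, _W_MAX))
    res = get_backend(backend).solve(lp)
    return (True, res.x) if res.ok else (False, None)


def min_conservation_relaxation(
    N: sp.spmatrix,
    approx: StepApprox | None = None,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
    weights: np.ndarray | float = 1.0,
) -> ConservationVector:
    """Minimum-cardinality relaxation x of mass conservation N^T w + x = 0,
    w >= 1 (variables [w, x]; card is minimized over x only).

    ``weights`` break ties among equal-cardinality relaxation supports
    (e.g. marginally cheaper relaxation of suspect reactions)."""
    N = sp.csc_matrix(N)
    m, n = N.shape
    if n == 0:
        return ConservationVector(w=np.ones(m), x=np.zeros(0))
    A_eq = sp.hstack([N.T.tocsr(), sp.identity(n, format="csr")], format="csr")
    problem = CardinalityProblem(
        n=m + n,
        A_eq=A_eq, b_eq=np.zeros(n),
        lb=np.concatenate([np.ones(m), np.full(n, -np.inf)]),
        ub=np.concatenate([np.full(m, _W_MAX), np.full(n, np.inf)]),
        min_idx=np.arange(m, m + n),
        min_weights=weights)
    sol = solve_cardinality(problem, approx=approx, settings=settings, backend=backend)
    if sol.status == "infeasible":  # cannot happen: x absorbs any imbalance
        raise RuntimeError("conservation relaxation LP unexpectedly infeasible")
    return ConservationVector(w=sol.x[:m], x=sol.x[m:], solution=sol)


def _maxnnz_subset(model: MetabolicModel, cols: np.ndarray) -> np.ndarray:
    """Columns with the highest nonzero count (lumped reactions); ties kept
    together, ordered deterministically by larger sum|S_ij| then id."""
    nnz = model.column_nnz()[cols]
    top = cols[nnz == nnz.max()]
    weight = np.asarray(np.abs(model.S[:, top]).sum(axis=0)).ravel()
    order = sorted(range(len(top)), key=lambda k: (-weight[k], model.rxn_ids[top[k]]))
    return top[np.asarray(order, dtype=int)]


def find_stoich_consistent_subset(
    model: MetabolicModel,
    partition: StoichPartition | None = None,
    criterion: str = "elemental",
    max_rounds: int = 20,
    approx: StepApprox | None = None,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
    eps_supp: float = 1e-6,
) -> ConsistencyPartition:
    """Sequential omission loop labelling every reaction and metabolite.

    Each round solves the minimum conservation relaxation on the remaining
    internal columns; among reactions still requiring relaxation the
    criterion-selected subset is omitted (elementally imbalanced ones by
    default, falling back to the most-coefficients rule when none qualify)
    and the problem is re-solved, until the relaxation cardinality stops
    decreasing, nothing qualifies, or ``max_rounds`` is reached.
    """
    if criterion not in ("elemental", "maxnnz"):
        raise ValueError(f"unknown omission criterion {criterion!r}")
    partition = partition or split_internal_external(model)
    balance: dict[str, ReactionBalance] = {}
    if criterion == "elemental":
        if model.met_formula is None:
            logger.warning("no metabolite formulae available; falling back to maxnnz")
            criterion = "maxnnz"
        else:
            balance = elemental_imbalance(model, partition)

    remaining = np.array(sorted(partition.internal_cols), dtype=int)
    omitted: list[tuple[int, int, str]] = []  # (col, round, criterion used)
    rounds: list[dict] = []
    prev_card = np.inf
    final_inconsistent: np.ndarray = np.array([], dtype=int)

    # the relaxation support is rarely unique; bias ties toward apparently
    # imbalanced reactions, which are the prime suspects the criterion omits,
    # and solve with the escape/restart preset so near-tie supports are found
    imbalanced_cols = {j for j in partition.internal_cols
                       if balance.get(model.rxn_ids[j]) is not None
                       and balance[model.rxn_ids[j]].status == "imbalanced"}
    if settings is None:
        settings = DCASettings.robust()

    for round_no in range(1, max_rounds + 1):
        weights = np.array([0.9 if j in imbalanced_cols else 1.0 for j in remaining])
        cv = min_conservation_relaxation(model.S[:, remaining], approx, settings,
                                         backend, weights=weights)
        supp = remaining[cv.support(eps_supp)]
        card = supp.size
        rounds.append({"round": round_no, "relaxation_card": int(card),
                       "remaining": int(remaining.size),
                       "omitted": []})
        if card == 0:
            final_inconsistent = np.array([], dtype=int)
            break
        if card >= prev_card:  # no smaller relaxation obtainable: stop
            final_inconsistent = supp
            break
        prev_card = card

        if criterion == "elemental":
            qualify = np.array(
                [j for j in supp if balance.get(model.rxn_ids[j]) is not None
                 and balance[model.rxn_ids[j]].status == "imbalanced"], dtype=int)
            used = "elemental"
            if qualify.size == 0:
                qualify = _maxnnz_subset(model, supp)
                used = "maxnnz-fallback"
                logger.info("round %d: no relaxed reaction elementally imbalanced; "
                            "omitting by maxnnz instead", round_no)
        else:
            qualify = _maxnnz_subset(model, supp)
            used = "maxnnz"

        omitted.extend((int(j), round_no, used) for j in qualify)
        rounds[-1]["omitted"] = [model.rxn_ids[j] for j in qualify]
        remaining = np.setdiff1d(remaining, qualify)
        final_inconsistent = np.setdiff1d(supp, qualify)
        if remaining.size == 0:
            break
    # else: max_rounds exhausted — keep the last round's labels

    omitted_cols = np.array([j for j, _, _ in omitted], dtype=int)
    consistent = np.setdiff1d(remaining, final_inconsistent)

    rxn_labels: dict[str, str] = {}
    for j in partition.external_cols:
        rxn_labels[model.rxn_ids[j]] = "external"
    for j in consistent:
        rxn_labels[model.rxn_ids[j]] = "stoich_consistent"
    for j in final_inconsistent:
        rxn_labels[model.rxn_ids[j]] = "stoich_inconsistent"
    for j in omitted_cols:
        rxn_labels[model.rxn_ids[j]] = "omitted_unknown"

    # metabolite labels: consistent iff exclusively in consistent internal rxns
    S = model.S.tocsr()
    internal_set = set(partition.internal_cols.tolist())
    met_labels: dict[str, str] = {}
    incons_set = set(final_inconsistent.tolist())
    omit_set = set(omitted_cols.tolist())
    for i, mid in enumerate(model.met_ids):
        cols = set(S.indices[S.indptr[i]:S.indptr[i + 1]].tolist()) & internal_set
        if not cols:
            met_labels[mid] = "external"
        elif cols & incons_set:
            met_labels[mid] = "not_consistent"
        elif cols & omit_set:
            met_labels[mid] = "omitted"
        else:
            met_labels[mid] = "stoich_consistent"

    return ConsistencyPartition(rxn_labels=rxn_labels, met_labels=met_labels, rounds=rounds)


# ---------------------------------------------------------------------------
# leaks and siphons
# ---------------------------------------------------------------------------

@dataclass
class LeakSiphonResult:
    leaks: set[str]
    siphons: set[str]
    leak_witness: dict[str, np.ndarray] = field(default_factory=dict)
    siphon_witness: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"leaks": sorted(self.leaks), "siphons": sorted(self.siphons)}


def _closed_bounds(model: MetabolicModel, partition: StoichPartition) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.lb.copy(), model.ub.copy()
    lb[partition.external_cols] = 0.0
    ub[partition.external_cols] = 0.0
    return lb, ub


def _leak_problem(model: MetabolicModel, lb: np.ndarray, ub: np.ndarray,
                  sign: float) -> CardinalityProblem:
    """Variables [v (n), y (m)]; S v - sign*y = 0, y in [0, cap]."""
    m, n = model.m, model.n
    A_eq = sp.hstack([model.S.tocsr(), -sign * sp.identity(m, format="csr")], format="csr")
    lb_v = np.clip(lb, -DEFAULT_BOUND, DEFAULT_BOUND)
    ub_v = np.clip(ub, -DEFAULT_BOUND, DEFAULT_BOUND)
    return CardinalityProblem(
        n=n + m, A_eq=A_eq, b_eq=np.zeros(m),
        lb=np.concatenate([lb_v, np.zeros(m)]),
        ub=np.concatenate([ub_v, np.full(m, DEFAULT_BOUND)]),
        max_idx=np.arange(n, n + m))


def find_leaks_siphons(
    model: MetabolicModel,
    partition: StoichPartition | None = None,
    closed: bool = True,
    eps: float = 1e-6,
    backend: str | LPBackend = "highs",
    settings: DCASettings | None = None,
) -> LeakSiphonResult:
    """Exact leak and siphon metabolite sets.

    A metabolite i is a leak when some admissible flux strictly produces it
    from nothing (S v = y >= 0 with y_i > 0); a siphon consumes it to
    nothing (S v = -y).  With ``closed`` the external reaction bounds are
    zeroed first, so a fully mass-conserving network can have neither.  One
    cardinality-maximization solve proposes candidates; every metabolite is
    then settled by an individual confirmation LP, making the result exact.
    """
    partition = partition or split_internal_external(model)
    lb, ub = _closed_bounds(model, partition) if closed else (model.lb, model.ub)
    be = get_backend(backend)
    result = LeakSiphonResult(leaks=set(), siphons=set())
    for sign, found, witness in ((1.0, result.leaks, result.leak_witness),
                                 (-1.0, result.siphons, result.siphon_witness)):
        problem = _leak_problem(model, lb, ub, sign)
        sol = solve_cardinality(problem, settings=settings, backend=be)
        y = sol.x[model.n:] if sol.x is not None else np.zeros(model.m)
        candidates = [i for i in range(model.m) if y[i] > eps]
        confirmed: set[int] = set()
        for i in candidates + [i for i in range(model.m) if i not in set(candidates)]:
            if i in confirmed:
                continue
            lp = LinearProgram(
                c=_unit_neg(model.n + model.m, model.n + i),  # max y_i
                A_eq=problem.A_eq, b_eq=problem.b_eq,
                lb=problem.lb, ub=np.minimum(problem.ub, _cap_y(model, i)))
            res = be.solve(lp)
            if res.ok and res.x[model.n + i] > eps:
                # every strictly produced metabolite in this mode is confirmed too
                for k in np.flatnonzero(res.x[model.n:] > eps):
                    if int(k) not in confirmed:
                        confirmed.add(int(k))
                        witness[model.met_ids[int(k)]] = res.x[:model.n]
        found.update(model.met_ids[i] for i in confirmed)
    return result


def _unit_neg(n: int, idx: int) -> np.ndarray:
    c = np.zeros(n)
    c[idx] = -1.0
    return c


def _cap_y(model: MetabolicModel, i: int) -> np.ndarray:
    ub = np.full(model.n + model.m, np.inf)
    ub[model.n + i] = 1.0  # normalize the maximized leak to avoid unbounded LPs
    return ub


def minimal_leak_mode(
    model: MetabolicModel,
    met_id: str,
    kind: str = "leak",
    partition: StoichPartition | None = None,
    closed: bool = True,
    settings: DCASettings | None = None,
    backend: str | LPBackend = "highs",
) -> tuple[list[str], CardinalitySolution]:
    """Minimum-cardinality flux mode leaking (or siphoning) ``met_id``:
    min card(v) s.t. S v = sign*y, y >= 0, y_i >= 1."""
    if kind not in ("leak", "siphon"):
        raise ValueError("kind must be 'leak' or 'siphon'")
    partition = partition or split_internal_external(model)
    lb, ub = _closed_bounds(model, partition) if closed else (model.lb, model.ub)
    sign = 1.0 if kind == "leak" else -1.0
    i = model.met_index(met_id)
    problem = _leak_problem(model, lb, ub, sign)
    problem.min_idx = np.arange(model.n)
    problem.min_weights = np.ones(model.n)
    problem.max_idx = np.array([], dtype=int)
    problem.max_weights = np.array([], dtype=float)
    problem.lb[model.n + i] = 1.0
    sol = solve_cardinality(problem, settings=settings or DCASettings.robust(), backend=backend)
    if sol.status == "infeasible":
        return [], sol
    return [model.rxn_ids[j] for j in sol.support_min], sol
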