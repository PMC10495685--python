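"""Seeded generators of networks with known ground truth.

Every generator works in integer arithmetic: metabolites carry small
integer masses (the first two are pinned to 1 and 2 so any mass total can
be change-made with coefficients bounded by 4), each internal reaction is
built exactly mass-balanced against those masses, and metabolite formulae
are written as C{mass} so elemental balance coincides with mass balance by
construction.  Injected defects come with exact certificates: an extra +1
participant makes a column imbalanced against *every* positive conservation
vector; dead-end metabolites block their reaction for any bounds; balanced
loops admit circulation but never chemical potentials.

These networks emulate the defect classes of real reconstructions
(misspecified stoichiometry, network gaps, thermodynamically infeasible
cycles, over-constrained bounds), not their topology — no attempt is made
at realistic degree distributions or compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dc_solver import CardinalityProblem
from .model_io import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_consistent_network",
    "inject_inconsistency",
    "inject_blocked",
    "inject_internal_cycle",
    "make_infeasible_fba",
    "make_atp_loop_model",
    "random_cardinality_problem",
    "MID_PRESET",
]

_MASSES = (1, 2, 3, 4)


@dataclass
class FixtureSpec:
    m: int = 6
    n_internal: int = 8
    n_external: int | str = "all"  # count, or "all" for one exchange per metabolite
    seed: int = 0
    reversible_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two metabolites (masses 1 and 2 are pinned)")
        if self.n_internal < 0:
            raise ValueError("n_internal must be nonnegative")
        if self.n_internal > 0 and self.m == 0:
            raise ValueError("internal reactions need metabolites")


MID_PRESET = FixtureSpec(m=300, n_internal=500, n_external="all", seed=0)


@dataclass
class GroundTruth:
    masses: np.ndarray
    inconsistent_rxns: set[str] = field(default_factory=set)
    blocked_rxns: set[str] = field(default_factory=set)
    cycle_rxns: set[str] = field(default_factory=set)
    conflict_rxns: set[str] = field(default_factory=set)
    min_relaxation_card: int = 0


def _change_make(total: int, rng: np.random.Generator, masses: np.ndarray,
                 exclude: set[int]) -> list[tuple[int, int]]:
    """Pick metabolites whose masses sum exactly to ``total`` with
    coefficients <= 4, using the pinned mass-1/2 metabolites as filler."""
    picks: list[tuple[int, int]] = []
    remaining = total
    candidates = [i for i in range(len(masses)) if i not in exclude and i > 1]
    rng.shuffle(candidates)
    for i in candidates:
        if remaining <= 2:
            break
        mass = int(masses[i])
        if mass <= remaining - 0 and rng.random() < 0.6:
            coeff = int(min(4, remaining // mass, int(rng.integers(1, 3))))
            if coeff >= 1:
                picks.append((i, coeff))
                remaining -= coeff * mass
        if remaining == 0:
            break
    # filler with the pinned masses 2 and 1
    if remaining > 0:
        twos = min(4, remaining // 2)
        if twos and 1 not in exclude:
            picks.append((1, twos))
            remaining -= 2 * twos
    if remaining > 0:
        if remaining > 4 or 0 in exclude:
            return []  # caller retries with a different draw
        picks.append((0, remaining))
    return picks


def make_consistent_network(spec: FixtureSpec) -> tuple[MetabolicModel, GroundTruth]:
    """A stoichiometrically consistent network with known integer masses.

    Internal reactions consume a random side and produce an exactly
    mass-equal side; exchanges (single -1 columns, ids EX_*) are appended
    for every metabolite by default so the internal core is also flux
    consistent under the generated reversible bounds.
    """
    rng = np.random.default_rng(spec.seed)
    masses = np.empty(spec.m, dtype=int)
    masses[0], masses[1] = 1, 2
    masses[2:] = rng.choice(_MASSES, size=spec.m - 2)
    met_ids = [f"M{i}" for i in range(spec.m)]

    cols: list[dict[int, float]] = []
    while len(cols) < spec.n_internal:
        n_sub = int(rng.integers(1, 3))
        subs = rng.choice(spec.m, size=n_sub, replace=False)
        sub_coeffs = {int(i): int(rng.integers(1, 3)) for i in subs}
        total = sum(masses[i] * k for i, k in sub_coeffs.items())
        prods = _change_make(total, rng, masses, exclude=set(sub_coeffs))
        if not prods:
            continue
        col = {i: -float(k) for i, k in sub_coeffs.items()}
        for i, k in prods:
            col[i] = col.get(i, 0.0) + float(k)
        col = {i: v for i, v in col.items() if v != 0.0}
        if len(col) < 2:
            continue
        cols.append(col)

    if spec.n_external == "all":
        ext_mets = list(range(spec.m))
    else:
        ext_mets = rng.choice(spec.m, size=min(int(spec.n_external), spec.m),
                              replace=False).tolist()
    rxn_ids = [f"R{j}" for j in range(spec.n_internal)]
    rxn_ids += [f"EX_M{i}" for i in ext_mets]
    n = len(rxn_ids)

    rows_, cols_, data = [], [], []
    for j, col in enumerate(cols):
        for i, v in col.items():
            rows_.append(i)
            cols_.append(j)
            data.append(v)
    for k, i in enumerate(ext_mets):
        rows_.append(i)
        cols_.append(spec.n_internal + k)
        data.append(-1.0)
    S = sp.coo_matrix((data, (rows_, cols_)), shape=(spec.m, n)).tocsc()

    lb = np.full(n, -DEFAULT_BOUND)
    ub = np.full(n, DEFAULT_BOUND)
    irrev = rng.random(spec.n_internal) > spec.reversible_fraction
    lb[:spec.n_internal][irrev] = 0.0
    model = MetabolicModel(
        S=S, lb=lb, ub=ub, met_ids=met_ids, rxn_ids=rxn_ids,
        met_formula=[f"C{int(mass)}" for mass in masses])
    return model, GroundTruth(masses=masses)


def inject_inconsistency(
    model: MetabolicModel,
    truth: GroundTruth,
    k: int,
    imbalanced_formulas: bool = True,
    seed: int = 0,
) -> tuple[MetabolicModel, GroundTruth]:
    """Corrupt k internal columns so no positive mass vector balances them.

    Adding a fresh +1 participant to a balanced column makes its mass
    residual strictly positive against *every* positive conservation
    vector, so the defect is certified independently of the construction
    masses.  With ``imbalanced_formulas`` the elemental check fails for
    exactly these columns (the formulae are left truthful; the
    stoichiometry is what is corrupted).
    """
    if k == 0:
        return model, truth
    from .lp import LinearProgram, get_backend

    rng = np.random.default_rng(seed)
    model = model.copy()
    nnz = model.column_nnz()
    internal = [j for j in range(model.n) if nnz[j] > 1
                and not model.rxn_ids[j].startswith("EX_")]
    order = list(internal)
    rng.shuffle(order)
    if len(order) < k:
        raise ValueError(f"cannot corrupt {k} of {len(order)} internal reactions")
    be = get_backend("highs")

    # each corrupted column must be uncertifiable against the core that
    # finally stays uncorrupted, so fix the candidate set first and certify
    # against internal - chosen; swap out any member that cannot be certified
    chosen = order[:k]
    pool = order[k:]
    for attempt in range(len(order)):
        S = model.S.tocsc(copy=True)
        added_mets = []
        core = np.array([c for c in internal if c not in set(chosen)], int)
        failed = None
        for j in chosen:
            present = set(S[:, j].indices.tolist())
            free = [i for i in range(model.m) if i not in present] or list(range(model.m))
            rng.shuffle(free)
            done = False
            for delta in (1.0, 2.0, 3.0):
                for i_new in free:
                    cand = S.tolil()
                    cand[i_new, j] = cand[i_new, j] + delta
                    cand = cand.tocsc()
                    ok, _ = _balance_feasible(cand[:, np.concatenate([core, [j]])], be)
                    if not ok:
                        S = cand
                        added_mets.append(int(i_new))
                        done = True
                        break
                if done:
                    break
            if not done:
                failed = j
                break
        if failed is None:
            break
        if not pool:
            raise RuntimeError(
                "could not certify the requested number of injected "
                "inconsistencies; use a larger or less redundant base network")
        chosen = [pool.pop(0) if j == failed else j for j in chosen]
    model.S = S
    if not imbalanced_formulas and model.met_formula is not None:
        # hide the defect from the elemental check: voiding the added
        # participant's formula degrades the reaction to "undetermined"
        for i in added_mets:
            model.met_formula[i] = None
    return model, GroundTruth(
        masses=truth.masses,
        inconsistent_rxns=truth.inconsistent_rxns | {model.rxn_ids[j] for j in chosen},
        blocked_rxns=set(truth.blocked_rxns),
        cycle_rxns=set(truth.cycle_rxns),
        conflict_rxns=set(truth.conflict_rxns),
        min_relaxation_card=truth.min_relaxation_card)


def _balance_feasible(N: sp.spmatrix, be) -> tuple[bool, np.ndarray | None]:
    from .lp import LinearProgram

    N = sp.csc_matrix(N)
    m = N.shape[0]
    res = be.solve(LinearProgram(c=np.ones(m), A_eq=N.T.tocsr(),
                                 b_eq=np.zeros(N.shape[1]),
                                 lb=np.ones(m), ub=np.full(m, 1e6)))
    return (res.ok, res.x if res.ok else None)


def inject_blocked(
    model: MetabolicModel,
    truth: GroundTruth,
    k: int,
    seed: int = 0,
) -> tuple[MetabolicModel, GroundTruth]:
    """Append k dead-end reactions: each consumes an existing metabolite and
    produces a fresh metabolite with no other reaction and no exchange, so
    steady state forces zero flux regardless of bounds.  Mass-balanced, so
    stoichiometric consistency is untouched."""
    if k == 0:
        return model, truth
    rng = np.random.default_rng(seed)
    model = model.copy()
    m0, n0 = model.m, model.n
    S = sp.lil_matrix((m0 + k, n0 + k))
    S[:m0, :n0] = model.S
    new_rxns, new_mets, new_formula = [], [], []
    for t in range(k):
        src = int(rng.integers(m0))
        S[src, n0 + t] = -1.0
        S[m0 + t, n0 + t] = 1.0
        new_mets.append(f"DEAD{t}")
        new_formula.append(f"C{int(truth.masses[src])}" if src < len(truth.masses) else "C1")
        new_rxns.append(f"RB{t}")
    model2 = MetabolicModel(
        S=S.tocsc(),
        lb=np.concatenate([model.lb, np.full(k, -DEFAULT_BOUND)]),
        ub=np.concatenate([model.ub, np.full(k, DEFAULT_BOUND)]),
        met_ids=model.met_ids + new_mets,
        rxn_ids=model.rxn_ids + new_rxns,
        b=np.concatenate([model.b, np.zeros(k)]),
        c=np.concatenate([model.c, np.zeros(k)]),
        met_formula=(list(model.met_formula) + new_formula
                     if model.met_formula is not None else None))
    masses2 = np.concatenate([truth.masses,
                              [int(f[1:]) for f in new_formula]])
    truth2 = GroundTruth(masses=masses2,
                         inconsistent_rxns=set(truth.inconsistent_rxns),
                         blocked_rxns=truth.blocked_rxns | set(new_rxns),
                         cycle_rxns=set(truth.cycle_rxns),
                         conflict_rxns=set(truth.conflict_rxns),
                         min_relaxation_card=truth.min_relaxation_card)
    return model2, truth2


def inject_internal_cycle(
    model: MetabolicModel,
    truth: GroundTruth,
    cycle_len: int = 3,
    seed: int = 0,
) -> tuple[MetabolicModel, GroundTruth]:
    """Append a stoichiometrically balanced internal loop whose reversible
    bounds admit circulation: M_{i1} -> M_{i2} -> ... -> M_{i1} with
    mass-matched coefficients.  The loop reactions are flux consistent even
    with all exchanges closed, but thermodynamically inconsistent there —
    net flux around a balanced cycle is impossible under any chemical
    potentials."""
    if cycle_len < 2:
        raise ValueError("cycle_len must be >= 2")
    rng = np.random.default_rng(seed)
    model = model.copy()
    # draw loop members from exchanged metabolites only, so the loop never
    # revives a dead-end planted by inject_blocked
    nnz = model.column_nnz()
    exchanged = sorted({int(model.S[:, j].indices[0])
                        for j in range(model.n) if nnz[j] == 1})
    pool = exchanged if len(exchanged) >= cycle_len else list(range(model.m))
    mets = rng.choice(pool, size=cycle_len, replace=False).tolist()
    masses = truth.masses
    S = sp.lil_matrix((model.m, model.n + cycle_len))
    S[:, :model.n] = model.S
    new_rxns = []
    for t in range(cycle_len):
        a, bmet = mets[t], mets[(t + 1) % cycle_len]
        g = np.gcd(int(masses[a]), int(masses[bmet]))
        S[a, model.n + t] = -float(masses[bmet] // g)
        S[bmet, model.n + t] = float(masses[a] // g)
        new_rxns.append(f"LOOP{t}")
    model2 = MetabolicModel(
        S=S.tocsc(),
        lb=np.concatenate([model.lb, np.full(cycle_len, -DEFAULT_BOUND)]),
        ub=np.concatenate([model.ub, np.full(cycle_len, DEFAULT_BOUND)]),
        met_ids=model.met_ids, rxn_ids=model.rxn_ids + new_rxns,
        b=model.b,
        c=np.concatenate([model.c, np.zeros(cycle_len)]),
        met_formula=model.met_formula)
    truth2 = GroundTruth(masses=masses,
                         inconsistent_rxns=set(truth.inconsistent_rxns),
                         blocked_rxns=set(truth.blocked_rxns),
                         cycle_rxns=truth.cycle_rxns | set(new_rxns),
                         conflict_rxns=set(truth.conflict_rxns),
                         min_relaxation_card=truth.min_relaxation_card)
    return model2, truth2


def make_infeasible_fba(
    model: MetabolicModel,
    truth: GroundTruth,
    n_conflicts: int = 1,
    seed: int = 0,
) -> tuple[MetabolicModel, GroundTruth]:
    """Force positive lower bounds on freshly injected dead-end reactions.

    Each conflict is independent and requires exactly one bound relaxation,
    so the minimal relaxation cardinality is ``n_conflicts`` exactly."""
    if n_conflicts == 0:
        return model, truth
    model2, truth2 = inject_blocked(model, truth, n_conflicts, seed=seed)
    conflicts = [f"RB{t}" for t in range(n_conflicts)]
    for rid in conflicts:
        j = model2.rxn_index(rid)
        model2.lb[j] = 1.0
        model2.ub[j] = 2.0
    truth2.conflict_rxns |= set(conflicts)
    truth2.min_relaxation_card = truth.min_relaxation_card + n_conflicts
    return model2, truth2


def make_atp_loop_model(seed: int = 0) -> tuple[MetabolicModel, str, set[str]]:
    """A closed toy energy network: hydrolysis atp + h2o -> adp + pi + h plus
    a deliberate 3-reaction regeneration loop that together admit isolated
    hydrolysis.  Returns (model, hydrolysis id, loop reaction ids)."""
    mets = ["atp", "h2o", "adp", "pi", "h", "x"]
    # x is the lumped "recharged" species: exactly atp + h2o worth of atoms
    formulas = ["C10H12N5O13P3", "H2O", "C10H12N5O10P2", "HO4P", "H", "C10H14N5O14P3"]
    rxns = {
        "ATPM":  {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},    # hydrolysis
        "LOOPA": {"adp": -1, "pi": -1, "h": -1, "x": 1},               # capture
        "LOOPB": {"x": -1, "atp": 1, "h2o": 1},                        # regenerate
    }
    met_index = {m: i for i, m in enumerate(mets)}
    S = sp.lil_matrix((len(mets), len(rxns)))
    for j, (rid, stoich) in enumerate(rxns.items()):
        for mid, v in stoich.items():
            S[met_index[mid], j] = float(v)
    model = MetabolicModel(
        S=S.tocsc(),
        lb=np.full(len(rxns), -DEFAULT_BOUND),
        ub=np.full(len(rxns), DEFAULT_BOUND),
        met_ids=mets, rxn_ids=list(rxns),
        met_formula=formulas)
    return model, "ATPM", {"LOOPA", "LOOPB"}


def random_cardinality_problem(rng: np.random.Generator) -> CardinalityProblem:
    """A sparse stoichiometric-like cardinality-minimization instance with a
    planted sparse solution: 2-4 nonzeros per column, coefficients ±1/±2,
    mixed reversible/irreversible bounds, b = A x0 for a 1-3-sparse x0."""
    n = int(rng.integers(8, 13))
    m = int(rng.integers(4, 8))
    A = np.zeros((m, n))
    for j in range(n):
        k = int(rng.integers(2, min(5, m + 1)))
        rows = rng.choice(m, size=k, replace=False)
        A[rows, j] = rng.choice([-2, -1, 1, 2], size=k)
    x0 = np.zeros(n)
    k = int(rng.integers(1, 4))
    sel = rng.choice(n, size=k, replace=False)
    x0[sel] = rng.uniform(0.5, 2.0, size=k) * rng.choice([-1, 1], size=k)
    b = A @ x0
    lb = np.where(rng.random(n) < 0.5, -3.0, 0.0)
    lb[sel] = np.minimum(lb[sel], np.minimum(x0[sel], 0.0))
    return CardinalityProblem(n=n, A_eq=sp.csr_matrix(A), b_eq=b, lb=lb,
                              ub=np.full(n, 3.0), min_idx=np.arange(n))
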