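"""DCA cardinality solver: toy optima, oracle agreement, descent, backends."""

import numpy as np
import pytest
import scipy.sparse as sp

from cardopt.dc_solver import (CardinalityProblem, DCASettings, UnboundedProblemError,
                               brute_force_min_card, solve_cardinality,
                               verify_support_minimality)
from cardopt.step_approx import StepApprox
from cardopt.synthetic_fixtures import random_cardinality_problem


def toy_unit_sum():
    # min card(x) s.t. x1 + x2 = 1, 0 <= x <= 1  -> one active entry
    return CardinalityProblem(
        n=2, A_eq=sp.csr_matrix(np.array([[1.0, 1.0]])), b_eq=np.array([1.0]),
        lb=np.zeros(2), ub=np.ones(2), min_idx=np.arange(2))


def toy_sum_three():
    # min card(x) s.t. x1+x2+x3 >= 3, 0 <= x <= 2 -> two active entries
    return CardinalityProblem(
        n=3, A_ub=sp.csr_matrix(-np.ones((1, 3))), b_ub=np.array([-3.0]),
        lb=np.zeros(3), ub=np.full(3, 2.0), min_idx=np.arange(3))


def test_min_card_toys_match_brute_force():
    for problem, expected in ((toy_unit_sum(), 1), (toy_sum_three(), 2)):
        sol = solve_cardinality(problem)
        assert sol.status == "optimal-approx"
        assert len(sol.support_min) == expected
        assert brute_force_min_card(problem)[0] == expected


def test_max_card_toy():
    # max card(y) s.t. y1 - y2 = 0, 0 <= y <= 1 -> both active
    problem = CardinalityProblem(
        n=2, A_eq=sp.csr_matrix(np.array([[1.0, -1.0]])), b_eq=np.array([0.0]),
        lb=np.zeros(2), ub=np.ones(2), max_idx=np.arange(2))
    sol = solve_cardinality(problem)
    assert len(sol.support_max) == 2
    np.testing.assert_allclose(sol.x, [1.0, 1.0])


def test_infeasible_reported_with_status():
    problem = CardinalityProblem(
        n=2, A_eq=sp.csr_matrix(np.array([[1.0, 1.0]])), b_eq=np.array([5.0]),
        lb=np.zeros(2), ub=np.ones(2), min_idx=np.arange(2))
    assert solve_cardinality(problem).status == "infeasible"
    assert brute_force_min_card(problem) == (None, None)


def test_unbounded_cost_block_raises():
    problem = CardinalityProblem(n=2, lb=np.array([0.0, -np.inf]),
                                 ub=np.array([1.0, np.inf]),
                                 min_idx=np.array([0]), cost=np.array([0.0, -1.0]))
    with pytest.raises(UnboundedProblemError):
        solve_cardinality(problem)


def test_max_block_requires_capped_family():
    problem = CardinalityProblem(n=2, lb=np.zeros(2), ub=np.ones(2),
                                 max_idx=np.arange(2))
    with pytest.raises(NotImplementedError, match="exp"):
        solve_cardinality(problem, approx=StepApprox("exp", 1.0))


@pytest.mark.parametrize("kind", ["cappedL1", "exp", "scad", "log", "lpPos", "lpNeg"])
def test_all_families_solve_minimization(kind):
    sol = solve_cardinality(toy_sum_three(), approx=StepApprox(kind, 0.5))
    assert sol.status == "optimal-approx"
    assert len(sol.support_min) == 2


def test_oracle_agreement_and_no_undershoot_quick():
    """On random sparse network instances the solver matches the exact
    minimum in most cases and never reports a smaller support."""
    rng = np.random.default_rng(3)
    settings = DCASettings.robust(seed=3)
    agree = 0
    for _ in range(15):
        problem = random_cardinality_problem(rng)
        sol = solve_cardinality(problem, settings=settings)
        exact, _ = brute_force_min_card(problem)
        assert len(sol.support_min) >= exact
        agree += len(sol.support_min) == exact
    assert agree >= 12


def test_solutions_feasible_and_descent_monotone():
    rng = np.random.default_rng(11)
    for _ in range(10):
        problem = random_cardinality_problem(rng)
        sol = solve_cardinality(problem)
        assert problem.residuals(sol.x) <= 1e-6
        assert sol.max_descent_violation <= 1e-9
        assert len(sol.trace) == sol.iterations


def test_support_minimality_judgments():
    problem = toy_sum_three()
    sol = solve_cardinality(problem)
    flags = verify_support_minimality(problem, sol.support_min)
    assert flags and not any(flags.values())  # minimal: nothing removable
    # padded support: the extra member is removable
    padded = np.arange(3)
    flags = verify_support_minimality(problem, padded)
    assert sum(flags.values()) >= 1
    # empty support is vacuously minimal
    assert verify_support_minimality(problem, np.array([], dtype=int)) == {}


def test_forced_nonzero_member_is_not_removable():
    # lb > 0 pins the variable; fixing it to zero is impossible, not a relaxation
    problem = CardinalityProblem(
        n=2, A_eq=sp.csr_matrix(np.array([[1.0, 1.0]])), b_eq=np.array([2.0]),
        lb=np.array([1.0, 0.0]), ub=np.full(2, 2.0), min_idx=np.arange(2))
    flags = verify_support_minimality(problem, np.array([0]))
    assert flags == {0: False}


def test_zero_weight_entries_are_free():
    # with zero weight on x2, the solver may use it freely: support counts x1 only
    problem = CardinalityProblem(
        n=2, A_eq=sp.csr_matrix(np.array([[1.0, 1.0]])), b_eq=np.array([1.0]),
        lb=np.zeros(2), ub=np.ones(2), min_idx=np.arange(2),
        min_weights=np.array([1.0, 0.0]))
    sol = solve_cardinality(problem)
    assert sol.x[1] == pytest.approx(1.0, abs=1e-6)


def test_backends_agree_on_toys():
    for problem, expected in ((toy_unit_sum(), 1), (toy_sum_three(), 2)):
        for backend in ("highs", "glpk"):
            sol = solve_cardinality(problem, backend=backend)
            assert sol.status == "optimal-approx"
            assert len(sol.support_min) == expected


def test_glpk_warm_start_preserves_feasibility():
    """Re-solving with the persistent GLPK model (warm-started basis) yields
    feasible iterates and the same support as a cold highs solve."""
    from cardopt.lp import GlpkBackend

    be = GlpkBackend()
    problem = toy_sum_three()
    s1 = solve_cardinality(problem, backend=be)
    s2 = solve_cardinality(problem, backend=be)  # reuses the built model
    assert problem.residuals(s1.x) <= 1e-6 and problem.residuals(s2.x) <= 1e-6
    assert len(s1.support_min) == len(s2.support_min) == 2


def test_problem_validation():
    with pytest.raises(ValueError):
        CardinalityProblem(n=2, min_idx=np.array([0]), max_idx=np.array([0]))
    with pytest.raises(ValueError):
        CardinalityProblem(n=2, min_idx=np.array([0]), min_weights=np.array([-1.0]))
    with pytest.raises(ValueError):
        CardinalityProblem(n=1, lb=np.array([1.0]), ub=np.array([0.0]))
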