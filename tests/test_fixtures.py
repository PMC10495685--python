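"""Ground-truth soundness and determinism of the synthetic generators."""

import numpy as np
import pytest

from cardopt.model_io import split_internal_external, write_model
from cardopt.stoich_consistency import check_full_consistency, min_conservation_relaxation
from cardopt.flux_thermo import oracle_flux_consistent
from cardopt.synthetic_fixtures import (FixtureSpec, GroundTruth, _balance_feasible,
                                        inject_blocked, inject_inconsistency,
                                        inject_internal_cycle,
                                        make_consistent_network, make_infeasible_fba,
                                        random_cardinality_problem)
from cardopt.lp import get_backend


def test_construction_is_consistent_and_masses_certify():
    model, truth = make_consistent_network(FixtureSpec(m=6, n_internal=8, seed=1))
    part = split_internal_external(model)
    N = model.S[:, part.internal_cols]
    ok, _ = check_full_consistency(N)
    assert ok
    # the construction masses balance N exactly (integer arithmetic)
    np.testing.assert_array_equal(np.asarray((N.T @ truth.masses)).ravel(), 0.0)
    # and the relaxation problem needs no relaxation
    assert len(min_conservation_relaxation(N).support()) == 0


def test_determinism_same_seed_same_bytes(tmp_path):
    spec = FixtureSpec(m=7, n_internal=12, seed=3)
    a, _ = make_consistent_network(spec)
    b, _ = make_consistent_network(spec)
    pa = write_model(a, tmp_path / "a.tsv")
    pb = write_model(b, tmp_path / "b.tsv")
    assert pa.read_bytes() == pb.read_bytes()
    c, _ = make_consistent_network(FixtureSpec(m=7, n_internal=12, seed=4))
    assert (a.S != c.S).nnz > 0


def test_inject_inconsistency_certified_and_flagged():
    model, truth = make_consistent_network(FixtureSpec(m=7, n_internal=16, seed=2))
    model2, truth2 = inject_inconsistency(model, truth, 3, seed=7)
    assert len(truth2.inconsistent_rxns) == 3
    part = split_internal_external(model2)
    internal = [model2.rxn_ids[j] for j in part.internal_cols]
    core = [model2.rxn_index(r) for r in internal if r not in truth2.inconsistent_rxns]
    be = get_backend("highs")
    for rid in truth2.inconsistent_rxns:
        cols = core + [model2.rxn_index(rid)]
        ok, _ = _balance_feasible(model2.S[:, cols], be)
        assert not ok  # each corrupted column is inconsistent with the core
    from cardopt.chem import elemental_imbalance
    balance = elemental_imbalance(model2, part)
    for rid in truth2.inconsistent_rxns:
        assert balance[rid].status == "imbalanced"


def test_inject_inconsistency_noop_and_hidden_formulas():
    model, truth = make_consistent_network(FixtureSpec(m=7, n_internal=16, seed=2))
    same, same_truth = inject_inconsistency(model, truth, 0, seed=7)
    assert (same.S != model.S).nnz == 0
    hidden, truth_h = inject_inconsistency(model, truth, 2, imbalanced_formulas=False, seed=7)
    from cardopt.chem import elemental_imbalance
    balance = elemental_imbalance(hidden, split_internal_external(hidden))
    for rid in truth_h.inconsistent_rxns:
        assert balance[rid].status == "undetermined"


def test_inject_blocked_excludes_exactly_k():
    model, truth = make_consistent_network(FixtureSpec(m=8, n_internal=12, seed=5))
    model2, truth2 = inject_blocked(model, truth, 3, seed=6)
    consistent = oracle_flux_consistent(model2)
    assert set(model2.rxn_ids) - consistent == truth2.blocked_rxns
    assert len(truth2.blocked_rxns) == 3
    # classes are independent: blocked reactions stay stoichiometrically fine
    part = split_internal_external(model2)
    ok, _ = check_full_consistency(model2.S[:, part.internal_cols])
    assert ok
    same, _ = inject_blocked(model, truth, 0, seed=6)
    assert same.n == model.n


def test_inject_cycle_two_member_loop():
    model, truth = make_consistent_network(FixtureSpec(m=6, n_internal=8, seed=8))
    model2, truth2 = inject_internal_cycle(model, truth, 2, seed=1)
    assert len(truth2.cycle_rxns) == 2
    # circulation exists with exchanges closed
    closed = model2.copy()
    part = split_internal_external(closed)
    closed.lb[part.external_cols] = 0.0
    closed.ub[part.external_cols] = 0.0
    assert truth2.cycle_rxns <= oracle_flux_consistent(closed)


def test_make_infeasible_fba_minimal_card_matches():
    from cardopt.fba_variants import fba, relaxed_fba
    base, truth = make_consistent_network(FixtureSpec(m=6, n_internal=8, seed=3))
    model, truth2 = make_infeasible_fba(base, truth, n_conflicts=2, seed=4)
    assert fba(model).status == "infeasible"
    res = relaxed_fba(model)
    assert res.total_cardinality == truth2.min_relaxation_card == 2
    zero, t0 = make_infeasible_fba(base, truth, n_conflicts=0, seed=4)
    assert fba(zero).status == "optimal"


def test_random_cardinality_problem_has_planted_solution():
    rng = np.random.default_rng(17)
    for _ in range(5):
        problem = random_cardinality_problem(rng)
        assert problem.min_idx.size == problem.n
        from cardopt.lp import get_backend
        res = get_backend("highs").solve(problem.feasibility_lp())
        assert res.ok  # the planted flux guarantees feasibility


def test_spec_validation():
    with pytest.raises(ValueError):
        FixtureSpec(m=1, n_internal=4)
    with pytest.raises(ValueError):
        FixtureSpec(m=3, n_internal=-1)
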