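"""Flux consistency and thermodynamic (cycle-free) flux consistency."""

import numpy as np
import pytest
import scipy.sparse as sp

from cardopt.flux_thermo import (find_flux_consistent_subset,
                                 find_thermo_flux_consistent_subset,
                                 oracle_flux_consistent,
                                 sign_pattern_admits_potentials)
from cardopt.model_io import split_internal_external
from cardopt.synthetic_fixtures import (FixtureSpec, inject_blocked,
                                        inject_internal_cycle,
                                        make_consistent_network)
from conftest import build_model


def test_open_conversion_fully_consistent():
    model = build_model({"EX_A": {"A": -1}, "R": {"A": -1, "B": 1}, "EX_B": {"B": -1}})
    res = find_flux_consistent_subset(model)
    assert res.consistent == {"EX_A", "R", "EX_B"}
    assert not res.blocked


def test_dead_end_blocks_its_reaction(chain_model):
    model = build_model({
        "EX_A": {"A": -1}, "R1": {"A": -1, "B": 1}, "EX_B": {"B": -1},
        "RD": {"B": -1, "D": 1},  # D has no outlet
    })
    res = find_flux_consistent_subset(model)
    assert res.blocked == {"RD"}


@pytest.mark.parametrize("seed", range(3))
def test_matches_per_reaction_oracle(seed):
    model, truth = make_consistent_network(FixtureSpec(m=8, n_internal=12, seed=seed))
    model, truth = inject_blocked(model, truth, 2, seed=seed + 50)
    res = find_flux_consistent_subset(model)
    assert res.consistent == oracle_flux_consistent(model)
    assert truth.blocked_rxns <= res.blocked


def test_flux_set_invariant_under_column_rescaling():
    model, _ = make_consistent_network(FixtureSpec(m=6, n_internal=10, seed=4))
    base = find_flux_consistent_subset(model).consistent
    scaled = model.copy()
    scaled.S = scaled.S.tolil()
    scaled.S[:, 0] = 3.0 * model.S[:, 0]
    scaled.S = scaled.S.tocsc()
    scaled.lb[0] = model.lb[0] / 3.0
    scaled.ub[0] = model.ub[0] / 3.0
    assert find_flux_consistent_subset(scaled).consistent == base


def test_flux_set_monotone_in_bounds():
    model, truth = make_consistent_network(FixtureSpec(m=8, n_internal=12, seed=7))
    model, _ = inject_blocked(model, truth, 1, seed=70)
    tight = model.copy()
    rng = np.random.default_rng(1)
    shrink = rng.uniform(0.0, 1.0, model.n)
    tight.lb = model.lb * shrink
    tight.ub = model.ub * shrink
    small = find_flux_consistent_subset(tight).consistent
    assert small <= find_flux_consistent_subset(model).consistent


# -- chemical potentials and cycles -----------------------------------------

def test_chain_sign_pattern_admits_potentials():
    N = sp.csc_matrix(np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]]))
    feasible, y, cycle = sign_pattern_admits_potentials(N, np.array([1, 1]))
    assert feasible and cycle is None
    assert (N[:, 0].T @ y)[0] <= -1 and (N[:, 1].T @ y)[0] <= -1


def test_cycle_sign_pattern_is_infeasible_with_certificate():
    N = sp.csc_matrix(np.array([[-1.0, 0.0, 1.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]))
    feasible, y, cycle = sign_pattern_admits_potentials(N, np.array([1, 1, 1]))
    assert not feasible and y is None
    assert np.abs(N @ cycle).max() < 1e-9
    assert np.all(cycle >= -1e-12) and cycle.max() > 0


def test_all_zero_pattern_trivially_feasible():
    N = sp.csc_matrix(np.array([[-1.0], [1.0]]))
    feasible, y, _ = sign_pattern_admits_potentials(N, np.array([0]))
    assert feasible and np.allclose(y, 0)


def test_theorem_of_the_alternative_random_patterns():
    """The potential LP and the cycle LP are never both feasible nor both
    infeasible, and each returns a verifiable witness."""
    rng = np.random.default_rng(99)
    for _ in range(30):
        m, n = int(rng.integers(3, 8)), int(rng.integers(3, 12))
        N = np.zeros((m, n))
        for j in range(n):
            k = int(rng.integers(2, min(4, m) + 1))
            N[rng.choice(m, k, replace=False), j] = rng.choice([-2, -1, 1, 2], k)
        sigma = rng.choice([-1, 0, 1], size=n)
        feasible, y, cycle = sign_pattern_admits_potentials(sp.csc_matrix(N), sigma)
        active = sigma != 0
        if feasible:
            assert np.all(sigma[active] * (N[:, active].T @ y) <= -1 + 1e-7)
        else:
            assert np.abs(N @ cycle).max() < 1e-7
            assert np.all(sigma[active] * cycle[active] >= -1e-9)
            assert np.abs(cycle).max() > 1e-9


# -- thermodynamic flux consistency -----------------------------------------

def test_chain_with_open_ends_thermo_equals_flux(chain_model):
    flux = find_flux_consistent_subset(chain_model)
    thermo = find_thermo_flux_consistent_subset(chain_model, flux_result=flux)
    assert thermo.consistent == flux.consistent
    assert not thermo.inconsistent


def test_closed_cycle_flux_consistent_but_thermo_inconsistent(three_cycle_closed):
    flux = find_flux_consistent_subset(three_cycle_closed)
    assert flux.consistent == {"R1", "R2", "R3"}  # circulation is admissible
    thermo = find_thermo_flux_consistent_subset(three_cycle_closed, flux_result=flux)
    assert thermo.inconsistent == {"R1", "R2", "R3"}
    assert not thermo.consistent


@pytest.mark.parametrize("seed", range(3))
def test_thermo_subset_of_flux_and_witnesses_verify(seed):
    model, truth = make_consistent_network(FixtureSpec(m=8, n_internal=12, seed=seed))
    model, truth = inject_internal_cycle(model, truth, 3, seed=seed + 5)
    part = split_internal_external(model)
    flux = find_flux_consistent_subset(model)
    thermo = find_thermo_flux_consistent_subset(model, part, flux_result=flux, seed=seed)
    assert thermo.consistent <= flux.consistent
    N = model.S[:, part.internal_cols]
    B = model.S[:, part.external_cols]
    for wit in thermo.witnesses:
        residual = N @ wit.z + (B @ wit.w if wit.w.size else 0.0)
        assert np.abs(residual).max() < 1e-6
        active = wit.sigma != 0
        if active.any():
            assert np.all(wit.sigma[active] * (N[:, active].T @ wit.y) <= -1 + 1e-6)


def test_injected_cycle_thermo_inconsistent_when_closed():
    model, truth = make_consistent_network(FixtureSpec(m=8, n_internal=12, seed=11))
    model, truth = inject_internal_cycle(model, truth, 3, seed=42)
    closed = model.copy()
    part = split_internal_external(closed)
    closed.lb[part.external_cols] = 0.0
    closed.ub[part.external_cols] = 0.0
    thermo = find_thermo_flux_consistent_subset(closed, part, seed=1)
    assert truth.cycle_rxns <= thermo.inconsistent
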