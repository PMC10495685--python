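import numpy as np
import pytest
import scipy.sparse as sp

from cardopt.model_io import MetabolicModel


def build_model(reactions, met_ids=None, lb=None, ub=None, formulas=None,
                charges=None, c=None, b=None):
    """Construct a MetabolicModel from {rxn_id: {met_id: coeff}} dicts.

    Metabolite order follows first appearance unless ``met_ids`` is given;
    bounds default to the reversible ±1000 convention.
    """
    if met_ids is None:
        met_ids = []
        for stoich in reactions.values():
            for mid in stoich:
                if mid not in met_ids:
                    met_ids.append(mid)
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rxn_ids = list(reactions)
    S = sp.lil_matrix((len(met_ids), len(rxn_ids)))
    for j, stoich in enumerate(reactions.values()):
        for mid, coeff in stoich.items():
            S[met_index[mid], j] = float(coeff)
    n = len(rxn_ids)
    return MetabolicModel(
        S=S.tocsc(),
        lb=np.full(n, -1000.0) if lb is None else np.asarray(lb, float),
        ub=np.full(n, 1000.0) if ub is None else np.asarray(ub, float),
        met_ids=met_ids, rxn_ids=rxn_ids, c=c, b=b,
        met_formula=[formulas.get(mid) for mid in met_ids] if formulas else None,
        met_charge=[charges.get(mid) for mid in met_ids] if charges else None)


@pytest.fixture
def chain_model():
    """A -> B -> C with exchanges for A and C (open ends)."""
    return build_model({
        "EX_A": {"A": -1},
        "R1": {"A": -1, "B": 1},
        "R2": {"B": -1, "C": 1},
        "EX_C": {"C": -1},
    })


@pytest.fixture
def three_cycle_closed():
    """A -> B -> C -> A, no exchanges: pure balanced circulation."""
    return build_model({
        "R1": {"A": -1, "B": 1},
        "R2": {"B": -1, "C": 1},
        "R3": {"C": -1, "A": 1},
    })
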