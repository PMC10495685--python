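"""Chemical-formula parsing and per-reaction elemental balance checking.

An internal reaction that creates or destroys atoms is misspecified; the
apparent elemental imbalance, computed from the metabolite formulae a
reconstruction provides, is the default criterion for omitting reactions
during sequential stoichiometric-consistency testing.  Metabolites whose
formulae contain generic-residue pseudo-elements (R groups, X, FULLR, *)
are incompletely specified: reactions involving them are *undetermined*,
never silently counted as balanced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model_io import MetabolicModel, StoichPartition

__all__ = [
    "FormulaError",
    "ParsedFormula",
    "ReactionBalance",
    "parse_formula",
    "elemental_imbalance",
    "charge_imbalance",
]

# all IUPAC element symbols (1..118)
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)
# generic residue / unspecified-moiety markers used in metabolic reconstructions
PSEUDO_ELEMENTS = frozenset({"R", "X"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    def __init__(self, formula: str, position: int, message: str) -> None:
        super().__init__(f"cannot parse formula {formula!r} at position {position}: {message}")
        self.formula = formula
        self.position = position


@dataclass(frozen=True)
class ParsedFormula:
    counts: dict[str, int]
    has_pseudo: bool


def parse_formula(formula: str) -> ParsedFormula:
    """Parse a Hill-notation-like formula into element counts.

    Multi-letter symbols and multi-digit counts are handled; R/X/FULLR/*
    mark generic residues and set ``has_pseudo`` (their counts are kept
    under their own symbol but such metabolites are never treated as fully
    specified).  Unknown tokens raise :class:`FormulaError` with the
    offending position.
    """
    if not isinstance(formula, str) or formula == "":
        raise FormulaError(str(formula), 0, "empty formula")
    has_pseudo = False
    text = formula
    if "*" in text:
        has_pseudo = True
        text = text.replace("*", "")
    # FULLR{n} tokens (generic acyl residues) would otherwise shatter into F+U+...
    if "FULL" in text:
        has_pseudo = True
        text = re.sub(r"FULLR\d*|FULL", "", text)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.group(1) == "":
            raise FormulaError(formula, pos, f"unexpected character {text[pos]!r}")
        symbol, digits = match.groups()
        if symbol not in ELEMENTS and symbol not in PSEUDO_ELEMENTS:
            # a two-letter guess like 'Rx' may hide a valid one-letter symbol
            if symbol[0] in ELEMENTS or symbol[0] in PSEUDO_ELEMENTS:
                symbol, digits = symbol[0], ""
            else:
                raise FormulaError(formula, pos, f"unknown element symbol {symbol!r}")
        if symbol in PSEUDO_ELEMENTS:
            has_pseudo = True
        count = int(digits) if digits else 1
        if count < 0:
            raise FormulaError(formula, pos, "negative count")
        counts[symbol] = counts.get(symbol, 0) + count
        pos += len(symbol) + len(digits)
    return ParsedFormula(counts=counts, has_pseudo=has_pseudo)


Status = Literal["balanced", "imbalanced", "undetermined"]


@dataclass
class ReactionBalance:
    rxn_id: str
    status: Status
    imbalance: dict[str, float]  # element -> net atoms produced per unit flux

    @property
    def is_balanced(self) -> bool:
        return self.status == "balanced"


def elemental_imbalance(
    model: MetabolicModel,
    partition: StoichPartition,
    tol: float = 1e-6,
    ignore_protons: bool = False,
) -> dict[str, ReactionBalance]:
    """Per-internal-reaction elemental imbalance.

    imbalance_e(j) = sum_i S_ij * count_e(i).  A reaction is balanced iff
    every element nets to zero and no participant has a missing formula or
    a pseudo-element; missing information degrades to ``undetermined``,
    never to ``balanced``.  With ``ignore_protons`` a pure hydrogen
    imbalance (proton bookkeeping) is not counted against a reaction.
    """
    parsed: list[ParsedFormula | None] = []
    for i in range(model.m):
        raw = model.met_formula[i] if model.met_formula is not None else None
        if raw is None:
            parsed.append(None)
        else:
            try:
                parsed.append(parse_formula(raw))
            except FormulaError:
                parsed.append(None)
    S = model.S.tocsc()
    out: dict[str, ReactionBalance] = {}
    for j in partition.internal_cols:
        sl = slice(S.indptr[j], S.indptr[j + 1])
        rows, coeffs = S.indices[sl], S.data[sl]
        undetermined = False
        net: dict[str, float] = {}
        for i, coeff in zip(rows, coeffs):
            pf = parsed[i]
            if pf is None or pf.has_pseudo:
                undetermined = True
                break
            for element, count in pf.counts.items():
                net[element] = net.get(element, 0.0) + coeff * count
        rid = model.rxn_ids[j]
        if undetermined:
            out[rid] = ReactionBalance(rid, "undetermined", {})
            continue
        residual = {e: v for e, v in net.items() if abs(v) > tol}
        if ignore_protons:
            residual.pop("H", None)
        status: Status = "balanced" if not residual else "imbalanced"
        out[rid] = ReactionBalance(rid, status, residual)
    return out


def charge_imbalance(
    model: MetabolicModel,
    partition: StoichPartition,
    tol: float = 1e-6,
) -> dict[str, float | None]:
    """Net charge produced per unit flux for each internal reaction.

    Reported separately from the elemental check and never used as an
    omission criterion; None where any participant lacks a charge.
    """
    if model.met_charge is None:
        return {model.rxn_ids[j]: None for j in partition.internal_cols}
    S = model.S.tocsc()
    out: dict[str, float | None] = {}
    for j in partition.internal_cols:
        sl = slice(S.indptr[j], S.indptr[j + 1])
        rows, coeffs = S.indices[sl], S.data[sl]
        charges = [model.met_charge[i] for i in rows]
        if any(ch is None for ch in charges):
            out[model.rxn_ids[j]] = None
            continue
        net = float(np.dot(coeffs, charges))
        out[model.rxn_ids[j]] = 0.0 if abs(net) <= tol else net
    return out
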