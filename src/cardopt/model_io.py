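"""Model input/output and the canonical in-memory metabolic model.

A :class:`MetabolicModel` is the stoichiometric matrix S (m metabolites x
n reactions) together with flux bounds l, u, a steady-state right-hand side
b (all-zero for ordinary mass balance), a linear objective c, identifier
lists and optional metabolite formulae/charges.

Readers/writers cover SBML Level 3 + FBC and the cobrapy JSON dialect
(both through cobra.io) plus a plain TSV-triplet format for small models:
``model.tsv`` holds (met_id, rxn_id, coefficient) rows, with sidecar files
``<stem>.bounds.tsv`` (rxn_id, lb, ub, objective) and optionally
``<stem>.mets.tsv`` (met_id, formula, charge).

The internal/external split is heuristic, in the COBRA community
convention: a column with a single nonzero coefficient represents net mass
exchange across the system boundary, as does any reaction whose identifier
carries a conventional exchange/demand/sink/biomass prefix.  Heuristic
assignment tends to underestimate the true number of external reactions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DEFAULT_BOUND",
    "DEFAULT_EXTERNAL_PREFIXES",
    "MetabolicModel",
    "StoichPartition",
    "read_model",
    "write_model",
    "split_internal_external",
    "write_report",
]

DEFAULT_BOUND = 1000.0
DEFAULT_EXTERNAL_PREFIXES = ("EX_", "DM_", "sink_", "SK_", "biomass")


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicModel:
    """Stoichiometric model: S v = b with l <= v <= u and objective c."""

    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    met_ids: list[str]
    rxn_ids: list[str]
    b: np.ndarray | None = None
    c: np.ndarray | None = None
    met_formula: list[str | None] | None = None
    met_charge: list[int | None] | None = None

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        m, n = self.S.shape
        self.lb = np.asarray(self.lb, float)
        self.ub = np.asarray(self.ub, float)
        self.b = np.zeros(m) if self.b is None else np.asarray(self.b, float)
        self.c = np.zeros(n) if self.c is None else np.asarray(self.c, float)
        if not (len(self.lb) == len(self.ub) == len(self.c) == n):
            raise ModelValidationError(
                f"bound/objective dimensions must equal n={n} "
                f"(got lb={len(self.lb)}, ub={len(self.ub)}, c={len(self.c)})")
        if len(self.b) != m:
            raise ModelValidationError(f"b has length {len(self.b)}, expected m={m}")
        if len(self.met_ids) != m or len(self.rxn_ids) != n:
            raise ModelValidationError("identifier list lengths do not match S")
        for name, ids in (("metabolite", self.met_ids), ("reaction", self.rxn_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({i for i in ids if ids.count(i) > 1})
                raise ModelValidationError(f"duplicate {name} ids: {dups[:5]}")
        if np.any(self.lb > self.ub):
            bad = self.rxn_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelValidationError(f"lb > ub on reaction {bad!r}")
        if self.met_formula is not None and len(self.met_formula) != m:
            raise ModelValidationError("met_formula length does not match m")
        if self.met_charge is not None and len(self.met_charge) != m:
            raise ModelValidationError("met_charge length does not match m")

    # -- convenience ---------------------------------------------------------

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self.rxn_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"no reaction with id {rxn_id!r}") from None

    def met_index(self, met_id: str) -> int:
        try:
            return self.met_ids.index(met_id)
        except ValueError:
            raise KeyError(f"no metabolite with id {met_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            S=self.S.copy(), lb=self.lb.copy(), ub=self.ub.copy(),
            met_ids=list(self.met_ids), rxn_ids=list(self.rxn_ids),
            b=self.b.copy(), c=self.c.copy(),
            met_formula=None if self.met_formula is None else list(self.met_formula),
            met_charge=None if self.met_charge is None else list(self.met_charge))

    def column_nnz(self) -> np.ndarray:
        return np.diff(self.S.indptr)


@dataclass
class StoichPartition:
    """Heuristic internal (columns of N) / external (columns of B) split."""

    internal_cols: np.ndarray
    external_cols: np.ndarray

    def __post_init__(self) -> None:
        self.internal_cols = np.asarray(self.internal_cols, int)
        self.external_cols = np.asarray(self.external_cols, int)
        if np.intersect1d(self.internal_cols, self.external_cols).size:
            raise ModelValidationError("internal and external column sets overlap")


def split_internal_external(
    model: MetabolicModel,
    prefixes: tuple[str, ...] = DEFAULT_EXTERNAL_PREFIXES,
) -> StoichPartition:
    """A column is external iff it has exactly one nonzero stoichiometric
    coefficient or its id matches a conventional boundary prefix.

    All-zero columns cannot move mass at all; they are flagged external with
    a warning.  The split depends only on column contents and ids, never on
    column order.
    """
    nnz = model.column_nnz()
    external = np.zeros(model.n, dtype=bool)
    for j, rid in enumerate(model.rxn_ids):
        if nnz[j] == 0:
            warnings.warn(f"reaction {rid!r} has an all-zero column; treated as external")
            external[j] = True
        elif nnz[j] == 1 or any(rid.startswith(p) for p in prefixes):
            external[j] = True
    return StoichPartition(internal_cols=np.flatnonzero(~external),
                           external_cols=np.flatnonzero(external))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml-fbc"
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv-triplet"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML+FBC, cobrapy JSON or a TSV triplet file.

    Missing bounds default to ±1000; a missing steady-state rhs defaults
    to zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml-fbc":
        import cobra.io
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _from_cobra(cobra.io.read_sbml_model(str(path)))
    if fmt == "json":
        import cobra.io
        return _from_cobra(cobra.io.load_json_model(str(path)))
    if fmt == "tsv-triplet":
        return _read_tsv(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml-fbc":
        import cobra.io
        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    elif fmt == "json":
        import cobra.io
        cobra.io.save_json_model(_to_cobra(model), str(path))
    elif fmt == "tsv-triplet":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


def _compartment_of(met_id: str) -> str:
    if met_id.endswith("]") and "[" in met_id:
        return met_id.rsplit("[", 1)[1][:-1]
    if len(met_id) > 2 and met_id[-2] == "_" and met_id[-1].isalpha():
        return met_id[-1]
    return "c"


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("cardopt_model")
    mets = []
    for i, mid in enumerate(model.met_ids):
        met = cobra.Metabolite(mid, compartment=_compartment_of(mid))
        if model.met_formula is not None and model.met_formula[i]:
            met.formula = model.met_formula[i]
        if model.met_charge is not None and model.met_charge[i] is not None:
            met.charge = int(model.met_charge[i])
        mets.append(met)
    cm.add_metabolites(mets)
    S = sp.csc_matrix(model.S)
    rxns = []
    for j, rid in enumerate(model.rxn_ids):
        rxn = cobra.Reaction(rid, lower_bound=float(model.lb[j]), upper_bound=float(model.ub[j]))
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for j, rxn in enumerate(rxns):
        sl = slice(S.indptr[j], S.indptr[j + 1])
        rxn.add_metabolites({mets[i]: float(v) for i, v in zip(S.indices[sl], S.data[sl])})
    objective = {rxns[j]: float(model.c[j]) for j in np.flatnonzero(model.c)}
    if objective:
        cm.objective = cm.problem.Objective(0, direction="max")
        cm.objective.set_linear_coefficients(
            {rxn.forward_variable: coef for rxn, coef in objective.items()})
        # cobra encodes the objective on reaction coefficients for serialization
        for rxn, coef in objective.items():
            rxn.objective_coefficient = coef
    return cm


def _from_cobra(cm) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = sp.csc_matrix(create_stoichiometric_matrix(cm, array_type="lil"))
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    lb = np.array([r.lower_bound if r.lower_bound is not None else -DEFAULT_BOUND
                   for r in cm.reactions], float)
    ub = np.array([r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
                   for r in cm.reactions], float)
    lb = np.where(np.isinf(lb), np.sign(lb) * DEFAULT_BOUND, lb)
    ub = np.where(np.isinf(ub), np.sign(ub) * DEFAULT_BOUND, ub)
    c = np.array([r.objective_coefficient for r in cm.reactions], float)
    formulas = [m.formula if m.formula else None for m in cm.metabolites]
    charges = [int(m.charge) if m.charge is not None else None for m in cm.metabolites]
    if all(f is None for f in formulas):
        formulas = None
    if all(ch is None for ch in charges):
        charges = None
    return MetabolicModel(S=S, lb=lb, ub=ub, met_ids=met_ids, rxn_ids=rxn_ids,
                          c=c, met_formula=formulas, met_charge=charges)


def _sidecar(path: Path, tag: str) -> Path:
    return path.with_name(path.stem + f".{tag}.tsv")


def _read_tsv(path: Path) -> MetabolicModel:
    try:
        trip = pd.read_csv(path, sep="\t", dtype={"met_id": str, "rxn_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed TSV triplet file {path.name}: {exc}") from exc
    for col in ("met_id", "rxn_id", "coefficient"):
        if col not in trip.columns:
            raise ValueError(f"TSV triplet file {path.name} lacks column {col!r}")
    met_ids = list(dict.fromkeys(trip["met_id"]))
    rxn_ids = list(dict.fromkeys(trip["rxn_id"]))
    mi = {m: i for i, m in enumerate(met_ids)}
    ri = {r: j for j, r in enumerate(rxn_ids)}
    S = sp.coo_matrix(
        (trip["coefficient"].to_numpy(float),
         (trip["met_id"].map(mi).to_numpy(), trip["rxn_id"].map(ri).to_numpy())),
        shape=(len(met_ids), len(rxn_ids))).tocsc()
    if S.nnz != len(trip):
        raise ValueError(f"duplicate (met_id, rxn_id) entries in {path.name}")

    lb = np.full(len(rxn_ids), -DEFAULT_BOUND)
    ub = np.full(len(rxn_ids), DEFAULT_BOUND)
    c = np.zeros(len(rxn_ids))
    bounds_path = _sidecar(path, "bounds")
    if bounds_path.exists():
        bounds = pd.read_csv(bounds_path, sep="\t", dtype={"rxn_id": str})
        for _, row in bounds.iterrows():
            if row["rxn_id"] not in ri:
                raise ValueError(f"bounds for unknown reaction {row['rxn_id']!r}")
            j = ri[row["rxn_id"]]
            lb[j], ub[j] = float(row["lb"]), float(row["ub"])
            if "objective" in bounds.columns:
                c[j] = float(row["objective"])
    formulas = charges = None
    b = np.zeros(len(met_ids))
    mets_path = _sidecar(path, "mets")
    if mets_path.exists():
        mets = pd.read_csv(mets_path, sep="\t", dtype={"met_id": str})
        formulas = [None] * len(met_ids)
        charges = [None] * len(met_ids)
        for _, row in mets.iterrows():
            if row["met_id"] not in mi:
                raise ValueError(f"metadata for unknown metabolite {row['met_id']!r}")
            i = mi[row["met_id"]]
            if "formula" in mets.columns and isinstance(row["formula"], str):
                formulas[i] = row["formula"]
            if "charge" in mets.columns and pd.notna(row.get("charge")):
                charges[i] = int(row["charge"])
            if "b" in mets.columns and pd.notna(row.get("b")):
                b[i] = float(row["b"])
    return MetabolicModel(S=S, lb=lb, ub=ub, met_ids=met_ids, rxn_ids=rxn_ids,
                          b=b, c=c, met_formula=formulas, met_charge=charges)


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    S = sp.coo_matrix(model.S)
    order = np.lexsort((S.row, S.col))
    pd.DataFrame({
        "met_id": [model.met_ids[i] for i in S.row[order]],
        "rxn_id": [model.rxn_ids[j] for j in S.col[order]],
        "coefficient": [repr(float(v)) for v in S.data[order]],
    }).to_csv(path, sep="\t", index=False)
    pd.DataFrame({
        "rxn_id": model.rxn_ids,
        "lb": [repr(float(v)) for v in model.lb],
        "ub": [repr(float(v)) for v in model.ub],
        "objective": [repr(float(v)) for v in model.c],
    }).to_csv(_sidecar(path, "bounds"), sep="\t", index=False)
    if model.met_formula is not None or model.met_charge is not None or np.any(model.b):
        pd.DataFrame({
            "met_id": model.met_ids,
            "formula": ["" if f is None else f for f in (model.met_formula or [None] * model.m)],
            "charge": ["" if ch is None else ch for ch in (model.met_charge or [None] * model.m)],
            "b": [repr(float(v)) for v in model.b],
        }).to_csv(_sidecar(path, "mets"), sep="\t", index=False)


def write_report(obj, path: str | Path, format: str | None = None) -> Path:
    """Write a partition/solution report as JSON or TSV.

    ``obj`` may be a dict, a list of record dicts, or any object exposing
    ``to_records()`` (list of per-item dicts) or ``to_dict()``.
    """
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() == ".tsv" else "json")
    if hasattr(obj, "to_records"):
        payload = obj.to_records()
    elif hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    else:
        payload = obj
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    elif fmt == "tsv":
        if isinstance(payload, dict):
            payload = [{"key": k, "value": v} for k, v in payload.items()]
        pd.DataFrame(payload).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
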