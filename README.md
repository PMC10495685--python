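# cardopt

Cardinality-optimization quality control for genome-scale metabolic models.

## The problem

Genome-scale metabolic reconstructions are assembled from heterogeneous
evidence, and misspecifications slip in: reactions whose stoichiometry
silently creates or destroys mass, reactions that can never carry flux
because of network gaps, stoichiometrically balanced internal cycles that
let a model synthesize ATP from nothing, and over-constrained bounds that
make flux balance analysis (FBA) infeasible.  Before a reconstruction can
be used as a predictive model, these defects must be found — and each of
these audits is, mathematically, a *cardinality optimization* problem:
minimize or maximize the number of nonzeros of a vector over a polyhedron,

```
min / max  card(x)   s.t.   A x {=, <=} b,   l <= x <= u,
```

an NP-hard problem in general.  `cardopt` solves such problems
approximately but scalably by replacing each step function `step(t) = [t != 0]`
with a continuous surrogate `psi(t)` (capped-L1 `psi(t) = min{1, theta|t|}`
by default), writing the surrogate objective as a difference of two convex
functions `zeta(s) = phi1(s) - phi2(s)`, and running the DC algorithm
(DCA): linearize `phi2` at the incumbent and solve the resulting LP, a
couple of times.  Supports are read off at the solver feasibility tolerance
(1e-6), verified against exact LP certificates wherever one exists, and on
small instances checked against a brute-force enumeration oracle.

Built on top of this core are the six audits a modeller actually runs:

| audit | formulation |
|---|---|
| stoichiometric consistency | `min card(x) s.t. N^T w + x = 0, w >= 1`, plus a sequential loop omitting elementally imbalanced (or maximally lumped) relaxed reactions |
| leak / siphon testing | `max card(y) s.t. S v = ±y, y >= 0, l <= v <= u` with per-metabolite LP confirmation |
| flux consistency | `max card(v) s.t. S v = b, l <= v <= u`, amalgamated and settled exactly against the 2n-LP oracle |
| thermodynamic flux consistency | cardinality maximization + cycle-free (weighted 1-norm) projection + chemical-potential LP certificate `sign(z_j)·N_j^T y <= -1`; reported as an underestimate |
| sparse FBA | `min card(v) s.t. S v = b, l <= v <= u, c^T v >= rho*` where `rho*` is the FBA optimum |
| relaxed FBA | `min lam·card(r) + alpha·card(p) + alpha·card(q) s.t. S v + r = b, l - p <= v <= u + q, p,q,r >= 0` |

Intended users: COBRA-style modellers curating human or microbial
reconstructions, and method developers who need a tested, certificated
reference implementation of DC cardinality optimization over polyhedra.

## Worked example

Generate a small network with known ground truth — two reactions corrupted
so that no positive molecular-mass vector can balance them, one dead-end
reaction — and audit it:

```bash
$ cardopt make-fixture --preset tiny --defects stoich=2,blocked=1 --seed 11 -o demo.json
wrote demo.json and demo.json.truth.json
$ cardopt full-audit demo.json
{
  "model": "demo.json",
  "reactions": 21,
  "internal_reactions": 15,
  "stoich_consistent_rxns": 13,
  "elementally_balanced_rxns": 13,
  "omitted_rxns": 2,
  "stoich_and_flux_consistent_rxns": 12,
  "stoich_not_flux_consistent_rxns": 1,
  ...
  "leak_mets": 7,
  "siphon_mets": 7,
  "fba_ready": false
}
$ echo $?
1
```

Reading the report: of 15 heuristically internal reactions, 13 are
stoichiometrically consistent — the 2 omitted ones are exactly the
injected corruptions, caught because they required a mass-conservation
relaxation *and* were apparently elementally imbalanced given the
metabolite formulae.  Of the 13 consistent reactions, 12 also admit a
nonzero steady-state flux; the missing one is the injected dead end.  The
corrupted stoichiometry makes every metabolite leakable/siphonable through
the reversible corrupted reactions, which is why repairing such defects
matters before trusting any FBA prediction.  The nonzero exit code says
the model is not FBA-ready (that requires all internal reactions
stoichiometrically and flux consistent and all external reactions flux
consistent).

The same pipeline is exposed as a library:

```python
from cardopt import read_model, find_stoich_consistent_subset, sparse_fba

model = read_model("demo.json")
partition = find_stoich_consistent_subset(model, criterion="elemental")
print(sorted(partition.reactions("omitted_unknown")))   # ['R12', 'R2']
```

`cardopt full-audit` runs on any SBML/JSON genome-scale model (e.g. the
published human reconstructions) and emits the same count table.

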