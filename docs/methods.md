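# Methods

## The core: cardinality optimization as a difference of convex functions

Every audit in this package reduces to minimizing or maximizing the number
of nonzero entries of some vector block over a polyhedron.  The zero norm
`card(t) = sum_j step(t_j)` is discontinuous at the origin, so each step
function is replaced by a continuous surrogate `psi` from one of six
families, all parameterized by a sharpness `theta > 0` and normalized so
that `psi(0) = 0`, `0 <= psi <= 1`, `psi` is even and nondecreasing in
`|t|`, and `psi -> step` pointwise as `theta -> inf`:

| family | `psi(u)`, `u = |t|` | notes |
|---|---|---|
| cappedL1 | `min{1, theta·u}` | default; both DC pieces piecewise linear |
| exp | `1 - exp(-theta·u)` | |
| log | `min{1, log(1+theta·u)/log 2}` | saturates at `u = 1/theta` |
| scad | normalized SCAD, knot `1/theta`, shoulder `a = 3.7` | |
| lpPos | `min{1, (theta·u)^p}`, `0 < p < 1` (default 0.5) | inner segment linearized below `psi = 0.01` so the majorant slope stays finite — `u^p` has unbounded derivative at 0 and otherwise admits no `s0·|t|` majorant |
| lpNeg | `1 - (1+theta·u)^p`, `p < 0` (default -1) | |

Each family is concave in `u`, which yields one uniform difference-of-convex
split with `s0 = psi'(0+)`:

```
minimize:  sum psi(t)     = [ s0·sum|t| ] - [ s0·sum|t| - sum psi(t) ]
maximize:  sum (1-psi(t)) = [ s0·sum|t| - sum psi(t) ] - [ s0·sum|t| ]  (+ const)
```

Both bracketed components are convex; the subgradient of the subtracted
component is `sign(t)·(s0 - psi'(|t|))` (minimize) or `s0·sign(t)`
(maximize), zero at the origin by symmetry.

**DCA iteration.**  Each outer iteration linearizes the subtracted
component at the incumbent and minimizes the convex remainder over the
polyhedron.  In minimization mode the remainder is linear for *all six*
families (absolute values enter through epigraph auxiliaries `a_j >= ±t_j`),
so every subproblem is an LP.  In maximization mode only capped-L1 keeps an
LP-representable convex part (`max(theta·a - 1, 0)` epigraph); the other
families are available as function/subgradient oracles but not on the LP
path.  Epigraph auxiliaries were chosen over nonnegative variable splitting
because the epigraph cost always *rises* when the auxiliary exceeds `|t|`,
so no mode can game the surrogate by inflating the absolute-value encoding.

**Initialization.**  The incumbent starts at the origin, where the
minimize-mode subgradient vanishes — the first LP is therefore exactly the
weighted one-norm relaxation, tying iterate 1 to the standard convex
baseline.  Maximize-mode entries take the subgradient at the
bound-preferred sign (`+s0` if the upper bound is positive, else `-s0`), a
valid element of the subdifferential at 0, so cardinality maximization has
a nonzero first-iteration drive.

**Schedule and stopping.**  `theta` starts at 0.5 and is multiplied by 1.5
per outer iteration (capped at 1e3).  The loop stops when the support sets
(read at `eps_supp = 1e-6`, the LP feasibility tolerance) are unchanged
*and* the surrogate objective moved by less than `tol = 1e-6` within one
iteration, or at `max_outer = 50`.  Because `psi_theta` changes between
iterations, the recorded descent certificate is the pair
`(zeta_theta_k(s_{k-1}), zeta_theta_k(s_k))` under a common `theta` — the
actual DCA guarantee — and the package asserts `post <= pre + 1e-9` on
every solve.  In practice two to three LPs suffice, including at the
~300x800 scale used in the tests.

**Support integrity.**  After convergence the solution is re-solved
restricted to its reported support; if that restriction is infeasible the
support is re-read at machine tolerance.  Reported support sizes can
therefore overestimate, but never undershoot, the true minimum — a
property the enumeration oracle verifies on every random instance.

**Escaping local optima.**  DCA is a local method; on small instances it
can converge to an equal-or-larger support than the true minimum.  Two
optional mechanisms (both off by default, `DCASettings.robust()` enables
them) trade extra LPs for quality: *backoff* tentatively forces individual
support members (weakest first) to zero and re-runs the DCA, accepting any
strict weighted-cardinality improvement; *restarts* re-run with seeded
multiplicative weight perturbations (uniform on [0.5, 1.5]).  With both,
agreement with the enumeration oracle on random sparse network instances
is 94–100% across seeds (plain: 72–90%), with zero undershoots.  Defaults
stay plain so the two-to-three-LP behavior remains the genome-scale
default regime.

**Oracles.**  `brute_force_min_card` enumerates supports in increasing
size, fixing off-support variables to zero and testing LP feasibility —
exact for up to ~20 cardinality variables.  `verify_support_minimality`
implements the one-by-one removal test: off-support variables fixed to
zero, then each member in turn; a member whose box excludes zero (e.g. a
forced lower bound) is unremovable by definition, not a relaxation
opportunity.

## The audits

**Stoichiometric consistency** asks for positive molecular masses
`w >= 1` with `N^T w = 0` on the internal reaction columns.  Rather than
maximizing the number of conserved metabolites, the package minimizes the
number of *relaxed conservation constraints*: `min card(x)` s.t.
`N^T w + x = 0, w >= 1`.  Reactions with `x_j = 0` are consistent;
reactions needing relaxation are only of *unknown* status, because
omitting some of them can render others consistent.  The sequential loop
therefore omits, per round, the relaxed reactions that are also apparently
elementally imbalanced (default criterion) or — lacking formulae, or when
no relaxed reaction is imbalanced — those with the most nonzero
coefficients (lumped reactions; ties kept together, ordered by total
absolute stoichiometry then id), and re-solves until the relaxation
cardinality stops shrinking (`max_rounds = 20`).  Because minimum-
cardinality relaxation supports are rarely unique, suspect (imbalanced)
reactions get a 10% relaxation-weight discount: ties then resolve toward
the reactions the omission criterion targets, without changing which
cardinalities are attainable; the loop runs with the robust solver preset
by default.  The final consistent subset always carries an exact
certificate — the optimal `w` itself satisfies `N^T w = 0` on it — which
the tests re-verify, and the partition provably depends only on `S`, never
on bounds (asserted under random bound rescalings).  The internal/external
split feeding this is heuristic (single-nonzero columns plus conventional
id prefixes `EX_/DM_/sink_/SK_/biomass`, configurable) and is known to
underestimate the true external set.

**Elemental balance.**  Hill-notation formulae are parsed with integer
counts; `R`, `X`, `FULLR…` and `*` mark generic residues, and any reaction
touching a residue-bearing or formula-less metabolite is *undetermined* —
never silently balanced.  Proton-only imbalances count as imbalances by
default (`ignore_protons` switches this off).  Charge balance is computed
when charges are present but reported separately; it never feeds the
omission criterion.

**Leaks and siphons.**  A leak is a metabolite strictly producible from
nothing (`S v = y >= 0`, `y_i > 0` within bounds; exchanges closed by
default), a siphon the mirror image.  One cardinality-maximization solve
proposes candidates; every metabolite is then settled by an individual LP
(maximize `y_i` capped at 1), and every strictly produced metabolite of
each confirming mode is absorbed, so the reported sets are exact, not
heuristic.  Minimal leak modes (`min card(v)` with `y_i >= 1`) use the
robust preset.

**Flux consistency** amalgamates supports of repeated cardinality
maximizations (covered reactions drop out of the objective each round,
bounds clipped to ±1000 for the card solves) and settles whatever remains
with the per-reaction LP pair (max then min `v_j`), so the result *equals*
the 2n-LP oracle while using far fewer LPs on typical networks.

**Thermodynamic flux consistency.**  A flux is thermodynamically
consistent when chemical potentials `y` exist with
`z_j > 0 => N_j^T y < 0` and `z_j < 0 => N_j^T y > 0` for every active
internal reaction; no condition is imposed on inactive reactions.  Net
flux around a stoichiometrically balanced cycle can never satisfy this.
The package uses a project-then-certify scheme: (1) propose a candidate
flux by cardinality maximization over not-yet-covered flux-consistent
reactions, with seeded random objective perturbations for support
diversity; (2) project it to a cycle-free flux at fixed exchange part by
weighted one-norm minimization with sign-restricted bounds (weights 0.01
on not-yet-covered reactions so projection prefers keeping them active) —
a one-norm-minimal flux cannot contain a cycle concordant with its own
signs, so (3) the potential LP (`sigma_j·N_j^T y <= -1`; potentials are
scale-free, so the strict inequality is normalized to -1) always certifies
it, and the witness `(z, w, y, sigma)` is stored and re-verified in tests.
When a full round adds no coverage, remaining reactions are probed one by
one (maximize `|v_j|`, project, certify) before being declared
inconsistent.  By a Gordan-type theorem of the alternative, infeasibility
of the potential LP is witnessed by a sign-concordant balanced cycle
(`N c = 0`, `sigma_j c_j >= 0`, `c != 0`), and the package computes that
certificate; the two LPs can never agree, which the tests check on random
sign patterns.  The amalgamated consistent set is an *underestimate*: the
thermodynamically feasible set is nonconvex, and a reaction whose every
admissible flux with a given exchange pattern is cyclic will (correctly)
never be covered, but sampling more rounds can only grow the set.
Forward and reverse directions are tracked separately.

**Sparse FBA** imposes attainment as `c^T v >= rho* - feas_tol`
(`feas_tol = 1e-6`), the same tolerance-relaxed re-check used by the
removal test, then minimizes `card(v)` with the plain DCA (two to three
LPs).  **Relaxed FBA** minimizes `lam·card(r) + alpha·card(p) +
alpha·card(q)` over `S v + r = b`, `l - p <= v <= u + q`, `p, q, r >= 0`
(weights scalar or per-constraint, default 1).  Note the sign convention:
`r >= 0` in `S v + r = b` can absorb net *consumption* of a metabolite but
not net overproduction; steady-state relaxation is disabled by default
(`allow_r=False`) and bound relaxations carry the load.  Relaxations below
`feas_tol` are zeroed and the relaxed model is re-verified feasible before
returning.  The **isolated-hydrolysis cycle test** closes all external
reactions, forces the energy-maintenance reaction (`v >= 1`; cycle
supports are scale-invariant, so the unit scale is arbitrary) and
minimizes internal support: any solution is a stoichiometrically balanced
cycle that admits unbounded ATP hydrolysis and should be repaired by
making one member irreversible; infeasibility ("none") is the desired
state.

## Synthetic study conditions

All tests and the acceptance script run on seeded generators, in integer
arithmetic so exact certificates exist:

* **Consistent cores** draw small integer masses (1–4; the first two
  metabolites are pinned to masses 1 and 2 so any total can be change-made
  with coefficients at most 4) and build each internal reaction exactly
  mass-balanced; formulae are written `C{mass}` so elemental balance
  coincides with mass balance.  Exchanges default to one per metabolite,
  making the core flux consistent under reversible ±1000 bounds.
* **Inconsistency injection** adds an extra participant to a column and
  *certifies*, by LP, that no positive mass vector balances the corrupted
  column together with the finally uncorrupted core; uncertifiable picks
  are swapped out.  Defect-recovery experiments use overdetermined cores
  (`n_internal ≈ 2m + 2`): with sparse cores the minimum-cardinality
  diagnosis is genuinely non-unique (removing one balanced column can
  "explain" several corrupted ones), so exact recovery is only a
  well-posed target in the overdetermined regime — which is also the
  regime of real reconstructions, whose thousands of reactions pin
  metabolite masses redundantly.
* **Blocked reactions** are fresh dead ends (new metabolite, no outlet):
  blocked for any bounds, mass-balanced, hence orthogonal to
  stoichiometric consistency.  **Cycles** are mass-matched loops over
  exchanged metabolites (so they never revive a planted dead end),
  reversible, hence flux-consistent even closed but never potential-
  certifiable.  **Infeasible FBA** instances force `lb = 1` on fresh dead
  ends, making the minimal relaxation cardinality exactly the number of
  conflicts.
* **Random cardinality instances** (the oracle-agreement study) use
  stoichiometric-like sparse matrices — 2–4 nonzeros per column,
  coefficients ±1/±2, 8–12 variables, 4–7 constraints, mixed
  reversible/irreversible bounds, right-hand side planted from a 1–3-sparse
  solution so feasibility is guaranteed and the true minimum is small.

What these fixtures do *not* emulate: realistic degree distributions,
compartments, cofactor coupling, or the sheer size of genome-scale
reconstructions.  Passing tests therefore demonstrate correctness of the
formulations, certificates and solver plumbing, and scalability up to the
300-metabolite preset — not biological fidelity of any particular
diagnosis on a published model.

## Problem sizes and runtime

The test suite and acceptance script were sized for a single CPU: 50
random oracle-agreement instances (enumeration is exponential, so
cardinality blocks stay at or below 12 variables), 20 defect-recovery
fixtures, 10 flux/thermo fixtures, 100 sign patterns, six sparse-FBA
models at m=300 metabolites with 500 internal reactions (a scaled check of the two-to-three-LP behavior), and 30
bound perturbations.  The full suite runs in about 40 s, the acceptance
script in about 25 s.

## Numerical choices and degenerate inputs

* LP feasibility tolerance, support threshold, attainment slack and
  relaxation-zeroing threshold all share `1e-6`, so supports are read at
  the solver's own resolution.  Mass variables are capped at 1e6 and
  relaxation variables at 1e6 for conditioning; default missing bounds are
  ±1000 (the community convention).
* All-zero columns are flagged external with a warning; empty internal
  sets are vacuously consistent; an empty support is vacuously minimal;
  `k = 0` injections are no-ops.
* Maximize-mode cardinality variables must have finite bounds (clipped to
  ±1000 in the flux audits); unbounded LP subproblems raise an error
  naming the linear-cost block, since cardinality objectives themselves
  are bounded.
* LP tie-breaking is delegated to the backend, so exact supports (not
  their sizes) are backend-reproducible rather than backend-independent;
  tests that depend on exact supports pin the default backend.
* GLPK warm starts reuse the previous basis through a persistent optlang
  model keyed on constraint structure; the scipy/HiGHS backend solves each
  subproblem cold.  Warm starting affects iteration cost only, never
  which iterates are feasible.

## Known limitations

* Thermodynamic consistency is an underestimate by design; the exact set
  is NP-hard to certify and nonconvex.
* The internal/external split is heuristic; audits accept an explicit
  partition wherever the caller knows better.
* The cobrapy JSON/SBML dialects carry no steady-state right-hand side, so
  files round-trip `b = 0` only; the TSV format and the in-memory type
  carry arbitrary `b`.
* Solution enumeration (multiple distinct minimal supports) is out of
  scope; the solver returns one support per run, diversified only by the
  seeded perturbations in the thermodynamic amalgamation.
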