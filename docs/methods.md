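# Methods

## Model representation and normalization

A model is an ordered list of metabolites and reactions. Metabolites
flagged *external* are boundary species exempt from mass balance; everything
else contributes a row to the stoichiometric matrix `S` (rows in declared
metabolite order, columns in declared reaction order — insertion order is
preserved everywhere so matrices, tables and serialized files are
bit-reproducible). A reaction is *reversible* iff its lower bound is
negative; this is a derived property, so the invariant can never drift out
of sync with the bounds.

SBML Level 2 has no canonical encoding for flux bounds or gene rules, so
the reader classifies each file into one of four dialects and normalizes:

| dialect | detected by | bounds |
|---|---|---|
| COBRA | kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters or `GENE_ASSOCIATION` notes | taken verbatim |
| SEED | `rxnNNNNN`/`cpdNNNNN` id namespace (no COBRA markers) | reversibility defaults |
| KGML | all reaction ids are KEGG R-numbers and no bounds exist anywhere | reversibility defaults |
| GENERIC | none of the above | reversibility defaults |

Precedence is COBRA > SEED > KGML > GENERIC: an explicit bound encoding is
the strongest signal, identifier namespaces the next. Reversibility
defaults are `[−BIG, +BIG]` (reversible) and `[0, +BIG]` (irreversible)
with `BIG = 10000`, the conventional "effectively unbounded" influx
sentinel; using a finite sentinel keeps every LP bounded. A species is
external iff it carries `boundaryCondition="true"`, sits in an
extracellular compartment (id `e`, id suffix `_b`, name containing
"extra"), or — in SEED files — its id ends in the `_b` boundary suffix.
The heuristics are a disjunction because the reader's whole purpose is to
accept all flavours. These detection rules are reconstructed from the
conventions of the named source platforms; files from other pipelines fall
back to GENERIC, which is always safe (reversibility defaults only).
SBML Level 3 files with `fbc` bounds are read through the same
normalization; SBML is never written (the native tabular format is the
interchange format).

*Orphan* (dead-end) metabolites are internal metabolites lacking either a
producer or a consumer, treating a reversible reaction as able to play both
roles; an orphan reaction touches at least one orphan metabolite. External
metabolites are counted in `n_metabolites` but can never be orphans.
Zero stoichiometric coefficients are rejected at validation as ambiguous.

## The LP

`solve_fba` maximizes (or minimizes) one reaction's flux subject to
`S v = 0` and the per-reaction bounds, via HiGHS
(`scipy.optimize.linprog`); the backend sits behind a single solve contract
(matrix, bounds, objective → status/value/point) and is swappable. Only
the objective *value* is contractual — FBA optima are famously degenerate
and the returned flux vector is one optimal vertex among possibly many.
Feasibility tolerance is 1e−6 absolute on constraints and 1e−6 relative on
objective comparisons (standard double-precision LP practice). UNBOUNDED
and INFEASIBLE are reported as statuses, never clamped or masked; since
the normalizer caps bounds at ±10000, unboundedness signals a modelling
error worth surfacing.

## Medium semantics

A medium maps external metabolite ids to maximal influx rates. Bounds on a
pseudo-reaction `∅ ↔ m` constrain nothing while `m` is exempt from mass
balance, so `apply_medium` (a) ensures every external metabolite has an
exchange reaction, auto-creating `∅ ↔ m` where models (SEED/KGML exports
often) omit it, (b) brings those metabolites under mass balance so the
exchange flux *is* the net influx, and (c) caps the import direction at
the medium value — 0 for external metabolites the medium does not list —
while leaving secretion unbounded (media describe what may enter, not what
may leave). The exchange map is recorded on the returned model, making the
operation idempotent and allowing a different medium to be re-applied
later; the input model is never mutated. A medium applied to a collection
must only name metabolites that are external in at least one member.

Batch comparative FBA is literally member-wise `apply_medium` + `solve_fba`
with the results tabulated in collection order; failed cells carry literal
status tokens (`INFEASIBLE`, `MISSING_OBJECTIVE`) rather than being
dropped, so every row stays complete. The heat-map normalization scales
each column to percent of its own maximum, pins the maximal cell to exactly
100 (immune to division round-off), treats status cells as absent, and maps
an all-zero column to zeros rather than NaN so the matrix stays plottable.

Reaction identity across models is by id string, which presumes a shared
namespace (e.g. all members SEED-derived); mixed-namespace collections
will under-report shared reactions. This is a known limitation.

## Pareto sweep

The trade-off between two objectives is computed by the ε-constraint
method: maximize objective 1 alone (`f1_max`), then for `i = 0..n` floor
objective 1 at the fraction `1 − i/n` of `f1_max` and re-maximize
objective 2 — `n+1` points inclusive of both endpoints, so the fraction-1
point can be checked against "maximize objective 2 at maximal objective 1"
and the fraction-0 point against the plain objective-2 optimum. The floor
is a *lower bound*, not an equality fix: an equality fix can dip below the
envelope when the projection is non-monotone, whereas the lower-bound sweep
always traces the upper boundary of the feasible region projected onto the
two objective fluxes. For an objective whose own lower bound is negative,
the floor interpolates from that bound to `f1_max` so the fraction-0 point
still coincides with the unconstrained optimum; with the usual lower bound
of 0 this reduces to `fraction · f1_max` exactly.

A nutrient is *binding* (limiting) at an optimum when its net import flux
equals its finite, positive medium cap within 1e−6. Transition points —
the metabolic switches where the active constraint set changes — are
fractions where the discrete second difference of objective 2 exceeds
`1e−6 · f2_max` (scale-free; absolute 1e−6 if `f2_max = 0`). A slope kink
lying strictly between grid fractions fires at the two bracketing points;
choose a resolution whose grid contains the kink when an exact count
matters.

## Pathway grafting

Pathway definitions are data (JSON: metabolites, reactions in the same
equation grammar as the native format, and a designated export reaction
whose flux is the production proxy), not per-compound scripts, so one
definition applies to any host. Grafting copies the host, adds missing
metabolites and reactions, and *skips* any pathway reaction whose id the
host already has — the host's version wins, which makes augmentation
idempotent and mirrors the practice of adding only the handful of reactions
a host is missing. Added/skipped ids are recorded on the derivative model.
The member × compound grid then feeds straight into batch FBA with each
pathway's export reaction as objective.

## Synthetic fixtures

All tests and demos run on generated networks with closed-form answers;
a single integer seed determines every output and there is no global
random state.

* **chain(k, uptake)** — uptake-limited linear path; max export = uptake.
* **branch(uptake, m)** — shared hub feeding `m` exports; mass balance on
  the hub forces `v_i + v_j = uptake` between any two products, so the
  front at `n = 10` is exactly the 11 points of that line.
* **two_nutrient(nh3, po4, capacity, glc)** — biomass consumes nitrogen,
  product consumes phosphate, both consume a shared precursor whose
  assimilation is capacity-limited. Defaults (6, 4, 8, 10) give
  `f1_max = min(nh3, capacity) = 6`, product maximum
  `min(po4, capacity) = 4`, and an exactly horizontal plateau over biomass
  fractions `≤ (capacity − po4)/f1_max = 2/3`. The coupling is an internal
  capacity rather than a shared *medium* nutrient deliberately: it keeps
  the binding-nutrient diagnosis at the two front ends a singleton —
  {nh3} at the biomass end, {po4} at the product end — for *every* optimal
  vertex, including the degenerate ones at the plateau where the biomass
  flux is not unique. Doubling both nutrient caps makes the shared
  capacity limiting everywhere and the plateau vanishes.
* **random networks** — ≤ 8 reactions with small integer coefficients and
  finite bounds straddling zero, so the flux polytope is bounded and
  non-empty and an exhaustive vertex-enumeration oracle (fix `n − rank(S)`
  fluxes at bounds, solve the rest, keep feasible basic solutions) can
  certify every optimum.
* **random collections** — a feasible core chain plus accessory reactions
  included per member with a Bernoulli draw; the `unlock_x` accessory is
  the only route to one product, so its presence/flux r² is exactly 1.

What the fixtures do *not* emulate: genome-scale network statistics
(thousands of reactions, realistic degree distributions), biomass
compositions, GPR structure, or compartmentalization. Passing tests
certify the algorithms and the bookkeeping, not the biological fidelity of
any particular curated model.

## Native format

Tab-separated, one reaction per line (`id`, equation, lower, upper, gene
association) with `#MODEL`, `#METABOLITE` and `#EXTERNAL` directives. The
per-metabolite directives preserve declared order and metabolites that
appear in no reaction, making write→read lossless and write→read→write
byte-idempotent; hand-written files may omit them and rely on `#EXTERNAL`
plus first-use order. Equation grammar: `2 a + b -> c` (irreversible),
`a <-> b` (reversible), with an empty side for exchanges (`-> a`).
Numbers are written in shortest-exact form so round-trips are bitwise.
Cosmetic fields (names, compartments, provenance) are carried from SBML
but not serialized here and are excluded from model equality.

## Problem sizes and determinism

The test suite and the acceptance script use 200 random networks of 4–8
reactions for oracle certification, 100 random fronts for sweep
invariants, an 8-member collection for correlation, and resolutions of
10–12 for the analytic fronts — sizes at which every quantity has an
independently computable answer and the whole suite runs in seconds.
Hypothesis-based property tests run derandomized. CLI reruns on identical
inputs produce byte-identical outputs.

## Known limitations

* GPR strings are carried, never evaluated; no gene-knockout analysis.
* No FVA, parsimonious FBA, MILP strain design, or >2-objective fronts.
* Cross-model reaction matching is by id only; no reconciliation.
* KGML-derived files carry no capacity information, so their bounds are
  purely reversibility defaults — comparisons against bound-carrying
  models reflect that (provenance records the dialect so users can tell).
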