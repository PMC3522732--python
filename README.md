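# fluxcompare

Comparative and multi-objective flux balance analysis across collections of
genome-scale metabolic models.

## The problem

Genome-scale constraint-based metabolic models encode the stoichiometry and
capacity bounds of every reaction a genome supports. Flux balance analysis
(FBA) finds a steady-state flux distribution **v** that optimizes a cellular
objective:

```
maximize    c·v
subject to  S v = 0            (mass balance over internal metabolites)
            lb ≤ v ≤ ub        (reaction capacity / medium bounds)
```

where `S` is the stoichiometric matrix and `c` selects an objective reaction
(biomass synthesis, or the final step of a product pathway).

Single-model FBA is routine; *comparative* FBA — asking which of many
organisms has the network topology best suited to overproduce a compound,
under one shared growth medium — is harder in practice, because models from
different pipelines (SEED, COBRA, KEGG-derived) encode FBA data in mutually
incompatible SBML flavours, and because the bookkeeping of grafting a
pathway onto dozens of hosts and tabulating hundreds of solves is tedious.
fluxcompare is a toolkit for exactly that workflow, aimed at people
screening candidate production hosts or studying how biomass growth
competes with secondary-metabolite biosynthesis:

* **Dialect-tolerant SBML reader** — normalizes SEED-, COBRA-, KGML-derived
  and generic SBML Level 2 (plus read-only Level 3/fbc) into one model
  representation, with a simple tabular native format for round-tripping.
* **Collections, media, batch FBA** — apply one medium (maximal influx per
  external metabolite) to every member and tabulate all optima in a single
  comparative table; normalize each column to percent-of-best for heat maps.
* **Pathway grafting** — inject a compound's biosynthesis pathway (a data
  file, not code) into every host, and compute the member × compound grid
  of maximal production fluxes.
* **Pareto fronts** — sweep the trade-off between two objectives
  (ε-constraint method: floor objective 1 at a decreasing fraction of its
  maximum, re-maximize objective 2), with diagnostics naming the *limiting
  nutrients* at any point of the front and locating the *transition points*
  where the active constraint set — the "metabolic switch" — changes.
* **Presence/flux correlation** — r² between a reaction's presence/absence
  across models and the per-model maximal flux, pinpointing the reactions
  that explain capacity differences.
* **Synthetic fixtures** — deterministic generators of toy networks with
  closed-form optima (chains, branches, a two-nutrient biomass/product
  model, random networks, random collections) that drive all tests and
  examples with no external data.

## Worked example

The two-nutrient fixture couples a biomass objective (nitrogen-limited) and
a product objective (phosphate-limited) through a shared assimilation
capacity:

```python
import fluxcompare as fc
from fluxcompare.pareto import ParetoSettings

model, medium = fc.fixtures.make_two_nutrient()
front = fc.pareto_front(model, ParetoSettings("biomass", "product", n=12), medium)
print(front.to_frame().to_string(index=False))
```

```
 fraction  obj1_floor  obj1_percent  obj2_flux  status binding_nutrients
 1.000000         6.0    100.000000        2.0 OPTIMAL             nh3_e
 0.916667         5.5     91.666667        2.5 OPTIMAL
 0.833333         5.0     83.333333        3.0 OPTIMAL
 0.750000         4.5     75.000000        3.5 OPTIMAL
 0.666667         4.0     66.666667        4.0 OPTIMAL             po4_e
 0.583333         3.5     58.333333        4.0 OPTIMAL             po4_e
 ...
 0.000000         0.0      0.000000        4.0 OPTIMAL             po4_e
```

Reading the table: biomass can rise to two-thirds of its maximum (flux 4 of
6) while the product holds its own maximum of 4 — a horizontal plateau, the
"free lunch" regime where the two objectives are limited by *different*
nutrients (`binding_nutrients` names phosphate on the plateau, ammonia at
the biomass end). Past the plateau edge the shared capacity binds and every
extra unit of biomass costs one unit of product.
`fc.transition_points(front)` returns `[0.6667]`, the single metabolic
switch, matching the analytic plateau edge
`(capacity − po4_cap)/f1_max = 2/3`. Re-running with both nutrient caps
doubled (`fc.fixtures.make_two_nutrient(nh3_bound=12, po4_bound=8)`)
removes the plateau: the trade-off becomes a straight line.

The `examples/` directory holds one narrative script per capability
(parsing and summaries, batch comparative FBA, Pareto sweeps, pathway grids
and correlation); each prints the numbers it computes and a line on what
they mean. The same operations are exposed as a thin CLI:

```sh
fluxcompare fixtures --kind two_nutrient --out demo/
fluxcompare pareto --model demo/two_nutrient.tsv --obj1 biomass --obj2 product \
    -n 12 --medium demo/medium.tsv --out front.tsv --plot front.png
```

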