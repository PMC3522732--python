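"""Deterministic generators of synthetic models, collections, media and
pathways with known analytic optima.

These toy networks are first-class citizens: every analysis in the package
can be demonstrated and verified against closed-form answers without
downloading a single real model.  All randomness flows through one integer
seed; there is no global random state.

The generators and what they prove:

``make_chain``
    Linear uptake → conversion → export path; maximal export flux equals
    the uptake bound exactly.
``make_branch``
    One shared precursor feeding ``m`` export paths; the trade-off between
    any two products is the straight line ``v_i + v_j = uptake``.
``make_two_nutrient``
    Biomass consumes nitrogen, product consumes phosphate, and both share a
    finite assimilation capacity.  The trade-off curve has a horizontal
    plateau whose extent is analytic in the bounds; doubling both nutrient
    caps removes the plateau (the limiting constraint shifts to the shared
    capacity everywhere).
``make_random_network``
    Small dense random network with finite bounds straddling zero — the
    flux polytope is bounded and non-empty, so an exhaustive
    vertex-enumeration oracle can certify every LP optimum.
``make_random_collection``
    A feasible shared core plus Bernoulli-included accessory reactions,
    with the presence matrix returned alongside — the test bed for
    presence/flux correlation and comparative grids.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .collection import Medium, ModelCollection
from .model import DEFAULT_BIG, MetabolicModel, Metabolite, Reaction

__all__ = [
    "make_chain",
    "make_branch",
    "make_two_nutrient",
    "make_disjoint_pair",
    "make_random_network",
    "make_random_collection",
    "make_demo_pathway",
]


def make_chain(k: int = 3, uptake: float = 10.0, model_id: str = "chain") -> MetabolicModel:
    """External source → ``k`` internal metabolites → external sink.

    The uptake reaction carries the bound ``[0, uptake]``; everything
    downstream is capacity-unlimited, so the maximal flux through
    ``export`` is exactly ``uptake``.
    """
    if k < 1:
        raise ValueError("chain length k must be >= 1")
    mets = [Metabolite("glc_e", external=True)]
    mets += [Metabolite(f"m{i}") for i in range(1, k + 1)]
    mets.append(Metabolite("prod_e", external=True))
    rxns = [
        Reaction("EX_glc", {"glc_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake", {"glc_e": -1.0, "m1": 1.0}, 0.0, uptake),
    ]
    for i in range(1, k):
        rxns.append(
            Reaction(f"step{i}", {f"m{i}": -1.0, f"m{i+1}": 1.0}, 0.0, DEFAULT_BIG)
        )
    rxns.append(Reaction("export", {f"m{k}": -1.0, "prod_e": 1.0}, 0.0, DEFAULT_BIG))
    rxns.append(Reaction("EX_prod", {"prod_e": -1.0}, 0.0, DEFAULT_BIG))
    model = MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                           provenance="synthetic")
    model.validate()
    return model


def make_branch(
    uptake: float = 10.0, m: int = 2, model_id: str = "branch"
) -> MetabolicModel:
    """Shared precursor feeding ``m`` export paths.

    Objectives ``export_1 .. export_m``; mass balance on the hub forces
    ``Σ v_export_i = v_uptake ≤ uptake``, so the Pareto front between any
    two products is the line ``v_i + v_j = uptake``.
    """
    if m < 2:
        raise ValueError("branch fixture needs at least 2 products")
    mets = [Metabolite("src_e", external=True), Metabolite("hub")]
    rxns = [
        Reaction("EX_src", {"src_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake", {"src_e": -1.0, "hub": 1.0}, 0.0, uptake),
    ]
    for i in range(1, m + 1):
        mets.append(Metabolite(f"p{i}_e", external=True))
        rxns.append(
            Reaction(f"export_{i}", {"hub": -1.0, f"p{i}_e": 1.0}, 0.0, DEFAULT_BIG)
        )
        rxns.append(Reaction(f"EX_p{i}", {f"p{i}_e": -1.0}, 0.0, DEFAULT_BIG))
    model = MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                           provenance="synthetic")
    model.validate()
    return model


def make_disjoint_pair(
    uptake1: float = 10.0, uptake2: float = 7.0, model_id: str = "disjoint"
) -> MetabolicModel:
    """Two completely independent uptake→export paths in one model.

    The objectives ``export_a``/``export_b`` share no resources, so their
    trade-off curve is flat: constraining one never costs the other.
    """
    mets = [
        Metabolite("a_e", external=True),
        Metabolite("a"),
        Metabolite("pa_e", external=True),
        Metabolite("b_e", external=True),
        Metabolite("b"),
        Metabolite("pb_e", external=True),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake_a", {"a_e": -1.0, "a": 1.0}, 0.0, uptake1),
        Reaction("export_a", {"a": -1.0, "pa_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_pa", {"pa_e": -1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_b", {"b_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake_b", {"b_e": -1.0, "b": 1.0}, 0.0, uptake2),
        Reaction("export_b", {"b": -1.0, "pb_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_pb", {"pb_e": -1.0}, 0.0, DEFAULT_BIG),
    ]
    model = MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                           provenance="synthetic")
    model.validate()
    return model


def make_two_nutrient(
    nh3_bound: float = 6.0,
    po4_bound: float = 4.0,
    capacity: float = 8.0,
    glc_bound: float = 10.0,
) -> Tuple[MetabolicModel, Medium]:
    """Biomass/product fixture with provably plateaued trade-off.

    Topology::

        glc_e -> c -> s   (assimilation, capacity-limited to ``capacity``)
        s + n -> biomass  (n from NH3, medium-capped at ``nh3_bound``)
        s + p -> product  (p from PO4, medium-capped at ``po4_bound``)

    With defaults: f1_max = min(nh3, capacity) = 6; the product stays at
    its maximum min(po4, capacity) = 4 while the biomass floor leaves at
    least 4 units of capacity, i.e. for fractions up to
    ``(capacity − po4)/f1_max = 2/3`` of maximal biomass — an exactly
    horizontal plateau.  At the fraction-1 end NH3 is the single binding
    nutrient; at the fraction-0 end PO4 is, regardless of which optimal
    vertex the solver returns.  Doubling both nutrient bounds makes the
    shared capacity limiting everywhere and the plateau vanishes.
    """
    mets = [
        Metabolite("glc_e", external=True),
        Metabolite("nh3_e", external=True),
        Metabolite("po4_e", external=True),
        Metabolite("c"),
        Metabolite("s"),
        Metabolite("n"),
        Metabolite("p"),
        Metabolite("bio_e", external=True),
        Metabolite("prod_e", external=True),
    ]
    rxns = [
        Reaction("EX_glc", {"glc_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_nh3", {"nh3_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_po4", {"po4_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake_glc", {"glc_e": -1.0, "c": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake_nh3", {"nh3_e": -1.0, "n": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("uptake_po4", {"po4_e": -1.0, "p": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("assimilate", {"c": -1.0, "s": 1.0}, 0.0, capacity),
        Reaction("biomass", {"s": -1.0, "n": -1.0, "bio_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("product", {"s": -1.0, "p": -1.0, "prod_e": 1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_bio", {"bio_e": -1.0}, 0.0, DEFAULT_BIG),
        Reaction("EX_prod", {"prod_e": -1.0}, 0.0, DEFAULT_BIG),
    ]
    model = MetabolicModel(
        id="two_nutrient", metabolites=mets, reactions=rxns, provenance="synthetic"
    )
    model.validate()
    medium = Medium(
        entries={"glc_e": glc_bound, "nh3_e": nh3_bound, "po4_e": po4_bound}
    )
    return model, medium


def plateau_fraction(
    nh3_bound: float = 6.0, po4_bound: float = 4.0, capacity: float = 8.0
) -> float:
    """Analytic plateau extent of the two-nutrient fixture, as a fraction of
    maximal biomass flux (0 means no plateau)."""
    f1_max = min(nh3_bound, capacity)
    p_max = min(po4_bound, capacity)
    return max(0.0, (capacity - p_max) / f1_max) if f1_max > 0 else 0.0


def make_random_network(
    seed: int,
    n_reactions: int = 6,
    n_metabolites: int = 3,
    max_bound: float = 10.0,
    model_id: str = "random",
) -> MetabolicModel:
    """Small random network whose flux polytope is bounded and non-empty.

    Every bound is finite and straddles zero (``lb ≤ 0 ≤ ub``), so the zero
    vector is always feasible and every LP optimum is certified by vertex
    enumeration.  Coefficients are small integers to keep vertex arithmetic
    well-conditioned.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"x{i}") for i in range(n_metabolites)]
    rxns = []
    for j in range(n_reactions):
        n_part = int(rng.integers(1, min(3, n_metabolites) + 1))
        chosen = rng.choice(n_metabolites, size=n_part, replace=False)
        stoich = {}
        for i in chosen:
            coeff = int(rng.choice([-2, -1, 1, 2]))
            stoich[f"x{i}"] = float(coeff)
        lo = float(rng.choice([0.0, -rng.integers(1, int(max_bound) + 1)]))
        hi = float(rng.integers(0, int(max_bound) + 1))
        rxns.append(Reaction(f"r{j}", stoich, lo, hi))
    model = MetabolicModel(
        id=f"{model_id}_{seed}", metabolites=mets, reactions=rxns,
        provenance="synthetic",
    )
    model.validate()
    return model


def make_random_collection(
    n_models: int = 6,
    n_core_reactions: int = 3,
    presence_prob: float = 0.5,
    seed: int = 0,
    uptake: float = 10.0,
) -> Tuple[ModelCollection, pd.DataFrame]:
    """Shared feasible core plus Bernoulli-included accessory reactions.

    The core is a linear chain (uptake bound ``uptake``) that alone
    sustains the main export, so every member is feasible.  Accessory
    reactions branch off core metabolites to extra exported products; each
    is included per member with probability ``presence_prob``.  One
    accessory, ``unlock_x``, is the *only* route to product ``x_e``: its
    presence alone decides whether that product's maximal flux is
    ``uptake`` or 0, giving a perfect presence/flux correlation.

    Returns the collection and the 0/1 presence matrix
    (rows = member ids, columns = accessory reaction ids).
    """
    if not (0 < presence_prob <= 1):
        raise ValueError("presence_prob must be in (0, 1]")
    if n_core_reactions < 2:
        raise ValueError("core chain needs at least 2 internal metabolites")
    rng = np.random.default_rng(seed)
    core = make_chain(k=n_core_reactions, uptake=uptake, model_id="core")

    accessory: Dict[str, Tuple[List[Metabolite], List[Reaction]]] = {}
    accessory["unlock_x"] = (
        [Metabolite("x_e", external=True)],
        [
            Reaction("unlock_x", {"m1": -1.0, "x_e": 1.0}, 0.0, DEFAULT_BIG),
            Reaction("EX_x", {"x_e": -1.0}, 0.0, DEFAULT_BIG),
        ],
    )
    accessory["alt_step"] = (
        [],
        [Reaction("alt_step", {"m1": -1.0, f"m{n_core_reactions}": 1.0}, 0.0, DEFAULT_BIG)],
    )
    accessory["side_y"] = (
        [Metabolite("y_e", external=True)],
        [
            Reaction("side_y", {f"m{n_core_reactions}": -1.0, "y_e": 1.0}, 0.0, DEFAULT_BIG),
            Reaction("EX_y", {"y_e": -1.0}, 0.0, DEFAULT_BIG),
        ],
    )

    members = []
    presence_rows = []
    for k in range(n_models):
        member = core.copy()
        member.id = f"model_{k:02d}"
        row = {}
        for acc_id, (acc_mets, acc_rxns) in accessory.items():
            present = bool(rng.random() < presence_prob)
            row[acc_id] = 1 if present else 0
            if present:
                existing = {m.id for m in member.metabolites}
                for met in acc_mets:
                    if met.id not in existing:
                        member.metabolites.append(
                            Metabolite(met.id, met.name, met.compartment, met.external)
                        )
                for rxn in acc_rxns:
                    if not member.has_reaction(rxn.id):
                        member.reactions.append(rxn.copy())
        member.validate()
        members.append(member)
        presence_rows.append(row)

    collection = ModelCollection(name=f"random_{seed}", members=members)
    presence = pd.DataFrame(
        presence_rows, index=[m.id for m in members], columns=list(accessory)
    )
    return collection, presence


def make_demo_pathway(compound: str = "demoamycin") -> "PathwayDefinition":
    """Two-step synthetic biosynthesis pathway branching off the chain
    fixture's ``m1`` precursor, with a new intermediate and an exported
    compound (the production proxy is the export step)."""
    from .pathway import PathwayDefinition

    return PathwayDefinition(
        compound=compound,
        new_metabolites=[
            Metabolite(f"{compound}_int"),
            Metabolite(f"{compound}_e", external=True),
        ],
        reactions=[
            Reaction(
                f"syn_{compound}",
                {"m1": -1.0, f"{compound}_int": 1.0},
                0.0,
                DEFAULT_BIG,
            ),
            Reaction(
                f"export_{compound}",
                {f"{compound}_int": -1.0, f"{compound}_e": 1.0},
                0.0,
                DEFAULT_BIG,
            ),
            Reaction(f"EX_{compound}", {f"{compound}_e": -1.0}, 0.0, DEFAULT_BIG),
        ],
        export_reaction=f"export_{compound}",
    )
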