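"""In-memory representation of constraint-based metabolic models.

A :class:`MetabolicModel` is an ordered set of metabolites and reactions.
Metabolites flagged ``external`` are boundary species: they are exempt from
the steady-state mass balance and form the interface to the growth medium.
The stoichiometric matrix S has one row per *internal* metabolite and one
column per reaction; flux balance analysis solves ``S v = 0`` subject to the
per-reaction capacity bounds.

Insertion order of metabolites and reactions is preserved everywhere so that
matrices, summaries and serialized files are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np

from .errors import StructuralError

#: Sentinel for an effectively unbounded flux capacity.  Keeps every LP
#: bounded; matches the conventional "influx upper bound 10000" used when a
#: medium ingredient is not meant to be limiting.
DEFAULT_BIG = 10000.0


@dataclass
class Metabolite:
    """A chemical species in a model.

    ``external=True`` marks a boundary species, excluded from mass balance.
    """

    id: str
    name: str = field(default="", compare=False)
    compartment: str = ""
    external: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise StructuralError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A (possibly reversible) conversion with capacity bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    for consumed species, positive for produced ones.  A coefficient of zero
    is rejected at validation (ambiguous intent).  ``gene_association`` is an
    opaque boolean rule over gene ids; it is carried, never evaluated.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BIG
    name: str = field(default="", compare=False)
    gene_association: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise StructuralError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise StructuralError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        """A reaction is reversible iff its lower bound admits negative flux."""
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gene_association=self.gene_association,
        )


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites and reactions.

    ``provenance`` records the source dialect of a parsed file (``SEED``,
    ``COBRA``, ``KGML``, ``GENERIC``, ``native`` or ``synthetic``).
    ``annotations`` is scratch space for operations that need to record
    bookkeeping on a derived model (e.g. which pathway reactions were added);
    neither field participates in equality.
    """

    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    name: str = field(default="", compare=False)
    provenance: str = field(default="native", compare=False)
    annotations: dict = field(default_factory=dict, compare=False)

    # -- lookup helpers -------------------------------------------------

    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    @property
    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.external]

    @property
    def external_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if m.external]

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise StructuralError on the
        first violation."""
        seen_m: set = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise StructuralError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise StructuralError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise StructuralError(
                    f"reaction {r.id!r}: lower bound exceeds upper bound"
                )
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in seen_m and met_id not in {
                    m.id for m in self.metabolites
                }:
                    raise StructuralError(
                        f"reaction {r.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
                if coeff == 0:
                    raise StructuralError(
                        f"reaction {r.id!r}: zero coefficient for {met_id!r}"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[
                Metabolite(m.id, m.name, m.compartment, m.external)
                for m in self.metabolites
            ],
            reactions=[r.copy() for r in self.reactions],
            name=self.name,
            provenance=self.provenance,
            annotations=dict(self.annotations),
        )


@dataclass(frozen=True)
class ModelSummary:
    """Structural overview counts for one model.

    An *orphan* (dead-end) metabolite is an internal metabolite that is only
    ever consumed or only ever produced across all reactions, treating
    reversible reactions as able to do both.  An orphan reaction is any
    reaction whose stoichiometry involves at least one orphan metabolite.
    External metabolites are included in ``n_metabolites`` but can never be
    orphans.
    """

    n_reactions: int
    n_metabolites: int
    n_orphan_reactions: int
    n_orphan_metabolites: int


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Assemble S with rows = internal metabolites (declared order) and
    columns = reactions (declared order).

    Entry (i, j) is the signed coefficient of internal metabolite i in
    reaction j; external metabolites contribute no row.  Raises
    :class:`StructuralError` if a reaction references an undeclared
    metabolite.
    """
    declared = {m.id for m in model.metabolites}
    internal_index = {m.id: i for i, m in enumerate(model.internal_metabolites)}
    S = np.zeros((len(internal_index), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in declared:
                raise StructuralError(
                    f"reaction {rxn.id!r} references undeclared metabolite "
                    f"{met_id!r}"
                )
            i = internal_index.get(met_id)
            if i is not None:
                S[i, j] = coeff
    return S


def orphan_metabolites(model: MetabolicModel) -> List[str]:
    """Ids of internal metabolites that lack either a producer or a consumer.

    A reversible reaction counts as both producer and consumer of every
    participant, since flux may run either way.
    """
    produced: set = set()
    consumed: set = set()
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoichiometry.items():
            if rxn.reversible:
                produced.add(met_id)
                consumed.add(met_id)
            elif coeff > 0:
                produced.add(met_id)
            else:
                consumed.add(met_id)
    return [
        m.id
        for m in model.internal_metabolites
        if not (m.id in produced and m.id in consumed)
    ]


def summarize(model: MetabolicModel) -> ModelSummary:
    """Compute the structural overview counts displayed for each model."""
    orphans = set(orphan_metabolites(model))
    orphan_rxns = [
        r.id for r in model.reactions if any(m in orphans for m in r.stoichiometry)
    ]
    return ModelSummary(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_orphan_reactions=len(orphan_rxns),
        n_orphan_metabolites=len(orphans),
    )
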