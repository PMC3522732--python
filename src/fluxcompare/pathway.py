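"""Grafting compound-biosynthesis pathways onto host models.

To ask "how well could organism X produce compound Y?", the biosynthetic
pathway for Y (its reactions, any metabolites new to the host, and helper
reactions for precursor supply) is injected into each model of a
collection, producing a derivative model per (member, compound) pair.  The
flux through the pathway's designated export reaction is the production
proxy maximized by FBA.

Pathway definitions are data (JSON), not code, so the same definition can
be applied to any host.  A pathway reaction whose id already exists in the
host is skipped — the host's own version wins — which makes augmentation
idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .collection import ModelCollection
from .errors import StructuralError
from .model import MetabolicModel, Metabolite, Reaction
from .sbml_io import format_equation, parse_equation

__all__ = ["PathwayDefinition", "augment", "augment_collection", "AugmentGrid"]


@dataclass
class PathwayDefinition:
    """A compound's biosynthesis pathway ready for injection.

    ``export_reaction`` names the member of ``reactions`` whose flux is the
    production proxy; every metabolite id a pathway reaction references must
    resolve either in the host model or in ``new_metabolites``.
    """

    compound: str
    reactions: List[Reaction]
    new_metabolites: List[Metabolite] = field(default_factory=list)
    export_reaction: str = ""

    def __post_init__(self) -> None:
        if self.export_reaction and self.export_reaction not in {
            r.id for r in self.reactions
        }:
            raise StructuralError(
                f"pathway {self.compound!r}: export reaction "
                f"{self.export_reaction!r} is not among its reactions"
            )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PathwayDefinition":
        data = json.loads(Path(path).read_text())
        metabolites = [
            Metabolite(id=m["id"], external=bool(m.get("external", False)))
            for m in data.get("metabolites", [])
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry=parse_equation(r["equation"]),
                lower_bound=float(r.get("lb", 0.0)),
                upper_bound=float(r.get("ub", 10000.0)),
            )
            for r in data.get("reactions", [])
        ]
        return cls(
            compound=data["compound"],
            reactions=reactions,
            new_metabolites=metabolites,
            export_reaction=data.get("export_reaction", ""),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            "compound": self.compound,
            "metabolites": [
                {"id": m.id, "external": m.external} for m in self.new_metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "equation": format_equation(r),
                    "lb": r.lower_bound,
                    "ub": r.upper_bound,
                }
                for r in self.reactions
            ],
            "export_reaction": self.export_reaction,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def augment(model: MetabolicModel, pathway: PathwayDefinition) -> MetabolicModel:
    """Return a derivative model with the pathway grafted on.

    All original content is preserved.  Pathway metabolites already present
    in the host are not duplicated; pathway reactions whose id already
    exists are skipped (the host's reaction wins).  The derivative model
    records the added and skipped reaction ids in
    ``annotations['pathway_added']`` / ``annotations['pathway_skipped']``.
    Raises :class:`StructuralError` if a pathway reaction references a
    metabolite declared neither in the host nor in ``new_metabolites``.
    """
    known = {m.id for m in model.metabolites} | {
        m.id for m in pathway.new_metabolites
    }
    for rxn in pathway.reactions:
        for met_id in rxn.stoichiometry:
            if met_id not in known:
                raise StructuralError(
                    f"pathway {pathway.compound!r} reaction {rxn.id!r} "
                    f"references unknown metabolite {met_id!r}"
                )

    out = model.copy()
    host_mets = {m.id for m in out.metabolites}
    for met in pathway.new_metabolites:
        if met.id not in host_mets:
            out.metabolites.append(
                Metabolite(met.id, met.name, met.compartment, met.external)
            )
            host_mets.add(met.id)

    added, skipped = [], []
    for rxn in pathway.reactions:
        if out.has_reaction(rxn.id):
            skipped.append(rxn.id)
        else:
            out.reactions.append(rxn.copy())
            added.append(rxn.id)

    out.annotations["pathway_compound"] = pathway.compound
    out.annotations["pathway_added"] = added
    out.annotations["pathway_skipped"] = skipped
    return out


@dataclass
class AugmentGrid:
    """Derivative models for every (member, compound) pair.

    ``models`` maps ``(model_id, compound)`` to the derivative model;
    per-cell failures are recorded in ``errors`` instead of aborting the
    grid.
    """

    models: Dict[Tuple[str, str], MetabolicModel]
    errors: Dict[Tuple[str, str], str]
    member_ids: List[str]
    compounds: List[str]
    export_reactions: Dict[str, str] = field(default_factory=dict)

    def collection_for(self, compound: str) -> ModelCollection:
        """The derivative models of one compound as a collection whose
        member ids are the original host ids (so batch tables align)."""
        members = []
        for mid in self.member_ids:
            derived = self.models.get((mid, compound))
            if derived is not None:
                renamed = derived.copy()
                renamed.id = mid
                members.append(renamed)
        return ModelCollection(name=compound, members=members)


def augment_collection(
    collection: ModelCollection, pathways: List[PathwayDefinition]
) -> AugmentGrid:
    """Build the member × compound grid of derivative models.

    Feeds directly into :func:`fluxcompare.collection.batch_fba` with each
    pathway's export reaction as the objective column.
    """
    models: Dict[Tuple[str, str], MetabolicModel] = {}
    errors: Dict[Tuple[str, str], str] = {}
    for member in collection.members:
        for pathway in pathways:
            key = (member.id, pathway.compound)
            try:
                derived = augment(member, pathway)
                derived.id = f"{member.id}__{pathway.compound}"
                models[key] = derived
            except StructuralError as exc:
                errors[key] = str(exc)
    return AugmentGrid(
        models=models,
        errors=errors,
        member_ids=collection.member_ids(),
        compounds=[p.compound for p in pathways],
        export_reactions={p.compound: p.export_reaction for p in pathways},
    )


def production_table(grid: AugmentGrid, medium=None):
    """Maximal production flux for every (member, compound) cell.

    Runs one batch FBA per compound column over that compound's derivative
    models, maximizing the pathway's export reaction, and assembles a
    member × compound :class:`~fluxcompare.collection.ComparativeResultTable`
    (the raw input of the relative-flux heat map).  Cells whose
    augmentation failed carry the ``MISSING_OBJECTIVE`` token.
    """
    from .collection import (
        MISSING_OBJECTIVE,
        ComparativeResultTable,
        batch_fba,
    )

    cells: Dict[Tuple[str, str], object] = {
        (mid, compound): MISSING_OBJECTIVE
        for mid in grid.member_ids
        for compound in grid.compounds
    }
    for compound in grid.compounds:
        sub = grid.collection_for(compound)
        if not sub.members:
            continue
        table = batch_fba(
            sub, {compound: grid.export_reactions[compound]}, medium=medium
        )
        for mid in sub.member_ids():
            cells[(mid, compound)] = table.cells[(mid, compound)]
    return ComparativeResultTable(
        model_ids=grid.member_ids,
        objective_labels=list(grid.compounds),
        cells=cells,  # type: ignore[arg-type]
    )
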