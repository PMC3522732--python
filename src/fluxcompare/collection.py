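"""Model collections, growth media, batch comparative FBA and the
presence/flux correlation statistic.

A *collection* is an ordered, named set of models analysed together.  A
*medium* assigns each permitted external metabolite a maximal influx rate;
applying it to a model caps the import direction of that metabolite's
exchange reaction while leaving secretion unbounded.  Unlisted external
metabolites get influx 0 — nothing enters that the medium does not supply.

Reaction identity across models is by id string match, which presumes a
shared reaction namespace (e.g. all models SEED-derived); this is a
documented limitation for mixed-namespace collections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import MediumError, StatisticsError, StructuralError
from .fba import FluxResult, SolverStatus, solve_fba
from .model import DEFAULT_BIG, MetabolicModel, Metabolite, Reaction
from . import sbml_io

__all__ = [
    "ModelCollection",
    "Medium",
    "ComparativeResultTable",
    "MISSING_OBJECTIVE",
    "apply_medium",
    "batch_fba",
    "relative_flux_matrix",
    "presence_flux_correlation",
]

#: Literal status token for a member lacking the requested objective.
MISSING_OBJECTIVE = "MISSING_OBJECTIVE"

_EXCHANGE_MAP_KEY = "exchange_map"


@dataclass
class ModelCollection:
    """Named ordered list of models; the unit of comparative analysis."""

    name: str
    members: List[MetabolicModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise StructuralError(
                f"collection {self.name!r} has duplicate member model ids"
            )

    def member_ids(self) -> List[str]:
        return [m.id for m in self.members]

    def get(self, model_id: str) -> MetabolicModel:
        for m in self.members:
            if m.id == model_id:
                return m
        raise KeyError(model_id)

    def external_metabolite_ids(self) -> set:
        """Union of external metabolite ids over all members, including ids
        recorded by an earlier medium application."""
        out: set = set()
        for m in self.members:
            out.update(met.id for met in m.external_metabolites)
            out.update(m.annotations.get(_EXCHANGE_MAP_KEY, {}))
        return out

    @classmethod
    def from_directory(
        cls, path: Union[str, Path], name: Optional[str] = None
    ) -> "ModelCollection":
        """Build a collection from a directory of model files, sorted
        lexicographically.  ``*.xml``/``*.sbml`` are parsed as SBML,
        ``*.tsv``/``*.txt`` as native format."""
        path = Path(path)
        members = []
        for file in sorted(path.iterdir()):
            if file.suffix.lower() in (".xml", ".sbml"):
                members.append(sbml_io.parse_sbml(file))
            elif file.suffix.lower() in (".tsv", ".txt"):
                members.append(sbml_io.read_native(file))
        return cls(name=name or path.name, members=members)


@dataclass
class Medium:
    """Maximal influx rates for external metabolites, applied uniformly to a
    collection.  Secretion is never limited by a medium."""

    entries: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met_id, value in self.entries.items():
            if value < 0:
                raise MediumError(
                    f"medium influx for {met_id!r} must be non-negative"
                )

    def validate_for(self, collection: ModelCollection) -> None:
        """Every medium key must be external in at least one member."""
        allowed = collection.external_metabolite_ids()
        for met_id in self.entries:
            if met_id not in allowed:
                raise MediumError(
                    f"medium metabolite {met_id!r} is not external in any "
                    f"member of collection {collection.name!r}"
                )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "Medium":
        """Read ``metabolite_id<TAB>max_influx`` lines; ``#`` comments allowed."""
        entries: Dict[str, float] = {}
        for lineno, raw in enumerate(
            Path(path).read_text().splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise MediumError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            entries[fields[0]] = float(fields[1])
        return cls(entries=entries)

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = [f"{met}\t{value}" for met, value in self.entries.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def _is_exchange(reaction: Reaction, external_ids: set) -> bool:
    """An exchange reaction touches exactly one metabolite, and it is
    external (the boundary pseudo-reaction ``∅ <-> m``)."""
    if len(reaction.stoichiometry) != 1:
        return False
    (met_id,) = reaction.stoichiometry
    return met_id in external_ids


def apply_medium(
    model: MetabolicModel,
    medium: Medium,
    collection: Optional[ModelCollection] = None,
) -> MetabolicModel:
    """Return a copy of ``model`` constrained to the given medium.

    Every external metabolite is given an exchange reaction (auto-created
    as ``∅ <-> m`` when absent) and brought under mass balance so that the
    exchange flux is the metabolite's net influx.  The import direction is
    capped at the medium value (0 for external metabolites the medium does
    not list); the secretion direction stays unbounded at ``BIG``.

    The exchange map is recorded in ``annotations`` so the operation is
    idempotent and a different medium can later be re-applied to the
    returned model.  The input model is never mutated.
    """
    if collection is not None:
        medium.validate_for(collection)
    out = model.copy()

    exchange_map: Dict[str, List[str]] = {
        met: list(rxns)
        for met, rxns in out.annotations.get(_EXCHANGE_MAP_KEY, {}).items()
    }
    external_ids = {m.id for m in out.external_metabolites}
    if collection is None:
        for met_id in medium.entries:
            if met_id not in external_ids and met_id not in exchange_map:
                raise MediumError(
                    f"medium metabolite {met_id!r} is not external in model "
                    f"{out.id!r}"
                )

    # locate pre-existing exchange reactions for currently-external species
    for rxn in out.reactions:
        if _is_exchange(rxn, external_ids):
            (met_id,) = rxn.stoichiometry
            exchange_map.setdefault(met_id, [])
            if rxn.id not in exchange_map[met_id]:
                exchange_map[met_id].append(rxn.id)

    # auto-create missing exchange reactions (orientation: +1 = import)
    for met_id in sorted(external_ids):
        if met_id not in exchange_map:
            ex_id = f"EX_{met_id}"
            while out.has_reaction(ex_id):
                ex_id += "_ex"
            out.reactions.append(
                Reaction(
                    id=ex_id,
                    stoichiometry={met_id: 1.0},
                    lower_bound=-DEFAULT_BIG,
                    upper_bound=DEFAULT_BIG,
                )
            )
            exchange_map[met_id] = [ex_id]

    # medium-controlled metabolites join the mass balance
    for met in out.metabolites:
        if met.id in exchange_map:
            met.external = False

    for met_id, rxn_ids in exchange_map.items():
        influx = float(medium.entries.get(met_id, 0.0))
        for rid in rxn_ids:
            rxn = out.get_reaction(rid)
            coeff = rxn.stoichiometry[met_id]
            if coeff > 0:  # forward flux imports
                rxn.lower_bound, rxn.upper_bound = -DEFAULT_BIG, influx
            else:  # forward flux exports, reverse imports
                rxn.lower_bound, rxn.upper_bound = -influx, DEFAULT_BIG

    out.annotations[_EXCHANGE_MAP_KEY] = {
        met: list(rxns) for met, rxns in exchange_map.items()
    }
    out.annotations["medium"] = dict(medium.entries)
    return out


def exchange_influx(result: FluxResult, model: MetabolicModel, met_id: str) -> float:
    """Net import flux of a medium metabolite at an optimal solution of a
    medium-applied model."""
    exchange_map = model.annotations.get(_EXCHANGE_MAP_KEY, {})
    if met_id not in exchange_map:
        raise MediumError(
            f"{met_id!r} has no exchange reaction in model {model.id!r}; "
            "apply a medium first"
        )
    total = 0.0
    for rid in exchange_map[met_id]:
        rxn = model.get_reaction(rid)
        coeff = rxn.stoichiometry[met_id]
        flux = result.fluxes[rid]
        total += flux if coeff > 0 else -flux
    return total


@dataclass
class ComparativeResultTable:
    """Batch-FBA results: one row per member, one column per objective.

    Cells hold the optimal flux, or a literal status token
    (``INFEASIBLE``, ``UNBOUNDED``, ``MISSING_OBJECTIVE``) — a failed solve
    is recorded, never silently dropped.
    """

    model_ids: List[str]
    objective_labels: List[str]
    cells: Dict[Tuple[str, str], Union[float, str]]

    def to_frame(self) -> pd.DataFrame:
        data = {
            label: [self.cells[(mid, label)] for mid in self.model_ids]
            for label in self.objective_labels
        }
        return pd.DataFrame(data, index=pd.Index(self.model_ids, name="model"))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ComparativeResultTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        cells: Dict[Tuple[str, str], Union[float, str]] = {}
        for mid in frame.index:
            for label in frame.columns:
                value = frame.loc[mid, label]
                try:
                    cells[(str(mid), str(label))] = float(value)
                except (TypeError, ValueError):
                    cells[(str(mid), str(label))] = str(value)
        return cls(
            model_ids=[str(i) for i in frame.index],
            objective_labels=[str(c) for c in frame.columns],
            cells=cells,
        )


def _normalize_objectives(
    collection: ModelCollection,
    objectives: Union[str, Mapping[str, str], Mapping[str, Mapping[str, str]]],
) -> Dict[str, Dict[str, str]]:
    """Normalize the objective spec to {column label: {model id: reaction id}}.

    Accepts a single reaction id common to all members, a per-member map
    (one column), or a map of column label -> (reaction id | per-member map).
    """
    member_ids = collection.member_ids()
    if isinstance(objectives, str):
        return {objectives: {mid: objectives for mid in member_ids}}
    first_value = next(iter(objectives.values()), None)
    if isinstance(first_value, str) and set(objectives) <= set(member_ids):
        label = "objective"
        return {label: {mid: objectives[mid] for mid in member_ids if mid in objectives}}
    out: Dict[str, Dict[str, str]] = {}
    for label, spec in objectives.items():
        if isinstance(spec, str):
            out[label] = {mid: spec for mid in member_ids}
        else:
            out[label] = dict(spec)
    return out


def batch_fba(
    collection: ModelCollection,
    objectives: Union[str, Mapping[str, str], Mapping[str, Mapping[str, str]]],
    medium: Optional[Medium] = None,
    sense: str = "maximize",
) -> ComparativeResultTable:
    """One FBA solve per member under a shared medium, tabulated together.

    Row order follows the collection order.  A member whose objective
    reaction is absent yields the ``MISSING_OBJECTIVE`` token, not an
    exception; infeasible or unbounded solves likewise record their status.
    """
    if medium is not None:
        medium.validate_for(collection)
    objective_map = _normalize_objectives(collection, objectives)
    cells: Dict[Tuple[str, str], Union[float, str]] = {}
    for member in collection.members:
        prepared = (
            apply_medium(member, medium, collection) if medium is not None else member
        )
        for label, per_member in objective_map.items():
            rxn_id = per_member.get(member.id)
            if rxn_id is None or not prepared.has_reaction(rxn_id):
                cells[(member.id, label)] = MISSING_OBJECTIVE
                continue
            result = solve_fba(prepared, rxn_id, sense=sense)
            if result.optimal:
                cells[(member.id, label)] = result.objective_value
            else:
                cells[(member.id, label)] = result.status.value
    return ComparativeResultTable(
        model_ids=collection.member_ids(),
        objective_labels=list(objective_map),
        cells=cells,
    )


def relative_flux_matrix(table: ComparativeResultTable) -> pd.DataFrame:
    """Scale each column to percent of its own maximum (heat-map input).

    Status cells are treated as absent (NaN).  An all-zero column maps to
    all zeros rather than NaN so the matrix stays plottable; a column's
    maximum maps to exactly 100.
    """
    frame = table.to_frame()
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    out = pd.DataFrame(index=numeric.index, columns=numeric.columns, dtype=float)
    for col in numeric.columns:
        column = numeric[col]
        top = column.max(skipna=True)
        if pd.isna(top) or top == 0:
            out[col] = column.where(column.isna(), 0.0)
        else:
            out[col] = 100.0 * column / top
            # the maximal cell is exactly 100, immune to division round-off
            out.loc[column == top, col] = 100.0
    return out


def presence_flux_correlation(
    collection: ModelCollection,
    flux_column: Mapping[str, float],
) -> pd.DataFrame:
    """Squared Pearson correlation between reaction presence/absence and the
    per-model maximal flux.

    For every reaction id occurring in at least one member, presence is
    coded 0/1 across members and correlated with ``flux_column``.  Reactions
    present in every member (zero presence variance) — or a constant flux
    column — yield an undefined r², reported as NaN rather than dropped.
    Rows are sorted by r² descending, ties broken by reaction id; columns
    are ``reaction_id``, ``r_squared``, ``n_present``.
    """
    member_ids = collection.member_ids()
    if len(member_ids) < 3:
        raise StatisticsError(
            "presence/flux correlation needs at least 3 members"
        )
    missing = [mid for mid in member_ids if mid not in flux_column]
    if missing:
        raise StatisticsError(f"flux column lacks members: {missing}")
    fluxes = np.array([float(flux_column[mid]) for mid in member_ids])

    all_reactions: List[str] = []
    seen: set = set()
    for member in collection.members:
        for rid in member.reaction_ids():
            if rid not in seen:
                seen.add(rid)
                all_reactions.append(rid)

    rows = []
    flux_var = float(np.var(fluxes))
    for rid in all_reactions:
        presence = np.array(
            [1.0 if collection.get(mid).has_reaction(rid) else 0.0 for mid in member_ids]
        )
        n_present = int(presence.sum())
        if presence.var() == 0 or flux_var == 0:
            r2 = math.nan
        else:
            r = np.corrcoef(presence, fluxes)[0, 1]
            r2 = float(r * r)
        rows.append((rid, r2, n_present))

    frame = pd.DataFrame(rows, columns=["reaction_id", "r_squared", "n_present"])
    frame = frame.sort_values(
        by=["r_squared", "reaction_id"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return frame


def write_correlation_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the correlation table with ``NA`` for undefined r²."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
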