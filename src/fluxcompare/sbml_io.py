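"""Dialect-tolerant SBML reading and the native tabular model format.

SBML Level 2 has no canonical place for FBA data (flux bounds, gene rules),
so every modelling platform invented its own convention:

* **COBRA**-generated files carry bounds as kinetic-law parameters named
  ``LOWER_BOUND``/``UPPER_BOUND`` and gene rules in ``GENE_ASSOCIATION``
  notes.
* **SEED**-generated files use ``rxnNNNNN``/``cpdNNNNN`` identifiers and a
  ``_b`` suffix on boundary species; they encode no explicit bounds.
* **KGML**-derived files (SBML exported from KEGG pathway XML) use KEGG
  R-numbers and carry no bounds information at all.

:func:`parse_sbml` detects the dialect and normalizes all of them into the
same :class:`~fluxcompare.model.MetabolicModel`, so that heterogeneous
collections can be compared on equal footing.  SBML Level 3 files with the
``fbc`` package are accepted read-only through the same normalization.

The native format is a line-oriented TSV: directive lines starting with
``#`` declare the model id and metabolites, then one reaction per line with
a human-readable equation (``2 a + b -> c`` or ``a <-> b``).
"""

from __future__ import annotations

import enum
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import libsbml

from .errors import FormatError, StructuralError
from .model import DEFAULT_BIG, MetabolicModel, Metabolite, Reaction

__all__ = [
    "Dialect",
    "detect_dialect",
    "parse_sbml",
    "read_native",
    "write_native",
    "format_equation",
    "parse_equation",
]


class Dialect(str, enum.Enum):
    """Recognized SBML flavours; exactly one is assigned per file."""

    SEED = "SEED"
    COBRA = "COBRA"
    KGML = "KGML"
    GENERIC = "GENERIC"


_SEED_RXN = re.compile(r"^(R_)?rxn\d{5}")
_SEED_CPD = re.compile(r"^(M_)?cpd\d{5}")
_KEGG_RXN = re.compile(r"^(R_)?R\d{5}$")


def _kinetic_parameters(reaction: libsbml.Reaction) -> Dict[str, float]:
    params: Dict[str, float] = {}
    law = reaction.getKineticLaw()
    if law is None:
        return params
    for i in range(law.getNumParameters()):
        p = law.getParameter(i)
        params[p.getId()] = p.getValue()
    for i in range(law.getNumLocalParameters()):
        p = law.getLocalParameter(i)
        params[p.getId()] = p.getValue()
    return params


def _notes_text(element) -> str:
    notes = element.getNotesString() if element.isSetNotes() else ""
    return notes or ""


def _gene_association(reaction: libsbml.Reaction) -> Optional[str]:
    notes = _notes_text(reaction)
    match = re.search(
        r"GENE[_ ]ASSOCIATION\s*:\s*([^<\n]*)", notes, flags=re.IGNORECASE
    )
    if match:
        value = match.group(1).strip()
        return value or None
    return None


def detect_dialect(document: libsbml.SBMLDocument) -> Dialect:
    """Classify a parsed SBML document into one of the four dialects.

    Precedence COBRA > SEED > KGML > GENERIC: explicit bound encoding is the
    strongest signal, identifier namespaces the next, and the total absence
    of bounds plus KEGG R-numbers the weakest.
    """
    sbml_model = document.getModel()
    if sbml_model is None:
        raise FormatError("SBML document contains no model element")

    has_bound_params = False
    has_gene_notes = False
    any_kegg_ids = len(sbml_model.getListOfReactions()) > 0
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        params = _kinetic_parameters(rxn)
        if "LOWER_BOUND" in params or "UPPER_BOUND" in params:
            has_bound_params = True
        if "GENE_ASSOCIATION" in _notes_text(rxn).upper().replace(" ", "_"):
            has_gene_notes = True
        if not _KEGG_RXN.match(rxn.getId() or ""):
            any_kegg_ids = False
    if has_bound_params or has_gene_notes:
        return Dialect.COBRA

    seed_rxn = any(
        _SEED_RXN.match(sbml_model.getReaction(i).getId() or "")
        for i in range(sbml_model.getNumReactions())
    )
    seed_cpd = any(
        _SEED_CPD.match(sbml_model.getSpecies(i).getId() or "")
        for i in range(sbml_model.getNumSpecies())
    )
    if seed_rxn or seed_cpd:
        return Dialect.SEED

    if any_kegg_ids and not has_bound_params:
        return Dialect.KGML
    return Dialect.GENERIC


def _read_document(path: Union[str, Path]) -> libsbml.SBMLDocument:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    document = libsbml.readSBMLFromFile(str(path))
    fatal = [
        document.getError(i)
        for i in range(document.getNumErrors())
        if document.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if fatal:
        first = fatal[0]
        raise FormatError(
            f"{path}:{first.getLine()}: {first.getMessage().strip()}"
        )
    return document


def _species_is_external(
    species: libsbml.Species, sbml_model: libsbml.Model, dialect: Dialect
) -> bool:
    if species.getBoundaryCondition():
        return True
    comp_id = species.getCompartment() or ""
    compartment = sbml_model.getCompartment(comp_id)
    comp_name = compartment.getName() if compartment is not None else ""
    if comp_id == "e" or comp_id.endswith("_b"):
        return True
    if "extra" in (comp_name or "").lower():
        return True
    if dialect is Dialect.SEED and (species.getId() or "").endswith("_b"):
        return True
    return False


def _fbc_bounds(
    reaction: libsbml.Reaction, sbml_model: libsbml.Model
) -> Optional[Tuple[float, float]]:
    plugin = reaction.getPlugin("fbc")
    if plugin is None:
        return None
    lo = hi = None
    if plugin.isSetLowerFluxBound():
        p = sbml_model.getParameter(plugin.getLowerFluxBound())
        if p is not None:
            lo = p.getValue()
    if plugin.isSetUpperFluxBound():
        p = sbml_model.getParameter(plugin.getUpperFluxBound())
        if p is not None:
            hi = p.getValue()
    if lo is None and hi is None:
        return None
    lo = -DEFAULT_BIG if lo is None else lo
    hi = DEFAULT_BIG if hi is None else hi
    return (max(lo, -DEFAULT_BIG), min(hi, DEFAULT_BIG))


def parse_sbml(path: Union[str, Path]) -> MetabolicModel:
    """Parse an SBML file of any supported dialect into a normalized model.

    Bounds come from kinetic-law parameters when present; otherwise the
    ``reversible`` attribute maps to ``[-BIG, BIG]`` (reversible) or
    ``[0, BIG]`` (irreversible) with ``BIG = 10000``.  A species is external
    iff it has ``boundaryCondition="true"``, sits in an extracellular
    compartment (id ``e``, id suffix ``_b``, or name containing "extra"),
    or — in SEED files — its id carries the ``_b`` boundary suffix.
    """
    document = _read_document(path)
    dialect = detect_dialect(document)
    sbml_model = document.getModel()

    metabolites: List[Metabolite] = []
    declared: set = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = sp.getId()
        if sid in declared:
            raise StructuralError(f"duplicate species id {sid!r} in {path}")
        declared.add(sid)
        metabolites.append(
            Metabolite(
                id=sid,
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                external=_species_is_external(sp, sbml_model, dialect),
            )
        )

    reactions: List[Reaction] = []
    seen_rxn: set = set()
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        if rid in seen_rxn:
            raise StructuralError(f"duplicate reaction id {rid!r} in {path}")
        seen_rxn.add(rid)

        stoich: Dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            sid = ref.getSpecies()
            if sid not in declared:
                raise StructuralError(
                    f"reaction {rid!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) - (ref.getStoichiometry() or 1.0)
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            sid = ref.getSpecies()
            if sid not in declared:
                raise StructuralError(
                    f"reaction {rid!r} references undeclared species {sid!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
        stoich = {m: c for m, c in stoich.items() if c != 0}

        params = _kinetic_parameters(rxn)
        fbc = _fbc_bounds(rxn, sbml_model)
        if "LOWER_BOUND" in params or "UPPER_BOUND" in params:
            default_lo = -DEFAULT_BIG if rxn.getReversible() else 0.0
            lo = params.get("LOWER_BOUND", default_lo)
            hi = params.get("UPPER_BOUND", DEFAULT_BIG)
        elif fbc is not None:
            lo, hi = fbc
        elif rxn.getReversible():
            lo, hi = -DEFAULT_BIG, DEFAULT_BIG
        else:
            lo, hi = 0.0, DEFAULT_BIG
        if lo > hi:
            raise StructuralError(
                f"reaction {rid!r}: lower bound {lo} exceeds upper bound {hi}"
            )
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lo,
                upper_bound=hi,
                name=rxn.getName() or "",
                gene_association=_gene_association(rxn),
            )
        )

    model = MetabolicModel(
        id=sbml_model.getId() or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        name=sbml_model.getName() or "",
        provenance=dialect.value,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Native tabular format
# ---------------------------------------------------------------------------


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _format_coeff_term(metabolite_id: str, coeff: float) -> str:
    if coeff == 1:
        return metabolite_id
    return f"{_format_number(coeff)} {metabolite_id}"


def format_equation(reaction: Reaction) -> str:
    """Render a reaction's stoichiometry as ``2 a + b -> c`` (or ``<->``)."""
    left = [
        _format_coeff_term(m, -c)
        for m, c in reaction.stoichiometry.items()
        if c < 0
    ]
    right = [
        _format_coeff_term(m, c)
        for m, c in reaction.stoichiometry.items()
        if c > 0
    ]
    arrow = "<->" if reaction.reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


def parse_equation(text: str) -> Dict[str, float]:
    """Parse the equation grammar back into a signed stoichiometry map."""
    if "<->" in text:
        left_text, right_text = text.split("<->", 1)
    elif "->" in text:
        left_text, right_text = text.split("->", 1)
    else:
        raise FormatError(f"equation lacks an arrow: {text!r}")

    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise FormatError(f"bad coefficient in term {term!r}") from exc
                met = parts[1]
            else:
                raise FormatError(f"unparseable term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left_text, -1.0)
    add_side(right_text, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}


def write_native(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the tab-separated native format.

    Layout: a ``#MODEL`` directive, one ``#METABOLITE`` directive per
    declared metabolite (preserving order), a ``#EXTERNAL`` directive
    listing boundary species, then one reaction per line:
    ``id<TAB>equation<TAB>lower<TAB>upper<TAB>gene_association``.
    """
    lines: List[str] = []
    lines.append(f"#MODEL\t{model.id}")
    for m in model.metabolites:
        lines.append(f"#METABOLITE\t{m.id}\t{'external' if m.external else 'internal'}")
    externals = ",".join(m.id for m in model.external_metabolites)
    lines.append(f"#EXTERNAL\t{externals}")
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    _format_number(r.lower_bound),
                    _format_number(r.upper_bound),
                    r.gene_association or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_native(path: Union[str, Path]) -> MetabolicModel:
    """Read the native tabular format back into a model.

    ``write_native`` followed by ``read_native`` reproduces the model
    exactly (ordering included).  Files written by hand may omit the
    ``#METABOLITE`` directives, in which case metabolites are inferred from
    equations in first-use order and the ``#EXTERNAL`` directive marks the
    boundary species.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    model_id = path.stem
    declared: List[Metabolite] = []
    declared_ids: set = set()
    external_ids: set = set()
    reactions: List[Reaction] = []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.split("\t")
            directive = fields[0].lstrip("#").strip().upper()
            if directive == "MODEL" and len(fields) > 1:
                model_id = fields[1]
            elif directive == "METABOLITE":
                if len(fields) < 2 or not fields[1]:
                    raise FormatError(f"{path}:{lineno}: bad #METABOLITE line")
                ext = len(fields) > 2 and fields[2].strip() == "external"
                declared.append(Metabolite(id=fields[1], external=ext))
                declared_ids.add(fields[1])
                if ext:
                    external_ids.add(fields[1])
            elif directive == "EXTERNAL":
                if len(fields) > 1 and fields[1].strip():
                    external_ids.update(
                        m.strip() for m in fields[1].split(",") if m.strip()
                    )
            # other comment lines are ignored
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected at least 4 tab-separated fields"
            )
        rid, equation, lo_text, hi_text = fields[:4]
        gene = fields[4] if len(fields) > 4 and fields[4] else None
        try:
            lo, hi = float(lo_text), float(hi_text)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad bounds") from exc
        try:
            stoich = parse_equation(equation)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        for met_id in stoich:
            if met_id not in declared_ids:
                declared.append(
                    Metabolite(id=met_id, external=met_id in external_ids)
                )
                declared_ids.add(met_id)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lo,
                upper_bound=hi,
                gene_association=gene,
            )
        )

    for m in declared:
        m.external = m.id in external_ids
    model = MetabolicModel(
        id=model_id,
        metabolites=declared,
        reactions=reactions,
        provenance="native",
    )
    model.validate()
    return model
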