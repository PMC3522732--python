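"""Synthetic SBML Level 2 emitters, one per dialect flavour.

These writers exist only to exercise the dialect-tolerant parser; they are
not part of the library API.  Each takes a MetabolicModel and renders the
conventions of one source platform:

* ``cobra``  — kinetic-law LOWER_BOUND/UPPER_BOUND parameters and
  GENE_ASSOCIATION notes;
* ``seed``   — rxnNNNNN / cpdNNNNN identifiers, ``_b`` boundary suffix,
  no bounds anywhere;
* ``kgml``   — KEGG R-number reaction ids, no bounds anywhere;
* ``generic``— plain SBML with only the reversible flag.

Each emitter returns the identifier maps (original -> emitted) so tests can
locate objectives after parsing.
"""

from pathlib import Path
from xml.sax.saxutils import escape


def _species_xml(sid, compartment, boundary):
    battr = ' boundaryCondition="true"' if boundary else ""
    return (
        f'      <species id="{escape(sid)}" name="{escape(sid)}" '
        f'compartment="{compartment}"{battr} initialAmount="0"/>'
    )


def _reference_xml(sid, coeff):
    return (
        f'          <speciesReference species="{escape(sid)}" '
        f'stoichiometry="{abs(coeff):g}"/>'
    )


def _kinetic_law_xml(lower, upper):
    return f"""        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML"><ci> FLUX_VALUE </ci></math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="{lower:g}" units="dimensionless"/>
            <parameter id="UPPER_BOUND" value="{upper:g}" units="dimensionless"/>
            <parameter id="FLUX_VALUE" value="0" units="dimensionless"/>
          </listOfParameters>
        </kineticLaw>"""


def _notes_xml(gene_association):
    return f"""        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: {escape(gene_association)}</p>
          </body>
        </notes>"""


def emit_sbml(model, path, flavor, boundary_attr=True):
    """Write ``model`` to ``path`` in the given dialect flavour.

    Returns ``(metabolite_map, reaction_map)`` of original -> emitted ids.
    ``boundary_attr=False`` suppresses the boundaryCondition attribute (the
    SEED flavour then signals externality only via the ``_b`` id suffix).
    """
    met_map = {}
    rxn_map = {}
    if flavor == "seed":
        for i, met in enumerate(model.metabolites, start=1):
            suffix = "_b" if met.external else ""
            met_map[met.id] = f"cpd{i:05d}{suffix}"
        for i, rxn in enumerate(model.reactions, start=1):
            rxn_map[rxn.id] = f"rxn{i:05d}"
    elif flavor == "kgml":
        for i, met in enumerate(model.metabolites, start=1):
            met_map[met.id] = f"C{i:05d}"
        for i, rxn in enumerate(model.reactions, start=1):
            rxn_map[rxn.id] = f"R{i:05d}"
    else:  # cobra / generic keep ids
        met_map = {m.id: m.id for m in model.metabolites}
        rxn_map = {r.id: r.id for r in model.reactions}

    species_lines = []
    for met in model.metabolites:
        compartment = "c"
        boundary = met.external and (boundary_attr or flavor != "seed")
        species_lines.append(
            _species_xml(met_map[met.id], compartment, boundary)
        )

    reaction_blocks = []
    for rxn in model.reactions:
        reactants = [
            _reference_xml(met_map[m], c)
            for m, c in rxn.stoichiometry.items()
            if c < 0
        ]
        products = [
            _reference_xml(met_map[m], c)
            for m, c in rxn.stoichiometry.items()
            if c > 0
        ]
        reversible = "true" if rxn.lower_bound < 0 else "false"
        parts = [
            f'      <reaction id="{escape(rxn_map[rxn.id])}" '
            f'reversible="{reversible}">'
        ]
        if flavor == "cobra":
            parts.append(_notes_xml(rxn.gene_association or "unknown"))
        if reactants:
            parts.append("        <listOfReactants>")
            parts.extend(reactants)
            parts.append("        </listOfReactants>")
        if products:
            parts.append("        <listOfProducts>")
            parts.extend(products)
            parts.append("        </listOfProducts>")
        if flavor == "cobra":
            parts.append(_kinetic_law_xml(rxn.lower_bound, rxn.upper_bound))
        parts.append("      </reaction>")
        reaction_blocks.append("\n".join(parts))

    document = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
  <model id="{escape(model.id)}">
    <listOfCompartments>
      <compartment id="c"/>
    </listOfCompartments>
    <listOfSpecies>
{chr(10).join(species_lines)}
    </listOfSpecies>
    <listOfReactions>
{chr(10).join(reaction_blocks)}
    </listOfReactions>
  </model>
</sbml>
"""
    Path(path).write_text(document)
    return met_map, rxn_map
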