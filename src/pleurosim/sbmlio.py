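"""SBML Level 2 Version 4 reader/writer for the model schema.

This is a self-contained implementation of the SBML subset the package
needs: compartments, species (with initial amounts and boundary
conditions), reactions with stoichiometric reactant/product references,
modifier species references, and kinetic laws as content MathML with
local parameters.  Species roles (gene, mRNA, protein, ...), modifier
modes and compartment kinds have no core-SBML representation, so they are
stored in a namespaced annotation block (and the modifier mode
additionally as an SBO term); the reader prefers the annotation.

Round-trip guarantee: ``read_sbml(write_sbml(m))`` equals ``m`` on every
schema field.  Constructs outside the subset (events, rules, function
definitions) are rejected with their location.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

from lxml import etree

from .core import (
    Compartment,
    CompartmentKind,
    Model,
    Modifier,
    ModifierMode,
    Reaction,
    Species,
    SpeciesRole,
    require_valid,
)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
#: annotation namespace for schema fields core SBML cannot express
PS_NS = "urn:pleurosim:annotations"

_NSMAP = {None: SBML_NS, "ps": PS_NS}

#: SBO terms for modifier modes (catalysis / inhibition / stimulation)
_SBO_BY_MODE = {
    ModifierMode.catalyst: "SBO:0000013",
    ModifierMode.inhibitor: "SBO:0000020",
    ModifierMode.activator: "SBO:0000459",
}

_UNSUPPORTED = {
    "listOfRules", "listOfEvents", "listOfConstraints",
    "listOfFunctionDefinitions", "listOfInitialAssignments",
}


class SBMLReadError(ValueError):
    """Unreadable or unsupported SBML content, with location."""


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def _annotate(parent: etree._Element, **fields: str) -> None:
    ann = etree.SubElement(parent, _q("annotation"))
    for key, value in fields.items():
        el = etree.SubElement(ann, _q(key, PS_NS))
        el.text = value


def _read_annotation(element: etree._Element, key: str) -> Optional[str]:
    hits = element.findall(f"{_q('annotation')}/{_q(key, PS_NS)}")
    return hits[0].text if hits else None


def write_sbml(
    model: Model,
    rate_laws: Optional[Mapping[str, "RateLaw"]] = None,  # noqa: F821
) -> str:
    """Serialize a model (and optionally its rate laws) to SBML L2V4 text."""
    require_valid(model)
    root = etree.Element(_q("sbml"), nsmap=_NSMAP, level="2", version="4")
    mdl = etree.SubElement(root, _q("model"), id=model.id)
    if model.name:
        mdl.set("name", model.name)

    locs = etree.SubElement(mdl, _q("listOfCompartments"))
    for c in model.compartments:
        el = etree.SubElement(locs, _q("compartment"), id=c.id, name=c.name, size="1")
        _annotate(el, kind=c.kind.value)

    loss = etree.SubElement(mdl, _q("listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(loss, _q("species"), id=s.id, name=s.name, compartment=s.compartment)
        if s.initial_amount is not None:
            el.set("initialAmount", repr(float(s.initial_amount)))
        if s.constant:
            el.set("boundaryCondition", "true")
            el.set("constant", "true")
        _annotate(el, role=s.role.value)

    lorx = etree.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        el = etree.SubElement(lorx, _q("reaction"), id=r.id, name=r.name,
                              reversible="true" if r.reversible else "false")
        if r.annotation:
            _annotate(el, note=r.annotation)
        if r.reactants:
            lo = etree.SubElement(el, _q("listOfReactants"))
            for sid, n in r.reactants:
                etree.SubElement(lo, _q("speciesReference"), species=sid, stoichiometry=str(n))
        if r.products:
            lo = etree.SubElement(el, _q("listOfProducts"))
            for sid, n in r.products:
                etree.SubElement(lo, _q("speciesReference"), species=sid, stoichiometry=str(n))
        if r.modifiers:
            lo = etree.SubElement(el, _q("listOfModifiers"))
            for m in r.modifiers:
                msr = etree.SubElement(lo, _q("modifierSpeciesReference"), species=m.species)
                msr.set("sboTerm", _SBO_BY_MODE[m.mode])
                _annotate(msr, mode=m.mode.value)
        if rate_laws and r.id in rate_laws:
            from .kinetics import render_expression

            law = rate_laws[r.id]
            kl = etree.SubElement(el, _q("kineticLaw"))
            math = etree.fromstring(render_expression(law, "mathml").encode())
            kl.append(math)
            lop = etree.SubElement(kl, _q("listOfParameters"))
            for pname, pval in sorted(law.parameters.items()):
                etree.SubElement(lop, _q("parameter"), id=pname, value=repr(float(pval)))

    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()


def _species_from_element(el: etree._Element) -> Species:
    sid = el.get("id")
    role_text = _read_annotation(el, "role") or SpeciesRole.simple_molecule.value
    init = el.get("initialAmount")
    return Species(
        id=sid,
        name=el.get("name", sid),
        role=SpeciesRole(role_text),
        compartment=el.get("compartment", ""),
        initial_amount=None if init is None else float(init),
        constant=el.get("boundaryCondition") == "true",
    )


def read_sbml(source: Union[str, Path]) -> Model:
    """Parse SBML L2V4 text (or a file path) back into a :class:`Model`.

    Raises :class:`SBMLReadError` for unsupported constructs or dangling
    references, naming the offending element.
    """
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".xml")):
        text = Path(source).read_text()
    try:
        root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    except etree.XMLSyntaxError as exc:
        raise SBMLReadError(f"not well-formed XML: {exc}") from exc
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SBMLReadError("no <model> element")
    for child in mdl:
        tag = etree.QName(child).localname if isinstance(child.tag, str) else ""
        if tag in _UNSUPPORTED:
            raise SBMLReadError(f"unsupported SBML construct <{tag}>")

    compartments = []
    for el in mdl.findall(f"{_q('listOfCompartments')}/{_q('compartment')}"):
        kind = _read_annotation(el, "kind") or CompartmentKind.other.value
        compartments.append(Compartment(el.get("id"), el.get("name", el.get("id")), CompartmentKind(kind)))
    comp_ids = {c.id for c in compartments}

    species = []
    for el in mdl.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        s = _species_from_element(el)
        if s.compartment not in comp_ids:
            raise SBMLReadError(
                f"species {s.id!r} references undefined compartment {s.compartment!r}"
            )
        species.append(s)

    reactions = []
    for el in mdl.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        rid = el.get("id")

        def refs(list_tag: str) -> tuple[tuple[str, int], ...]:
            out = []
            for ref in el.findall(f"{_q(list_tag)}/{_q('speciesReference')}"):
                stoich = ref.get("stoichiometry", "1")
                out.append((ref.get("species"), int(float(stoich))))
            return tuple(out)

        modifiers = []
        for msr in el.findall(f"{_q('listOfModifiers')}/{_q('modifierSpeciesReference')}"):
            mode = _read_annotation(msr, "mode")
            if mode is None:
                sbo = msr.get("sboTerm", "")
                by_sbo = {v: k for k, v in _SBO_BY_MODE.items()}
                mode = by_sbo.get(sbo, ModifierMode.catalyst).value
            modifiers.append(Modifier(msr.get("species"), ModifierMode(mode)))

        reactions.append(
            Reaction(
                id=rid,
                name=el.get("name", rid),
                reactants=refs("listOfReactants"),
                products=refs("listOfProducts"),
                modifiers=tuple(modifiers),
                reversible=el.get("reversible", "true") == "true",
                annotation=_read_annotation(el, "note") or "",
            )
        )

    return Model(
        id=mdl.get("id", "model"),
        name=mdl.get("name", ""),
        compartments=compartments,
        species=species,
        reactions=reactions,
    )


def read_kinetic_laws(source: Union[str, Path]) -> dict[str, "sympy.Expr"]:  # noqa: F821
    """Extract kinetic-law expressions (parameters substituted) from SBML."""
    from .kinetics import parse_content_mathml
    import sympy as sp

    text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
    root = etree.fromstring(text.encode())
    out: dict[str, sp.Expr] = {}
    for el in root.findall(f"{_q('model')}/{_q('listOfReactions')}/{_q('reaction')}"):
        kl = el.find(_q("kineticLaw"))
        if kl is None:
            continue
        math = kl.find(f"{{{MATHML_NS}}}math")
        if math is None:
            continue
        expr = parse_content_mathml(etree.tostring(math).decode())
        params = {
            sp.Symbol(p.get("id")): sp.Float(p.get("value"))
            for p in kl.findall(f"{_q('listOfParameters')}/{_q('parameter')}")
        }
        out[el.get("id")] = expr.xreplace(params)
    return out
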