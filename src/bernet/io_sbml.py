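"""SBML core import/export for Petri nets.

A qualitative Petri net maps onto SBML core level 3 in the conventional
way: species are places (initialAmount = marking), reactions are
transitions, and integer stoichiometries are arc weights.  Only this
stoichiometric subset is read — kinetic laws, compartment semantics and
units are ignored; reversible reactions are rejected because net
transitions are directed.  Written documents round-trip through
:func:`read_sbml` / :func:`write_sbml` losslessly.
"""

from __future__ import annotations

from lxml import etree

from .net import Arc, PetriNet, Place, Transition

__all__ = ["read_sbml", "write_sbml", "SBMLError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"


class SBMLError(ValueError):
    """Malformed or unsupported SBML content."""


def _int_stoich(value: str, where: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise SBMLError(f"non-numeric stoichiometry in {where}: {value!r}") from None
    if f != int(f) or f <= 0:
        raise SBMLError(f"non-positive-integer stoichiometry in {where}: {value!r}")
    return int(f)


def read_sbml(source) -> PetriNet:
    """Parse an SBML file or string into a :class:`PetriNet`."""
    try:
        if hasattr(source, "read") or (isinstance(source, str) and "<" not in source):
            tree = etree.parse(source)
            root = tree.getroot()
        else:
            root = etree.fromstring(
                source.encode() if isinstance(source, str) else source
            )
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLError(f"cannot parse SBML input: {exc}") from exc

    ns = root.nsmap.get(None, SBML_NS)
    def q(tag):
        return f"{{{ns}}}{tag}"

    model = root.find(q("model"))
    if model is None:
        raise SBMLError("no <model> element found")

    places, marking = [], {}
    for sp in model.iterfind(f"{q('listOfSpecies')}/{q('species')}"):
        sid = sp.get("id")
        if sid is None:
            raise SBMLError("species without id")
        places.append(Place(sid, sp.get("name", sid)))
        amount = sp.get("initialAmount")
        if amount not in (None, ""):
            f = float(amount)
            if f != int(f) or f < 0:
                raise SBMLError(f"species {sid}: marking must be a nonnegative integer")
            if int(f):
                marking[sid] = int(f)

    known = {p.id for p in places}
    transitions, arcs = [], []
    for rx in model.iterfind(f"{q('listOfReactions')}/{q('reaction')}"):
        rid = rx.get("id")
        if rid is None:
            raise SBMLError("reaction without id")
        if rx.get("reversible", "false").lower() == "true":
            raise SBMLError(f"reaction {rid} is reversible; net transitions are directed")
        transitions.append(Transition(rid, rx.get("name", rid)))
        for ref in rx.iterfind(f"{q('listOfReactants')}/{q('speciesReference')}"):
            species = ref.get("species")
            if species not in known:
                raise SBMLError(f"reaction {rid} references unknown species {species!r}")
            arcs.append(Arc(species, rid, _int_stoich(ref.get("stoichiometry", "1"), rid)))
        for ref in rx.iterfind(f"{q('listOfProducts')}/{q('speciesReference')}"):
            species = ref.get("species")
            if species not in known:
                raise SBMLError(f"reaction {rid} references unknown species {species!r}")
            arcs.append(Arc(rid, species, _int_stoich(ref.get("stoichiometry", "1"), rid)))

    return PetriNet(places, transitions, arcs, initial_marking=marking,
                    name=model.get("name", model.get("id", "")))


def write_sbml(net: PetriNet, path=None) -> str:
    """Serialise ``net`` as SBML core L3V1; returns the XML text."""
    root = etree.Element("sbml", nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, "model")
    model.set("id", (net.name or "petri_net").replace(" ", "_"))
    if net.name:
        model.set("name", net.name)
    comp_list = etree.SubElement(model, "listOfCompartments")
    comp = etree.SubElement(comp_list, "compartment")
    comp.set("id", "default")
    comp.set("constant", "true")

    sp_list = etree.SubElement(model, "listOfSpecies")
    for p, tokens in zip(net.places, net.initial_marking):
        sp = etree.SubElement(sp_list, "species")
        sp.set("id", p.id)
        if p.label and p.label != p.id:
            sp.set("name", p.label)
        sp.set("compartment", "default")
        sp.set("initialAmount", str(int(tokens)))
        sp.set("hasOnlySubstanceUnits", "true")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    pre, post = net.pre_matrix(), net.post_matrix()
    rx_list = etree.SubElement(model, "listOfReactions")
    for t in net.transitions:
        rx = etree.SubElement(rx_list, "reaction")
        rx.set("id", t.id)
        if t.label and t.label != t.id:
            rx.set("name", t.label)
        rx.set("reversible", "false")
        j = t.index
        reactants = [(p, int(pre[p.index, j])) for p in net.places if pre[p.index, j]]
        products = [(p, int(post[p.index, j])) for p in net.places if post[p.index, j]]
        if reactants:
            lst = etree.SubElement(rx, "listOfReactants")
            for p, w in reactants:
                ref = etree.SubElement(lst, "speciesReference")
                ref.set("species", p.id)
                ref.set("stoichiometry", str(w))
                ref.set("constant", "true")
        if products:
            lst = etree.SubElement(rx, "listOfProducts")
            for p, w in products:
                ref = etree.SubElement(lst, "speciesReference")
                ref.set("species", p.id)
                ref.set("stoichiometry", str(w))
                ref.set("constant", "true")

    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
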