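"""SBML export/import of pathways with embedded GlycoCT annotations.

Pathways are written as SBML Level 2 Version 4 documents.  Each glycan
species carries its structure inside the ``annotation`` element as::

    <annotation>
      <glycoct xmlns="http://www.eurocarbdb.org/recommendations/encoding">
        <sugar version="1.0">
          <residues>...GlycoCT RES lines...</residues>
          <linkages>...GlycoCT LIN lines...</linkages>
        </sugar>
      </glycoct>
    </annotation>

Species ids are deterministic (``gly_`` + truncated SHA-1 of the canonical
string) so export/import round trips are stable.  Enzymes appear both as
boundary "modifier" species and as an attribute on each reaction's
annotation.
"""

from __future__ import annotations

import hashlib
import re

from lxml import etree

from .glycan import Glycan
from .glycoct import parse_glycoct, write_glycoct
from .network import Pathway
from .reactions import Rxn

__all__ = ["export_sbml", "import_sbml", "SbmlError", "GLYCOCT_NS", "species_id"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
GLYCOCT_NS = "http://www.eurocarbdb.org/recommendations/encoding"
GNET_NS = "https://glyconet.invalid/sbml"


class SbmlError(ValueError):
    pass


def species_id(g: Glycan | str) -> str:
    key = g.canonical if isinstance(g, Glycan) else g
    return "gly_" + hashlib.sha1(key.encode()).hexdigest()[:10]


def _enzyme_id(name: str) -> str:
    return "enz_" + re.sub(r"[^A-Za-z0-9]", "_", name)


def export_sbml(p: Pathway, path) -> None:
    """Write a pathway to an SBML file."""
    E = lambda tag, parent, **attrs: etree.SubElement(parent, f"{{{SBML_NS}}}{tag}", **attrs)
    root = etree.Element(
        f"{{{SBML_NS}}}sbml",
        level="2",
        version="4",
        nsmap={None: SBML_NS, "gnet": GNET_NS},
    )
    model = E("model", root, id="glycosylation_pathway")
    compartments = E("listOfCompartments", model)
    E("compartment", compartments, id="cell", size="1")
    species_list = E("listOfSpecies", model)
    enzymes = sorted({r.enzyme for r in p.reactions.values()})
    for key in sorted(p.species):
        g = p.species[key]
        sp = E(
            "species",
            species_list,
            id=species_id(key),
            name=str(g),
            compartment="cell",
        )
        roles = ",".join(sorted(p.roles.get(key, ())))
        if roles:
            sp.set(f"{{{GNET_NS}}}roles", roles)
        ann = etree.SubElement(sp, f"{{{SBML_NS}}}annotation")
        # the glycoct element carries its namespace as a default xmlns,
        # matching the published annotation snippet byte for byte
        glycoct = etree.SubElement(
            ann, f"{{{GLYCOCT_NS}}}glycoct", nsmap={None: GLYCOCT_NS}
        )
        sugar = etree.SubElement(glycoct, f"{{{GLYCOCT_NS}}}sugar", version="1.0")
        text = write_glycoct(g)
        res_part, _, lin_part = text.partition("LIN\n")
        residues = etree.SubElement(sugar, f"{{{GLYCOCT_NS}}}residues")
        residues.text = "\n" + res_part.replace("RES\n", "", 1).strip() + "\n"
        linkages = etree.SubElement(sugar, f"{{{GLYCOCT_NS}}}linkages")
        linkages.text = "\n" + lin_part.strip() + "\n" if lin_part.strip() else "\n"
    for enz in enzymes:
        E(
            "species",
            species_list,
            id=_enzyme_id(enz),
            name=enz,
            compartment="cell",
            boundaryCondition="true",
        )
    reactions_el = E("listOfReactions", model)
    for i, key in enumerate(sorted(p.reactions)):
        r = p.reactions[key]
        rx = E("reaction", reactions_el, id=f"rxn_{i:04d}", reversible="false")
        rx.set(f"{{{GNET_NS}}}enzyme", r.enzyme)
        rx.set(f"{{{GNET_NS}}}direction", r.direction)
        reactants = E("listOfReactants", rx)
        E("speciesReference", reactants, species=species_id(key[0]))
        products = E("listOfProducts", rx)
        E("speciesReference", products, species=species_id(key[1]))
        modifiers = E("listOfModifiers", rx)
        E("modifierSpeciesReference", modifiers, species=_enzyme_id(r.enzyme))
    tree = etree.ElementTree(root)
    etree.indent(tree, space="  ")
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=False)


def import_sbml(path) -> Pathway:
    """Read a pathway from an SBML file produced by :func:`export_sbml`.

    Any SBML document whose species carry parseable ``glycoct``
    annotations is accepted; glycan species lacking the annotation are
    rejected with their species id.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"malformed XML: {exc}") from None
    root = tree.getroot()
    ns = {"s": SBML_NS, "g": GLYCOCT_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise SbmlError("no SBML model element found")
    pw = Pathway()
    by_id: dict[str, Glycan] = {}
    enzyme_names: dict[str, str] = {}
    for sp in model.findall("s:listOfSpecies/s:species", ns):
        sid = sp.get("id", "")
        if sp.get("boundaryCondition") == "true":
            enzyme_names[sid] = sp.get("name", sid)
            continue
        sugar = sp.find("s:annotation/g:glycoct/g:sugar", ns)
        if sugar is None:
            raise SbmlError(f"species {sid!r} lacks a glycoct annotation")
        residues = sugar.find("g:residues", ns)
        linkages = sugar.find("g:linkages", ns)
        res_text = (residues.text or "").strip() if residues is not None else ""
        lin_text = (linkages.text or "").strip() if linkages is not None else ""
        if not res_text:
            raise SbmlError(f"species {sid!r} has an empty residues section")
        text = "RES\n" + res_text + ("\nLIN\n" + lin_text if lin_text else "") + "\n"
        g = parse_glycoct(text)
        by_id[sid] = g
        key = pw.add_species(g)
        roles = sp.get(f"{{{GNET_NS}}}roles")
        if roles:
            pw.roles[key] |= set(roles.split(","))
    for rx in model.findall("s:listOfReactions/s:reaction", ns):
        refs = rx.findall("s:listOfReactants/s:speciesReference", ns)
        prods = rx.findall("s:listOfProducts/s:speciesReference", ns)
        if len(refs) != 1 or len(prods) != 1:
            raise SbmlError(f"reaction {rx.get('id')!r} is not 1-to-1")
        sid, pid = refs[0].get("species"), prods[0].get("species")
        if sid not in by_id or pid not in by_id:
            raise SbmlError(f"reaction {rx.get('id')!r} references unknown species")
        enzyme = rx.get(f"{{{GNET_NS}}}enzyme")
        if enzyme is None:
            mod = rx.find("s:listOfModifiers/s:modifierSpeciesReference", ns)
            enzyme = enzyme_names.get(mod.get("species"), "") if mod is not None else ""
        sub, prod = by_id[sid], by_id[pid]
        direction = rx.get(f"{{{GNET_NS}}}direction")
        if direction is None:
            direction = "transfer" if len(prod) > len(sub) else "hydrolysis"
        pw.add_reaction(Rxn(sub, prod, enzyme or "unknown", direction))
    return pw
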