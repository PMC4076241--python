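"""GlycoCT condensed reader/writer.

Only the RES and LIN sections are emitted (no REP/ALT/UND), which covers
every structure this package handles.  Residues are written as GlycoCT
basetypes with N-acetyl substituents on their own ``s:`` lines, e.g. the
core-2 trisaccharide::

    RES
    1b:x-dgal-HEX-1:5
    2s:n-acetyl
    3b:b-dgal-HEX-1:5
    4b:b-dglc-HEX-1:5
    5s:n-acetyl
    LIN
    1:1d(2+1)2n
    2:1o(3+1)3d
    3:1o(6+1)4d
    4:4d(2+1)5n

The writer is deterministic: residues are numbered in a root-first
traversal with children in canonical order and each residue's substituent
immediately after it.  ``parse_glycoct(write_glycoct(g))`` is the identity
on structure.
"""

from __future__ import annotations

import re

from .glycan import Glycan, GlycanNode, Linkage
from .residues import Monosaccharide

__all__ = ["parse_glycoct", "write_glycoct", "GlycoCTParseError"]


class GlycoCTParseError(ValueError):
    pass


# residue -> (basetype without anomer prefix, N-acetyl position or None)
_BASETYPE = {
    Monosaccharide.Glc: ("dglc-HEX-1:5", None),
    Monosaccharide.Gal: ("dgal-HEX-1:5", None),
    Monosaccharide.Man: ("dman-HEX-1:5", None),
    Monosaccharide.GlcNAc: ("dglc-HEX-1:5", 2),
    Monosaccharide.GalNAc: ("dgal-HEX-1:5", 2),
    Monosaccharide.Fuc: ("lgal-HEX-1:5|6:d", None),
    Monosaccharide.Neu5Ac: ("dgro-dgal-NON-2:6|1:a|2:keto|3:d", 5),
    Monosaccharide.Xyl: ("dxyl-PEN-1:5", None),
}

# (basetype, has N-acetyl) -> residue
_FROM_BASETYPE = {
    ("dglc-HEX-1:5", False): Monosaccharide.Glc,
    ("dgal-HEX-1:5", False): Monosaccharide.Gal,
    ("dman-HEX-1:5", False): Monosaccharide.Man,
    ("dglc-HEX-1:5", True): Monosaccharide.GlcNAc,
    ("dgal-HEX-1:5", True): Monosaccharide.GalNAc,
    ("lgal-HEX-1:5|6:d", False): Monosaccharide.Fuc,
    ("dgro-dgal-NON-2:6|1:a|2:keto|3:d", True): Monosaccharide.Neu5Ac,
    ("dxyl-PEN-1:5", False): Monosaccharide.Xyl,
}


def write_glycoct(g: Glycan) -> str:
    """Serialise a glycan to GlycoCT condensed text."""
    res_lines: list[str] = []
    lin_lines: list[tuple[str, str]] = []  # deferred so numbering is complete
    index = {"n": 0}

    def nxt() -> int:
        index["n"] += 1
        return index["n"]

    def emit(node: GlycanNode) -> int:
        basetype, nac = _BASETYPE[node.residue]
        anomer = node.parent_link.anomer if node.parent_link is not None else "x"
        anomer = "x" if anomer == "?" else anomer
        rid = nxt()
        res_lines.append(f"{rid}b:{anomer}-{basetype}")
        if nac is not None:
            sid = nxt()
            res_lines.append(f"{sid}s:n-acetyl")
            lin_lines.append((f"{rid}d:({nac}+1){sid}n", ""))
        ordered = sorted(
            node.children, key=lambda c: (c.parent_link.position_key, c.parent_link.anomer)
        )
        for child in ordered:
            cl = child.parent_link
            acc = -1 if cl.acceptor_pos is None else cl.acceptor_pos
            cid = emit(child)
            lin_lines.append((f"{rid}o:({acc}+{cl.donor_pos}){cid}d", ""))
        return rid

    emit(g.root)
    lines = ["RES"] + res_lines
    if lin_lines:
        lines.append("LIN")
        for n, (body, _) in enumerate(lin_lines, 1):
            left, right = body.split(":", 1)
            lines.append(f"{n}:{left}{right}")
    return "\n".join(lines) + "\n"


_RES_B = re.compile(r"^(\d+)b:([abx?])-(.+)$")
_RES_S = re.compile(r"^(\d+)s:(.+)$")
_LIN = re.compile(r"^\d+:(\d+)([od])\((-?\d+)\+(\d+)\)(\d+)([dn])$")


def parse_glycoct(text: str) -> Glycan:
    """Parse GlycoCT condensed text into a :class:`Glycan`."""
    section = None
    bases: dict[int, tuple[str, str]] = {}  # id -> (anomer, basetype)
    subs: dict[int, str] = {}
    links: list[tuple[int, str, int, int, int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in ("RES", "LIN"):
            section = line
            continue
        if section == "RES":
            m = _RES_B.match(line)
            if m:
                bases[int(m.group(1))] = (m.group(2), m.group(3))
                continue
            m = _RES_S.match(line)
            if m:
                subs[int(m.group(1))] = m.group(2)
                continue
            raise GlycoCTParseError(f"line {lineno}: bad RES entry {line!r}")
        elif section == "LIN":
            m = _LIN.match(line)
            if not m:
                raise GlycoCTParseError(f"line {lineno}: bad LIN entry {line!r}")
            parent, ptype, acc, donor, child, ctype = (
                int(m.group(1)),
                m.group(2),
                int(m.group(3)),
                int(m.group(4)),
                int(m.group(5)),
                m.group(6),
            )
            links.append((parent, ptype, acc, donor, child, ctype))
        else:
            raise GlycoCTParseError(f"line {lineno}: content outside RES/LIN: {line!r}")
    if not bases:
        raise GlycoCTParseError("no residues found")

    has_nac: dict[int, bool] = {rid: False for rid in bases}
    tree_links: list[tuple[int, int, int, int]] = []
    for parent, ptype, acc, donor, child, ctype in links:
        if ctype == "n":
            if parent not in bases:
                raise GlycoCTParseError(f"substituent link to unknown residue {parent}")
            if child not in subs:
                raise GlycoCTParseError(f"dangling substituent index {child}")
            if subs[child] != "n-acetyl":
                raise GlycoCTParseError(f"unsupported substituent {subs[child]!r}")
            has_nac[parent] = True
        else:
            if parent not in bases or child not in bases:
                raise GlycoCTParseError(
                    f"dangling linkage index {parent}->{child}"
                )
            tree_links.append((parent, acc, donor, child))

    nodes: dict[int, GlycanNode] = {}
    for rid, (anomer, basetype) in sorted(bases.items()):
        key = (basetype, has_nac[rid])
        if key not in _FROM_BASETYPE:
            raise GlycoCTParseError(f"unknown basetype {basetype!r}")
        nodes[rid] = GlycanNode(_FROM_BASETYPE[key])
        nodes[rid].parent_link = None

    children: set[int] = set()
    for parent, acc, donor, child in sorted(tree_links, key=lambda t: t[3]):
        if child in children:
            raise GlycoCTParseError(f"residue {child} has two parents")
        children.add(child)
        anomer = bases[child][0]
        link = Linkage(
            "?" if anomer == "x" else anomer,
            donor,
            None if acc == -1 else acc,
        )
        node = nodes[child]
        node.parent_link = link
        nodes[parent].add_child(node)

    roots = [rid for rid in bases if rid not in children]
    if len(roots) != 1:
        raise GlycoCTParseError(f"expected one root residue, found {len(roots)}")
    # reject cycles / disconnected parts: every residue must be reachable
    reach = set()
    stack = [nodes[roots[0]]]
    while stack:
        n = stack.pop()
        reach.add(id(n))
        stack.extend(n.children)
    if len(reach) != len(nodes):
        raise GlycoCTParseError("disconnected residues in LIN section")
    return Glycan(nodes[roots[0]])
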