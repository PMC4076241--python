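"""Linear (LINUCS-style) glycan notation.

The dialect is the condensed linear notation used throughout the
glycobiology literature: residues are written non-reducing end first, the
reducing-end residue last, with the linkage in parentheses after the donor
residue and side branches in square brackets, e.g. the core-2
trisaccharide::

    Gal(b1,3)[GlcNAc(b1,6)]GalNAc

Anomers may be written ``a``/``b`` or ``α``/``β``; undetermined anomer or
acceptor position is ``?``.  The writer is deterministic (branches in
canonical order, backbone = last-sorted child) so ``write -> parse`` round
trips reproduce a structurally equal glycan.
"""

from __future__ import annotations

import re

from .glycan import Glycan, GlycanNode, Linkage
from .residues import resolve_residue

__all__ = ["parse_linear", "write_linear", "LinearParseError"]


class LinearParseError(ValueError):
    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


_TOKEN = re.compile(r"\s*([A-Za-z0-9]+|\(|\)|\[|\])")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if not m:
            # allow linkage characters inside parens to be picked up raw
            if text[i] in ",?αβ-":
                tokens.append((text[i], i))
                i += 1
                continue
            raise LinearParseError(f"unexpected character {text[i]!r}", i)
        tokens.append((m.group(1), m.start(1)))
        i = m.end()
    return tokens


def parse_linear(text: str) -> Glycan:
    """Parse linear notation into a :class:`Glycan`."""
    if not text or not text.strip():
        raise LinearParseError("empty glycan string")
    items, rest = _parse_chain(_tokenize(text), 0)
    if rest != -1:
        raise LinearParseError("unbalanced brackets", rest)
    root = _build_chain(items, text)
    return Glycan(root)


# A chain is a list of items; each item is ("res", name, link_or_None, pos)
# or ("branch", subchain, pos).
def _parse_chain(tokens, i):
    items = []
    while i < len(tokens):
        tok, pos = tokens[i]
        if tok == "]":
            return items, i
        if tok == "[":
            sub, j = _parse_chain(tokens, i + 1)
            if j >= len(tokens) or tokens[j][0] != "]":
                raise LinearParseError("unclosed '['", pos)
            items.append(("branch", sub, pos))
            i = j + 1
        elif tok == "(":
            raise LinearParseError("linkage without preceding residue", pos)
        elif tok == ")":
            raise LinearParseError("unmatched ')'", pos)
        else:
            name = tok
            link = None
            if i + 1 < len(tokens) and tokens[i + 1][0] == "(":
                j = i + 2
                linktoks = []
                while j < len(tokens) and tokens[j][0] != ")":
                    linktoks.append(tokens[j][0])
                    j += 1
                if j >= len(tokens):
                    raise LinearParseError("unclosed linkage", tokens[i + 1][1])
                try:
                    link = Linkage.parse("".join(linktoks))
                except ValueError as exc:
                    raise LinearParseError(str(exc), tokens[i + 1][1]) from None
                i = j + 1
            else:
                i += 1
            items.append(("res", name, link, pos))
    return items, -1


def _build_chain(items, text) -> GlycanNode:
    if not items:
        raise LinearParseError("empty chain")
    kind = items[-1][0]
    if kind != "res":
        raise LinearParseError("chain must end in a residue", items[-1][-1])
    _, name, link, pos = items[-1]
    try:
        residue = resolve_residue(name)
    except KeyError as exc:
        raise LinearParseError(str(exc), pos) from None
    node = GlycanNode(residue, link)
    current = node
    for item in reversed(items[:-1]):
        if item[0] == "res":
            _, name, link, pos = item
            if link is None:
                raise LinearParseError(f"residue {name} lacks a linkage", pos)
            try:
                child = GlycanNode(resolve_residue(name), link)
            except KeyError as exc:
                raise LinearParseError(str(exc), pos) from None
            current.add_child(child)
            current = child
        else:
            _, sub, pos = item
            branch_root = _build_chain(sub, text)
            if branch_root.parent_link is None:
                raise LinearParseError("branch lacks a linkage", pos)
            current.add_child(branch_root)
    return node


def _write_node(node: GlycanNode) -> str:
    suffix = f"({node.parent_link})" if node.parent_link is not None else ""
    if not node.children:
        return f"{node.residue}{suffix}"
    ordered = sorted(
        node.children, key=lambda c: (c.parent_link.position_key, _write_node(c))
    )
    backbone, side = ordered[-1], ordered[:-1]
    brackets = "".join(f"[{_write_node(c)}]" for c in side)
    return f"{_write_node(backbone)}{brackets}{node.residue}{suffix}"


def write_linear(g: Glycan) -> str:
    """Serialise a glycan to linear notation (deterministic branch order)."""
    return _write_node(g.root)
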