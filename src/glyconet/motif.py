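"""Anchored subtree patterns (motifs) and their matching semantics.

A :class:`GlycanMotif` wraps a pattern :class:`~glyconet.glycan.Glycan`
plus an anchor that fixes how the pattern aligns with a target glycan:

``at_reducing_end``
    The pattern root aligns with the target's root; every pattern edge must
    map onto an equal edge of the target (the target may carry extra
    branches).  Used by ``substNABranch``/``substMinStruct`` enzyme fields.

``at_target_residue``
    The pattern is a linear chain anchored at an enzyme's acted-on residue.
    With ``direction='toward_root'`` (the ``targetBranch`` semantics) the
    chain runs from the acted-on residue toward the reducing end and is
    matched as a prefix of the residue's ancestor path; ``to_root=True``
    additionally requires the chain to end exactly at the root.  With
    ``direction='toward_leaves'`` the pattern is matched downward into the
    residue's own subtree (acceptor-context semantics).

``floating``
    The pattern may align at any residue (downward matching).

Undetermined anomers or acceptor positions in the *pattern* act as
wildcards; a determined pattern linkage only matches the identical
determined target linkage.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .glycan import Glycan, GlycanNode, Linkage, StructureError

__all__ = ["GlycanMotif", "match_motif"]


def _link_matches(pattern: Optional[Linkage], target: Optional[Linkage]) -> bool:
    if pattern is None:
        return True
    if target is None:
        return False
    if pattern.donor_pos != target.donor_pos:
        return False
    if pattern.anomer != "?" and pattern.anomer != target.anomer:
        return False
    if pattern.acceptor_pos is not None and pattern.acceptor_pos != target.acceptor_pos:
        return False
    return True


def _embed_down(pnode: GlycanNode, gnode: GlycanNode) -> bool:
    """Can the pattern subtree rooted at ``pnode`` embed at ``gnode``?

    Pattern children must map injectively onto distinct children of
    ``gnode`` with matching linkages; extra target branches are allowed.
    """
    if pnode.residue != gnode.residue:
        return False
    if not pnode.children:
        return True

    gchildren = gnode.children

    def assign(i: int, used: int) -> bool:
        if i == len(pnode.children):
            return True
        pc = pnode.children[i]
        for j, gc in enumerate(gchildren):
            if used & (1 << j):
                continue
            if _link_matches(pc.parent_link, gc.parent_link) and _embed_down(pc, gc):
                if assign(i + 1, used | (1 << j)):
                    return True
        return False

    return assign(0, 0)


def _chain_of(pattern: Glycan) -> list[GlycanNode]:
    """Linear pattern as a list from the acted-on residue toward the root.

    The pattern glycan is written reducing-end-rooted; the acted-on residue
    is its single leaf.
    """
    chain = []
    node: Optional[GlycanNode] = pattern.root
    while node is not None:
        chain.append(node)
        if len(node.children) > 1:
            raise StructureError("targetBranch pattern must be a linear chain")
        node = node.children[0] if node.children else None
    chain.reverse()  # leaf (acted-on residue) first
    return chain


@dataclasses.dataclass(frozen=True)
class GlycanMotif:
    """An anchored glycan pattern."""

    pattern: Glycan
    anchor: str = "floating"
    direction: str = "toward_leaves"
    to_root: bool = False

    def __post_init__(self) -> None:
        if self.anchor not in ("at_reducing_end", "at_target_residue", "floating"):
            raise StructureError(f"bad motif anchor {self.anchor!r}")
        if self.direction not in ("toward_root", "toward_leaves"):
            raise StructureError(f"bad motif direction {self.direction!r}")
        if self.anchor == "at_target_residue" and self.direction == "toward_root":
            _chain_of(self.pattern)  # validates linearity

    # -- site-anchored matching ------------------------------------------
    def matches_at(self, g: Glycan, node: GlycanNode) -> bool:
        """Match the motif at a specific residue of ``g``."""
        if self.anchor == "at_target_residue" and self.direction == "toward_root":
            chain = _chain_of(self.pattern)
            cur: Optional[GlycanNode] = node
            for i, pnode in enumerate(chain):
                if cur is None or pnode.residue != cur.residue:
                    return False
                # linkage between chain[i] and chain[i+1] is chain[i].parent_link
                # in the pattern tree (leaf-first ordering reverses parentage)
                if i + 1 < len(chain):
                    pl = chain[i].parent_link
                    if not _link_matches(pl, cur.parent_link):
                        return False
                cur = cur.parent
            if self.to_root and cur is not None:
                return False
            return True
        return _embed_down(self.pattern.root, node)


def match_motif(g: Glycan, m: GlycanMotif) -> list[tuple]:
    """Return the paths of all residues where the motif aligns.

    For ``at_reducing_end`` the only possible site is the root (empty
    path); for ``floating`` every residue is tried.  An empty list means no
    match.
    """
    if m.anchor == "at_reducing_end":
        return [()] if _embed_down(m.pattern.root, g.root) else []
    sites = []
    for path, node in g.walk():
        if m.matches_at(g, node):
            sites.append(path)
    return sites
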