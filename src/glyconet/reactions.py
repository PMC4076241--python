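"""Single-step reaction inference.

Given one enzyme record and one glycan, inference proceeds in three steps:

1. *Feasibility* (:func:`can_act`): global blocking and requirement rules —
   ``substNAResidue`` (a residue anywhere in the substrate blocks action),
   ``substNABranch`` (a reducing-end-anchored motif blocks action) and
   ``substMinStruct`` (a motif the substrate must carry).
2. *Site identification* (:func:`find_sites`): residues that can be
   modified.  For a glycosyltransferase these are residues equal to
   ``resAtt2FG`` whose own parent linkage matches ``linkAtt2FG``, whose
   ancestor chain matches ``targetBranch``, whose subtree matches
   ``acceptor_context``, and whose acceptor position for the new linkage is
   free.  For a glycosidase these are terminal residues equal to
   ``resfuncgroup`` attached through a cleavable linkage in the attachment
   context ``resAtt2FG``/``linkAtt2FG``; when several linkages are listed
   they act as an ordered preference (sites for the first linkage with any
   match).
3. *Product creation* (:func:`infer_products`): one reaction per site,
   attaching ``resfuncgroup`` via ``linkFG`` (transfer) or removing the
   site residue (hydrolysis), deduplicated by product canonical string.

:func:`infer_substrates` runs the inverse inference (substrate from
product) and forward-checks every candidate so that reverse inference
never proposes a substrate the enzyme could not actually convert.
"""

from __future__ import annotations

import dataclasses

from .enzymes import GHEnz, GTEnz
from .glycan import Glycan
from .motif import match_motif

__all__ = ["Rxn", "can_act", "find_sites", "infer_products", "infer_substrates"]


@dataclasses.dataclass(frozen=True)
class Rxn:
    """One enzymatic conversion between two glycans."""

    substrate: Glycan
    product: Glycan
    enzyme: str
    direction: str  # "transfer" | "hydrolysis"

    def __post_init__(self) -> None:
        delta = len(self.product) - len(self.substrate)
        expected = 1 if self.direction == "transfer" else -1
        if delta != expected:
            raise ValueError(
                f"{self.direction} reaction must change residue count by {expected}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.substrate.canonical, self.product.canonical, self.enzyme)

    def __str__(self) -> str:
        from .linear import write_linear

        arrow = "->" if self.direction == "transfer" else "-|"
        return f"[{self.enzyme}] {write_linear(self.substrate)} {arrow} {write_linear(self.product)}"


def _enzyme_name(e: GTEnz | GHEnz) -> str:
    rec = e.name_recommended or e.name_systematic
    return rec or ".".join(str(x) for x in e.ecno)


def _residue_present(g: Glycan, residues) -> bool:
    wanted = set(residues)
    return any(node.residue in wanted for _p, node in g.walk())


def can_act(e: GTEnz | GHEnz, g: Glycan) -> bool:
    """Whether the enzyme can act on the glycan at all (step 1 + sites)."""
    return _feasible(e, g) and bool(find_sites(e, g))


def _feasible(e: GTEnz | GHEnz, g: Glycan) -> bool:
    if e.substNAResidue and _residue_present(g, e.substNAResidue):
        return False
    for motif in e.substNABranch:
        if match_motif(g, motif):
            return False
    if e.substMinStruct is not None and not match_motif(g, e.substMinStruct):
        return False
    return True


def _gt_sites(e: GTEnz, g: Glycan) -> list[tuple]:
    sites = []
    for path, node in g.walk():
        if e.resAtt2FG is not None and node.residue != e.resAtt2FG:
            continue
        if e.linkAtt2FG is not None:
            from .motif import _link_matches

            if not _link_matches(e.linkAtt2FG, node.parent_link):
                continue
        if node.position_occupied(e.linkFG.acceptor_pos, e.linkFG.anomer):
            continue
        if e.targetBranch is not None and not e.targetBranch.matches_at(g, node):
            continue
        if e.acceptor_context is not None and not e.acceptor_context.matches_at(g, node):
            continue
        sites.append(path)
    return sites


def _gh_sites(e: GHEnz, g: Glycan) -> list[tuple]:
    from .motif import _link_matches

    for link in e.linkFG:  # ordered preference: first linkage with any match wins
        sites = []
        for path, node in g.walk():
            if not node.is_terminal() or node.parent_link is None:
                continue
            if node.residue != e.resfuncgroup:
                continue
            if not _link_matches(link, node.parent_link):
                continue
            parent = node.parent
            assert parent is not None
            if e.resAtt2FG is not None and parent.residue != e.resAtt2FG:
                continue
            if e.linkAtt2FG is not None and not _link_matches(
                e.linkAtt2FG, parent.parent_link
            ):
                continue
            if e.targetBranch is not None and not e.targetBranch.matches_at(g, node):
                continue
            sites.append(path)
        if sites:
            return sites
    return []


def find_sites(e: GTEnz | GHEnz, g: Glycan) -> list[tuple]:
    """Residue paths the enzyme can modify, in deterministic order."""
    sites = _gt_sites(e, g) if isinstance(e, GTEnz) else _gh_sites(e, g)
    return sorted(sites)


def infer_products(e: GTEnz | GHEnz, g: Glycan, name: str | None = None) -> list[Rxn]:
    """All single-step products of ``e`` acting on ``g`` (may be empty)."""
    name = name if name is not None else _enzyme_name(e)
    if not _feasible(e, g):
        return []
    out: dict[str, Rxn] = {}
    if isinstance(e, GTEnz):
        for path in find_sites(e, g):
            product = g.attach(path, e.resfuncgroup, e.linkFG)
            out.setdefault(
                product.canonical, Rxn(g, product, name, "transfer")
            )
    else:
        for path in find_sites(e, g):
            product = g.remove(path)
            out.setdefault(
                product.canonical, Rxn(g, product, name, "hydrolysis")
            )
    return [out[k] for k in sorted(out)]


def _candidate_substrates_gt(e: GTEnz, p: Glycan) -> list[Glycan]:
    """Remove one transferred residue from the product in every legal way."""
    from .motif import _link_matches

    candidates = []
    for path, node in p.walk():
        if not node.is_terminal() or node.parent_link is None:
            continue
        if node.residue != e.resfuncgroup:
            continue
        if not _link_matches(e.linkFG, node.parent_link):
            continue
        parent = node.parent
        assert parent is not None
        if e.resAtt2FG is not None and parent.residue != e.resAtt2FG:
            continue
        if e.linkAtt2FG is not None and not _link_matches(
            e.linkAtt2FG, parent.parent_link
        ):
            continue
        candidates.append(p.remove(path))
    return candidates


def _candidate_substrates_gh(e: GHEnz, p: Glycan) -> list[Glycan]:
    """Re-attach one cleaved residue to the product in every legal way."""
    from .motif import _link_matches

    candidates = []
    for path, node in p.walk():
        if e.resAtt2FG is not None and node.residue != e.resAtt2FG:
            continue
        if e.linkAtt2FG is not None and not _link_matches(
            e.linkAtt2FG, node.parent_link
        ):
            continue
        for link in e.linkFG:
            if link.acceptor_pos is None:
                continue
            if node.position_occupied(link.acceptor_pos, link.anomer):
                continue
            candidates.append(p.attach(path, e.resfuncgroup, link))
    return candidates


def infer_substrates(e: GTEnz | GHEnz, p: Glycan, name: str | None = None) -> list[Rxn]:
    """All substrates from which ``e`` produces ``p`` in one step.

    Every candidate is forward-checked with :func:`infer_products`, so the
    returned reactions are exactly the forward reactions ending at ``p``.
    """
    name = name if name is not None else _enzyme_name(e)
    if isinstance(e, GTEnz):
        candidates = _candidate_substrates_gt(e, p)
    else:
        candidates = _candidate_substrates_gh(e, p)
    out: dict[str, Rxn] = {}
    for s in candidates:
        for r in infer_products(e, s, name=name):
            if r.product == p:
                out.setdefault(s.canonical, r)
    return [out[k] for k in sorted(out)]
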