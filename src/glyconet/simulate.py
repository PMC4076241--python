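"""Seeded random structure generators.

Used by the property-test suites (round trips, canonicalisation,
forward/reverse duality, graph oracles) and by the acceptance checks; all
randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import numpy as np

from .glycan import Glycan, GlycanNode, Linkage
from .network import Pathway
from .reactions import Rxn
from .residues import Monosaccharide

__all__ = ["random_glycan", "shuffled_copy", "random_pathway", "random_dag"]

_POSITIONS = (2, 3, 4, 6, 8)


def random_glycan(
    rng: np.random.Generator,
    n_residues: int = 6,
    p_undetermined: float = 0.0,
) -> Glycan:
    """A random glycan tree with ``n_residues`` residues.

    Residues and attachment sites are drawn uniformly; with probability
    ``p_undetermined`` a linkage's anomer or acceptor position is left
    undetermined.
    """
    residues = list(Monosaccharide)
    root = GlycanNode(residues[rng.integers(len(residues))])
    nodes = [root]
    for _ in range(n_residues - 1):
        res = residues[rng.integers(len(residues))]
        for _attempt in range(50):
            parent = nodes[rng.integers(len(nodes))]
            anomer = "ab"[rng.integers(2)]
            pos: int | None = int(_POSITIONS[rng.integers(len(_POSITIONS))])
            if rng.random() < p_undetermined:
                if rng.random() < 0.5:
                    anomer = "?"
                else:
                    pos = None
            if parent.position_occupied(pos, anomer):
                continue
            child = GlycanNode(res, Linkage(anomer, res.donor_pos, pos))
            parent.add_child(child)
            nodes.append(child)
            break
    return Glycan(root)


def _shuffle_node(rng: np.random.Generator, node: GlycanNode) -> GlycanNode:
    children = [_shuffle_node(rng, c) for c in node.children]
    order = rng.permutation(len(children))
    out = GlycanNode(node.residue, node.parent_link)
    for i in order:
        out.add_child(children[i])
    return out


def shuffled_copy(rng: np.random.Generator, g: Glycan) -> Glycan:
    """A structurally equal copy with sibling order randomly permuted."""
    return Glycan(_shuffle_node(rng, g.root))


def random_dag(rng: np.random.Generator, n_nodes: int = 8, p_edge: float = 0.3):
    """Random DAG edge list over nodes ``0..n-1`` (edges go low -> high)."""
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((i, j))
    return edges


def random_pathway(
    rng: np.random.Generator,
    n_species: int = 8,
    p_edge: float = 0.5,
    p_parallel: float = 0.15,
) -> Pathway:
    """A random graded acyclic pathway over distinct random glycans.

    Species are arranged in levels of increasing residue count and edges
    (single-residue transfers) connect consecutive levels, so every
    reaction respects the one-residue mass balance.  With probability
    ``p_parallel`` an edge is duplicated under a second enzyme name,
    exercising parallel multigraph edges.
    """
    n_levels = max(2, int(rng.integers(2, 5)))
    levels: list[list[Glycan]] = [[] for _ in range(n_levels)]
    seen = set()
    for i in range(n_species):
        lvl = i % n_levels
        for _attempt in range(50):
            g = random_glycan(rng, n_residues=3 + lvl)
            if g.canonical not in seen:
                seen.add(g.canonical)
                levels[lvl].append(g)
                break
    pw = Pathway()
    for lvl in levels:
        for g in lvl:
            pw.add_species(g)
    for lo, hi in zip(levels, levels[1:]):
        for u in lo:
            for v in hi:
                if rng.random() < p_edge:
                    pw.add_reaction(Rxn(u, v, "enzyme_a", "transfer"))
                    if rng.random() < p_parallel:
                        pw.add_reaction(Rxn(u, v, "enzyme_b", "transfer"))
    return pw
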