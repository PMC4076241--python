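"""DOT and GraphML export of pathways and path unions."""

from __future__ import annotations

import networkx as nx

from .graph import PathwayGraph
from .network import Pathway
from .sbml import species_id

__all__ = ["export_graph"]


def _label(p: Pathway, key: str) -> str:
    from .linear import write_linear

    return write_linear(p.species[key])


def export_graph(p: Pathway | PathwayGraph, fmt: str, path) -> None:
    """Write a pathway as a graph file.

    ``fmt`` is ``"dot"`` or ``"graphml"``.  Nodes are labelled with the
    glycan (linear notation) and role flags; edges with the enzyme name.
    """
    pw = p.pathway if isinstance(p, PathwayGraph) else p
    fmt = fmt.lower()
    if fmt == "dot":
        lines = ["digraph pathway {"]
        for key in sorted(pw.species):
            roles = ",".join(sorted(pw.roles.get(key, ())))
            label = _label(pw, key)
            if roles:
                label += f"\\n[{roles}]"
            lines.append(f'  "{species_id(key)}" [label="{label}"];')
        for s, t, e in sorted(pw.reactions):
            lines.append(f'  "{species_id(s)}" -> "{species_id(t)}" [label="{e}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = nx.MultiDiGraph()
        for key in sorted(pw.species):
            g.add_node(
                species_id(key),
                label=_label(pw, key),
                roles=",".join(sorted(pw.roles.get(key, ()))),
            )
        for s, t, e in sorted(pw.reactions):
            g.add_edge(species_id(s), species_id(t), enzyme=e)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use 'dot' or 'graphml')")
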