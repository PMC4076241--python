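"""Graph-theoretic analysis of pathways.

A :class:`PathwayGraph` is a directed multigraph view of a
:class:`~glyconet.network.Pathway`: nodes are species keys (canonical
strings), parallel edges are reactions labelled by enzyme.  On top of it:

* :func:`path_finding` — all simple directed paths between two species by
  recursive depth-first search, returned as alternating
  species/reaction sequences;
* :func:`subnet_by_num_del` — exhaustive (or seeded random) generation of
  subset networks by deleting ``k`` species, with validity constraints;
* :func:`subnet_by_spec_del` / :func:`subnet_by_spec_keep` — subset
  networks from named species;
* :func:`detect_isolated_species` / :func:`remove_isolated_species`.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Optional

import networkx as nx

from .network import INTERMEDIATE, Pathway
from .reactions import Rxn

__all__ = [
    "PathwayGraph",
    "SubsetConstraints",
    "SubsetResult",
    "SubsetScan",
    "path_finding",
    "subnet_by_num_del",
    "subnet_by_spec_del",
    "subnet_by_spec_keep",
    "detect_isolated_species",
    "remove_isolated_species",
]


class PathwayGraph:
    """Directed multigraph view of a pathway."""

    def __init__(self, pathway: Pathway) -> None:
        self.pathway = pathway
        g = nx.MultiDiGraph()
        for key in pathway.species:
            g.add_node(key, roles=sorted(pathway.roles.get(key, ())))
        for r in pathway.reactions.values():
            g.add_edge(r.key[0], r.key[1], enzyme=r.enzyme, rxn=r)
        self.graph = g

    @property
    def nodes(self):
        return self.graph.nodes

    def out_reactions(self, key: str) -> list[Rxn]:
        return sorted(
            (d["rxn"] for _u, _v, d in self.graph.out_edges(key, data=True)),
            key=lambda r: r.key,
        )


def path_finding(g: PathwayGraph | Pathway, source: str, target: str) -> list[list]:
    """All simple directed paths from ``source`` to ``target``.

    Each path alternates species keys and :class:`Rxn` objects:
    ``[s0, r01, s1, r12, s2, ...]``.  ``source == target`` yields one
    zero-length path.  Parallel (differently catalysed) edges give
    distinct paths.
    """
    pg = g if isinstance(g, PathwayGraph) else PathwayGraph(g)
    for key in (source, target):
        if key not in pg.graph:
            raise KeyError(f"species {key!r} not in pathway")
    paths: list[list] = []
    if source == target:
        return [[source]]

    visited = [source]
    trail: list = [source]

    def dfs(u: str) -> None:
        for r in pg.out_reactions(u):
            v = r.key[1]
            if v in visited:
                continue
            trail.append(r)
            trail.append(v)
            if v == target:
                paths.append(list(trail))
            else:
                visited.append(v)
                dfs(v)
                visited.pop()
            trail.pop()
            trail.pop()

    dfs(source)
    return paths


def detect_isolated_species(p: Pathway) -> list[str]:
    """Species keys that participate in no reaction."""
    return p.isolated_species()


def remove_isolated_species(p: Pathway) -> Pathway:
    """A copy of ``p`` with isolated species removed (idempotent)."""
    isolated = set(p.isolated_species())
    out = Pathway()
    for key, g in p.species.items():
        if key not in isolated:
            out.add_species(g)
            out.roles[key] = set(p.roles.get(key, ()))
    for r in p.reactions.values():
        out.add_reaction(r)
    out.truncated = p.truncated
    return out


def _restrict(p: Pathway, keep: set[str]) -> Pathway:
    out = Pathway()
    for key in sorted(keep):
        out.add_species(p.species[key])
        out.roles[key] = set(p.roles.get(key, ()))
    for (s, t, _e), r in p.reactions.items():
        if s in keep and t in keep:
            out.add_reaction(r)
    return out


def subnet_by_spec_del(g: PathwayGraph | Pathway, drop: Iterable[str]) -> Pathway:
    """Delete named species (plus incident reactions, plus stranded orphans)."""
    p = g.pathway if isinstance(g, PathwayGraph) else g
    drop = set(drop)
    unknown = drop - set(p.species)
    if unknown:
        raise KeyError(f"unknown species {sorted(unknown)[0]!r}")
    return remove_isolated_species(_restrict(p, set(p.species) - drop))


def subnet_by_spec_keep(g: PathwayGraph | Pathway, keep: Iterable[str]) -> Pathway:
    """Retain exactly the named species and the reactions among them."""
    p = g.pathway if isinstance(g, PathwayGraph) else g
    keep = set(keep)
    unknown = keep - set(p.species)
    if unknown:
        raise KeyError(f"unknown species {sorted(unknown)[0]!r}")
    return _restrict(p, keep)


@dataclasses.dataclass(frozen=True)
class SubsetConstraints:
    """Validity constraints for subset-network generation.

    A candidate subset network is valid when it contains every species in
    ``require``; contains at least one species of ``require_any`` (if
    given); every surviving species is reachable from ``connected_from``
    (if given); every surviving in-silico intermediate is both the
    substrate and the product of at least one reaction
    (``intermediates_internal``); and the deletion stranded no species
    (``forbid_orphans`` — orphans make the candidate invalid instead of
    being silently pruned).
    """

    require: frozenset = frozenset()
    require_any: frozenset = frozenset()
    connected_from: Optional[str] = None
    intermediates_internal: bool = True
    forbid_orphans: bool = True

    def __init__(
        self,
        require=(),
        require_any=(),
        connected_from=None,
        intermediates_internal=True,
        forbid_orphans=True,
    ):
        object.__setattr__(self, "require", frozenset(require))
        object.__setattr__(self, "require_any", frozenset(require_any))
        object.__setattr__(self, "connected_from", connected_from)
        object.__setattr__(self, "intermediates_internal", bool(intermediates_internal))
        object.__setattr__(self, "forbid_orphans", bool(forbid_orphans))


class SubsetResult:
    """One valid subset network: the deletion and the surviving pathway."""

    __slots__ = ("deleted", "_master", "_surviving")

    def __init__(self, deleted: frozenset, master: Pathway, surviving: frozenset):
        self.deleted = deleted
        self._master = master
        self._surviving = surviving

    @property
    def surviving(self) -> frozenset:
        return self._surviving

    @property
    def valid(self) -> bool:
        return True

    @property
    def pathway(self) -> Pathway:
        return _restrict(self._master, set(self._surviving))


class SubsetScan(list):
    """List of valid :class:`SubsetResult` plus enumeration accounting."""

    def __init__(self, results, n_examined: int):
        super().__init__(results)
        self.n_examined = n_examined


def subnet_by_num_del(
    g: PathwayGraph | Pathway,
    k: int,
    protected: Iterable[str] = (),
    constraints: Optional[SubsetConstraints] = None,
    rng=None,
    max_samples: Optional[int] = None,
) -> SubsetScan:
    """Generate subset networks by deleting ``k`` non-protected species.

    All ``C(n_deletable, k)`` deletions are examined exhaustively unless
    ``rng`` (a :class:`numpy.random.Generator`) and ``max_samples`` are
    given, in which case that many random deletions are drawn.  Only valid
    results (per ``constraints``) are returned.
    """
    p = g.pathway if isinstance(g, PathwayGraph) else g
    protected = set(protected)
    unknown = protected - set(p.species)
    if unknown:
        raise KeyError(f"unknown species {sorted(unknown)[0]!r}")
    cons = constraints or SubsetConstraints()
    keys = sorted(p.species)
    index = {key: i for i, key in enumerate(keys)}
    n = len(keys)
    deletable = [i for i, key in enumerate(keys) if key not in protected]
    if not 1 <= k <= len(deletable):
        raise ValueError(f"k must be in 1..{len(deletable)}")

    edges = [(index[s], index[t]) for (s, t, _e) in p.reactions]
    require = {index[key] for key in cons.require}
    require_any = {index[key] for key in cons.require_any}
    start = index[cons.connected_from] if cons.connected_from is not None else None
    inter = {
        index[key]
        for key, flags in p.roles.items()
        if INTERMEDIATE in flags
    }

    def evaluate(deleted: frozenset) -> Optional[frozenset]:
        alive = [True] * n
        for i in deleted:
            alive[i] = False
        live = [(u, v) for u, v in edges if alive[u] and alive[v]]
        touched = set()
        for u, v in live:
            touched.add(u)
            touched.add(v)
        present = {i for i in range(n) if alive[i]}
        orphans = present - touched if live else present
        if cons.forbid_orphans and orphans:
            return None
        surv = present - orphans
        if not require <= surv:
            return None
        if require_any and not (require_any & surv):
            return None
        subs = {u for u, _v in live}
        prods = {v for _u, v in live}
        if cons.intermediates_internal:
            for i in surv & inter:
                if i not in subs or i not in prods:
                    return None
        if start is not None:
            if start not in surv:
                return None
            adj: dict[int, list[int]] = {}
            for u, v in live:
                adj.setdefault(u, []).append(v)
            seen = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj.get(u, ()):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if surv - seen:
                return None
        return frozenset(surv)

    if rng is not None and max_samples is not None:
        candidates = (
            frozenset(rng.choice(deletable, size=k, replace=False).tolist())
            for _ in range(max_samples)
        )
    else:
        candidates = (frozenset(c) for c in itertools.combinations(deletable, k))

    results = []
    examined = 0
    for deleted in candidates:
        examined += 1
        surv = evaluate(deleted)
        if surv is not None:
            results.append(
                SubsetResult(
                    frozenset(keys[i] for i in deleted),
                    p,
                    frozenset(keys[i] for i in surv),
                )
            )
    return SubsetScan(results, examined)
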