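"""Rooted-tree representation of glycans.

A glycan is modelled as an ordered rooted tree of monosaccharide residues.
The root is the reducing-end residue (for released O-glycans the GalNAc,
for N-glycans the innermost GlcNAc); edges are glycosidic linkages typed by
anomeric configuration, donor carbon and acceptor carbon.

Identity of glycans is defined through :func:`canonical_string`: two trees
that differ only in sibling order canonicalise to the same string, while
any structural difference (residue, anomer, position, undetermined versus
determined linkage) yields different strings.  All structural edits are
value-semantic: they return a new :class:`Glycan` and never mutate their
input.

Residue positions are addressed by *paths*: tuples of
``(acceptor_pos, anomer, child_index)`` triples from the root, so a site
reference stays meaningful across serialisation round trips.  The
``child_index`` disambiguates the (rare) case of two children sharing an
undetermined linkage.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterator, Mapping, Optional, Sequence

from .residues import GenericClass, Monosaccharide, resolve_residue

__all__ = [
    "Linkage",
    "GlycanNode",
    "Glycan",
    "GlycanComposition",
    "GlycanError",
    "LinkageError",
    "StructureError",
    "UNDETERMINED",
]

UNDETERMINED = "?"

_ANOMER_ALIASES = {"a": "a", "b": "b", "α": "a", "β": "b", "?": "?", "x": "?", "u": "?"}


class GlycanError(ValueError):
    """Base error for structural problems."""


class LinkageError(GlycanError):
    pass


class StructureError(GlycanError):
    pass


@dataclasses.dataclass(frozen=True, order=True)
class Linkage:
    """A glycosidic linkage: anomer, donor carbon, acceptor carbon.

    ``anomer`` is ``'a'``, ``'b'`` or ``'?'`` (undetermined); ``acceptor_pos``
    is an integer carbon or ``None`` for undetermined.
    """

    anomer: str = UNDETERMINED
    donor_pos: int = 1
    acceptor_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.anomer not in ("a", "b", UNDETERMINED):
            raise LinkageError(f"bad anomer {self.anomer!r}")
        if self.donor_pos not in (1, 2):
            raise LinkageError(f"donor position must be 1 or 2, got {self.donor_pos}")
        if self.acceptor_pos is not None and not (1 <= self.acceptor_pos <= 9):
            raise LinkageError(f"bad acceptor position {self.acceptor_pos}")

    @classmethod
    def parse(cls, text: str) -> "Linkage":
        """Parse linkage notation such as ``b1,4``, ``α2,3`` or ``?1,?``."""
        t = text.strip()
        if not t:
            raise LinkageError("empty linkage")
        anomer = _ANOMER_ALIASES.get(t[0])
        if anomer is None:
            raise LinkageError(f"bad anomer in linkage {text!r}")
        rest = t[1:]
        if "," in rest:
            d, _, a = rest.partition(",")
        elif "-" in rest:
            d, _, a = rest.partition("-")
        else:
            raise LinkageError(f"missing positions in linkage {text!r}")
        try:
            donor = int(d)
        except ValueError:
            raise LinkageError(f"bad donor position in linkage {text!r}") from None
        if a.strip() == UNDETERMINED:
            acceptor: Optional[int] = None
        else:
            try:
                acceptor = int(a)
            except ValueError:
                raise LinkageError(f"bad acceptor position in linkage {text!r}") from None
        return cls(anomer, donor, acceptor)

    def __str__(self) -> str:
        acc = UNDETERMINED if self.acceptor_pos is None else str(self.acceptor_pos)
        return f"{self.anomer}{self.donor_pos},{acc}"

    @property
    def position_key(self) -> tuple:
        """Sort key: acceptor position (undetermined last), then anomer."""
        pos = self.accepted_position_order()
        return (pos, self.anomer)

    def accepted_position_order(self) -> int:
        return 99 if self.acceptor_pos is None else self.acceptor_pos


class GlycanNode:
    """One residue in a glycan tree."""

    __slots__ = ("residue", "parent_link", "children", "parent")

    def __init__(
        self,
        residue: Monosaccharide,
        parent_link: Optional[Linkage] = None,
        children: Optional[list["GlycanNode"]] = None,
    ) -> None:
        self.residue = residue
        self.parent_link = parent_link
        self.children: list[GlycanNode] = []
        self.parent: Optional[GlycanNode] = None
        for c in children or ():
            self.add_child(c)

    def add_child(self, child: "GlycanNode") -> None:
        if child.parent_link is None:
            raise StructureError("non-root node requires a parent linkage")
        link = child.parent_link
        if link.acceptor_pos is not None:
            for other in self.children:
                ol = other.parent_link
                if (
                    ol is not None
                    and ol.acceptor_pos == link.acceptor_pos
                    and ol.anomer == link.anomer
                ):
                    raise StructureError(
                        f"position {link} of {self.residue} already occupied"
                    )
        child.parent = self
        self.children.append(child)

    def copy(self) -> "GlycanNode":
        return GlycanNode(
            self.residue,
            self.parent_link,
            [c.copy() for c in self.children],
        )

    def is_terminal(self) -> bool:
        return not self.children

    def position_occupied(self, acceptor_pos: Optional[int], anomer: str) -> bool:
        """Whether a child already sits at (acceptor_pos, anomer)."""
        if acceptor_pos is None:
            return False
        for c in self.children:
            pl = c.parent_link
            if pl is not None and pl.acceptor_pos == acceptor_pos and pl.anomer == anomer:
                return True
        return False

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GlycanNode({self.residue}, {self.parent_link})"


def _canon(node: GlycanNode) -> str:
    if not node.children:
        return node.residue.value
    parts = sorted(
        (c.parent_link.position_key, _canon(c), str(c.parent_link)) for c in node.children
    )
    inner = ",".join(f"{link}:{text}" for _key, text, link in parts)
    return f"{node.residue.value}({inner})"


class Glycan:
    """A glycan structure (immutable by convention).

    Construct from a root :class:`GlycanNode` or via the parsers in
    :mod:`glyconet.linear` and :mod:`glyconet.glycoct`.
    """

    __slots__ = ("root", "reducing_end_state", "_canonical")

    def __init__(self, root: GlycanNode, reducing_end_state: str = "free") -> None:
        if reducing_end_state not in ("free", "attachment-point"):
            raise StructureError(f"bad reducing end state {reducing_end_state!r}")
        self.root = root
        self.reducing_end_state = reducing_end_state
        self._canonical: Optional[str] = None

    # -- identity ---------------------------------------------------------
    @property
    def canonical(self) -> str:
        if self._canonical is None:
            self._canonical = _canon(self.root)
        return self._canonical

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Glycan) and self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __repr__(self) -> str:
        from .linear import write_linear

        return f"Glycan({write_linear(self)!r})"

    # -- traversal --------------------------------------------------------
    def walk(self) -> Iterator[tuple[tuple, GlycanNode]]:
        """Yield ``(path, node)`` pairs in root-first order.

        Paths are tuples of ``(acceptor_pos, anomer, child_index)``.
        """

        def rec(node: GlycanNode, path: tuple):
            yield path, node
            for i, c in enumerate(node.children):
                pl = c.parent_link
                step = (pl.accepted_position_order(), pl.anomer, i)
                yield from rec(c, path + (step,))

        yield from rec(self.root, ())

    def node_at(self, path: Sequence) -> GlycanNode:
        node = self.root
        for step in path:
            _, _, idx = step
            try:
                node = node.children[idx]
            except IndexError:
                raise StructureError(f"no node at path {tuple(path)}") from None
        return node

    def __len__(self) -> int:
        return sum(1 for _ in self.walk())

    # -- edits (value semantics) -----------------------------------------
    def attach(self, path: Sequence, residue: Monosaccharide, link: Linkage) -> "Glycan":
        """Return a new glycan with ``residue`` attached at ``path`` via ``link``."""
        if link.donor_pos != residue.donor_pos:
            raise LinkageError(
                f"{residue} links through C{residue.donor_pos}, not C{link.donor_pos}"
            )
        new_root = self.root.copy()
        g = Glycan(new_root, self.reducing_end_state)
        site = g.node_at(path)
        if site.position_occupied(link.acceptor_pos, link.anomer):
            raise StructureError(
                f"position {link.anomer}{link.acceptor_pos} of {site.residue} occupied"
            )
        site.add_child(GlycanNode(residue, link))
        return g

    def remove(self, path: Sequence) -> "Glycan":
        """Return a new glycan with the terminal residue at ``path`` removed."""
        if not path:
            raise StructureError("cannot remove the reducing-end residue")
        new_root = self.root.copy()
        g = Glycan(new_root, self.reducing_end_state)
        site = g.node_at(path)
        if site.children:
            raise StructureError("cannot remove a non-terminal residue")
        parent = site.parent
        assert parent is not None
        parent.children.remove(site)
        return g

    # -- derived data -----------------------------------------------------
    def composition(self) -> "GlycanComposition":
        counts: Counter = Counter()
        for _path, node in self.walk():
            counts[node.residue.generic_class] += 1
        return GlycanComposition(dict(counts))


@dataclasses.dataclass(frozen=True)
class GlycanComposition:
    """Multiset of generic residue classes."""

    counts: Mapping[GenericClass, int]

    def __post_init__(self) -> None:
        clean = {}
        for k, v in dict(self.counts).items():
            key = k if isinstance(k, GenericClass) else GenericClass(k)
            if v < 0:
                raise StructureError("negative composition count")
            if v:
                clean[key] = int(v)
        if sum(clean.values()) < 1:
            raise StructureError("composition must contain at least one residue")
        object.__setattr__(self, "counts", clean)

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, key) -> int:
        key = key if isinstance(key, GenericClass) else GenericClass(key)
        return self.counts.get(key, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __str__(self) -> str:
        order = [GenericClass.Hex, GenericClass.HexNAc, GenericClass.dHex, GenericClass.NeuAc]
        return "".join(
            f"{c.value}{self.counts[c]}" for c in order if self.counts.get(c)
        )


def single_residue(name: str | Monosaccharide) -> Glycan:
    """Convenience constructor for a one-residue glycan."""
    res = name if isinstance(name, Monosaccharide) else resolve_residue(name)
    return Glycan(GlycanNode(res))
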