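"""Whole-network reconstruction.

Three inference modes build a consolidated :class:`Pathway`:

* :func:`forward_network` — fixed point of product inference from a set of
  seed glycans ("which species can these enzymes make?").
* :func:`reverse_network` — fixed point of substrate inference from a set
  of observed products, pruned to species that actually reach a product.
* :func:`connection_network` — for every unordered pair of input glycans,
  enumerate all reaction chains converting one into the other (the smaller
  is designated the initial substrate with pure-transferase pools; with
  mixed pools both directions are attempted), with intermediate sizes
  bounded by the pair; the union over all ``m*(m-1)/2`` pairs is
  consolidated by removing duplicate species and reactions.

Species are deduplicated by canonical string; reaction identity is the
(substrate, product, enzyme) triple, so two enzymes catalysing the same
conversion contribute two distinct reactions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .enzymes import EnzymeDB, GHEnz, GTEnz
from .glycan import Glycan
from .reactions import Rxn, infer_products, infer_substrates

__all__ = ["Pathway", "forward_network", "reverse_network", "connection_network"]

logger = logging.getLogger(__name__)

#: species role flags
SEED = "seed"
END_PRODUCT = "end_product"
INTERMEDIATE = "inferred_intermediate"


def _named(enzymes, db: Optional[EnzymeDB]) -> list[tuple[str, GTEnz | GHEnz]]:
    """Normalise an enzyme spec (names, records, or pairs) to named records."""
    out = []
    for item in enzymes:
        if isinstance(item, str):
            if db is None:
                raise ValueError("enzyme names require a database")
            out.extend(db.resolve([item]))
        elif isinstance(item, tuple):
            out.append(item)
        else:
            from .reactions import _enzyme_name

            out.append((_enzyme_name(item), item))
    return out


class Pathway:
    """A deduplicated set of glycan species and reactions between them."""

    def __init__(self) -> None:
        self.species: dict[str, Glycan] = {}
        self.reactions: dict[tuple[str, str, str], Rxn] = {}
        self.roles: dict[str, set[str]] = {}
        self.truncated = False  # max_iter exhausted before the fixed point

    # -- construction -----------------------------------------------------
    def add_species(self, g: Glycan, role: Optional[str] = None) -> str:
        key = g.canonical
        self.species.setdefault(key, g)
        flags = self.roles.setdefault(key, set())
        if role:
            flags.add(role)
        return key

    def add_reaction(self, r: Rxn) -> None:
        self.add_species(r.substrate)
        self.add_species(r.product)
        self.reactions.setdefault(r.key, r)

    def merge(self, other: "Pathway") -> None:
        for key, g in other.species.items():
            self.add_species(g)
            self.roles[key] |= other.roles.get(key, set())
        for r in other.reactions.values():
            self.add_reaction(r)
        self.truncated = self.truncated or other.truncated

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_with_role(self, role: str) -> list[str]:
        return sorted(k for k, flags in self.roles.items() if role in flags)

    def substrates_of(self, key: str) -> list[Rxn]:
        return [r for r in self.reactions.values() if r.key[1] == key]

    def products_of(self, key: str) -> list[Rxn]:
        return [r for r in self.reactions.values() if r.key[0] == key]

    def isolated_species(self) -> list[str]:
        """Species participating in no reaction (when any reaction exists)."""
        if not self.reactions:
            return []
        touched = set()
        for s, p, _e in self.reactions:
            touched.add(s)
            touched.add(p)
        return sorted(set(self.species) - touched)

    def __repr__(self) -> str:
        return f"Pathway({self.n_species} species, {self.n_reactions} reactions)"


def forward_network(
    seeds: Sequence[Glycan],
    enzymes: Iterable,
    max_iter: int = 50,
    db: Optional[EnzymeDB] = None,
) -> Pathway:
    """Iterate product inference from ``seeds`` to a fixed point.

    Every enzyme is applied to every known species each round; the loop
    stops when a round adds no new species or reactions, or after
    ``max_iter`` rounds (in which case ``Pathway.truncated`` is set — open
    ended chemistries such as polylactosamine extension never reach a
    fixed point).
    """
    if not seeds:
        raise ValueError("forward_network requires at least one seed glycan")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    named = _named(enzymes, db)
    pw = Pathway()
    for g in sorted(seeds, key=lambda g: g.canonical):
        pw.add_species(g, SEED)
    frontier = sorted(pw.species)
    for _round in range(max_iter):
        new_keys: list[str] = []
        for key in frontier:
            g = pw.species[key]
            for name, enz in named:
                for r in infer_products(enz, g, name=name):
                    fresh = r.product.canonical not in pw.species
                    pw.add_reaction(r)
                    if fresh:
                        new_keys.append(r.product.canonical)
        logger.debug("forward round %d: %d species", _round + 1, pw.n_species)
        if not new_keys:
            break
        frontier = sorted(new_keys)
    else:
        pw.truncated = True
    for key in pw.species:
        if SEED not in pw.roles[key]:
            pw.roles[key].add(INTERMEDIATE)
        if not pw.products_of(key):
            pw.roles[key].add(END_PRODUCT)
    return pw


def reverse_network(
    products: Sequence[Glycan],
    enzymes: Iterable,
    max_iter: int = 50,
    db: Optional[EnzymeDB] = None,
    max_size: Optional[int] = None,
) -> Pathway:
    """Iterate substrate inference backward from observed ``products``.

    With glycosidases in the pool the backward search is open-ended
    (hydrolysis substrates are larger than their products), so ``max_size``
    caps the residue count of candidate substrates; ``None`` leaves the
    search bounded only by ``max_iter``.
    """
    if not products:
        raise ValueError("reverse_network requires at least one product glycan")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    named = _named(enzymes, db)
    pw = Pathway()
    targets = [g.canonical for g in products]
    for g in sorted(products, key=lambda g: g.canonical):
        pw.add_species(g, END_PRODUCT)
    frontier = sorted(pw.species)
    for _round in range(max_iter):
        new_keys: list[str] = []
        for key in frontier:
            g = pw.species[key]
            for name, enz in named:
                for r in infer_substrates(enz, g, name=name):
                    if max_size is not None and len(r.substrate) > max_size:
                        continue
                    fresh = r.substrate.canonical not in pw.species
                    if r.key not in pw.reactions:
                        pw.add_reaction(r)
                        if fresh:
                            new_keys.append(r.substrate.canonical)
        if not new_keys:
            break
        frontier = new_keys
    else:
        pw.truncated = True
    # keep only species that reach at least one input product
    keep = set(targets)
    changed = True
    while changed:
        changed = False
        for (s, p, _e) in list(pw.reactions):
            if p in keep and s not in keep:
                keep.add(s)
                changed = True
    for key in sorted(set(pw.species) - keep):
        del pw.species[key]
        del pw.roles[key]
    pw.reactions = {
        k: r for k, r in pw.reactions.items() if k[0] in keep and k[1] in keep
    }
    for key in pw.species:
        if END_PRODUCT not in pw.roles[key]:
            pw.roles[key].add(INTERMEDIATE)
        if not pw.substrates_of(key):
            pw.roles[key].add(SEED)
    return pw


def _bounded_backward_graph(
    product: Glycan, named, lo: int, hi: int
) -> tuple[dict[str, Glycan], dict[tuple[str, str, str], Rxn]]:
    """All reactions on backward chains from ``product`` with sizes in [lo, hi]."""
    species = {product.canonical: product}
    reactions: dict[tuple[str, str, str], Rxn] = {}
    frontier = [product]
    while frontier:
        nxt = []
        for g in frontier:
            for name, enz in named:
                for r in infer_substrates(enz, g, name=name):
                    n = len(r.substrate)
                    if not (lo <= n <= hi):
                        continue
                    if r.key not in reactions:
                        reactions[r.key] = r
                        skey = r.substrate.canonical
                        if skey not in species:
                            species[skey] = r.substrate
                            nxt.append(r.substrate)
        frontier = nxt
    return species, reactions


def _chain_between(
    substrate: Glycan, product: Glycan, named
) -> Optional[tuple[dict[str, Glycan], dict[tuple[str, str, str], Rxn]]]:
    """Species/reactions on some chain substrate -> product, or None."""
    lo = min(len(substrate), len(product))
    hi = max(len(substrate), len(product))
    species, reactions = _bounded_backward_graph(product, named, lo, hi)
    skey, pkey = substrate.canonical, product.canonical
    if skey not in species:
        return None
    # prune to nodes on a path substrate -> product
    fwd: dict[str, set[str]] = {}
    bwd: dict[str, set[str]] = {}
    for (s, p, _e) in reactions:
        fwd.setdefault(s, set()).add(p)
        bwd.setdefault(p, set()).add(s)

    def reach(start: str, adj) -> set[str]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    on_path = reach(skey, fwd) & reach(pkey, bwd)
    if skey not in on_path or pkey not in on_path:
        return None
    kept_rxns = {
        k: r for k, r in reactions.items() if k[0] in on_path and k[1] in on_path
    }
    kept_species = {k: species[k] for k in on_path}
    return kept_species, kept_rxns


def connection_network(
    glycans: Sequence[Glycan],
    enzymes: Iterable,
    db: Optional[EnzymeDB] = None,
) -> Pathway:
    """Join the input glycans through all enzyme-consistent reaction chains.

    Returns the consolidated pathway; ``pathway.pair_analyses`` records the
    number of pair analyses performed (``m*(m-1)/2`` for ``m`` inputs).
    """
    if len(glycans) < 2:
        raise ValueError("connection_network requires at least two glycans")
    named = _named(enzymes, db)
    has_gt = any(isinstance(e, GTEnz) for _n, e in named)
    has_gh = any(isinstance(e, GHEnz) for _n, e in named)
    mixed = has_gt and has_gh

    inputs = []
    seen = set()
    for g in glycans:
        if g.canonical not in seen:
            seen.add(g.canonical)
            inputs.append(g)

    pw = Pathway()
    for g in inputs:
        pw.add_species(g)
    pairs = 0
    for i in range(len(inputs)):
        for j in range(i + 1, len(inputs)):
            pairs += 1
            small, large = sorted((inputs[i], inputs[j]), key=len)
            # the enzyme pool's net direction designates the initial
            # substrate: transferases grow the smaller into the larger,
            # glycosidases trim the larger into the smaller; with a mixed
            # pool both designations are attempted
            if has_gt and not has_gh:
                attempts = [(small, large)]
            elif has_gh and not has_gt:
                attempts = [(large, small)]
            else:
                attempts = [(small, large), (large, small)]
            for substrate, product in attempts:
                found = _chain_between(substrate, product, named)
                if found is not None:
                    species, reactions = found
                    for g in species.values():
                        pw.add_species(g)
                    for r in reactions.values():
                        pw.add_reaction(r)
                    pw.add_species(substrate, SEED)
                    pw.add_species(product, END_PRODUCT)
                    break
            logger.debug("pair %d/%d analysed", pairs, len(inputs) * (len(inputs) - 1) // 2)
    pw.pair_analyses = pairs  # type: ignore[attr-defined]
    input_keys = {g.canonical for g in inputs}
    for key in pw.species:
        if key not in input_keys:
            pw.roles[key].add(INTERMEDIATE)
    return pw
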