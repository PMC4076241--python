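"""Machine-readable glycoenzyme definitions.

The class hierarchy mirrors the biochemical one: a generic enzyme
(:class:`Enz`) is specialised into transferases (:class:`TfEnz`) and
hydrolases (:class:`HlEnz`), which are in turn specialised into the
glycan-aware glycosyltransferase (:class:`GTEnz`) and glycosidase
(:class:`GHEnz`) classes.  ``GTEnz``/``GHEnz`` carry the substrate
specificity fields that drive reaction inference:

==================  =====================================================
resfuncgroup        residue transferred (GT) or cleaved (GH) — obligatory
linkFG              linkage formed/broken — obligatory; a GH may list
                    several linkages in order of preference
resAtt2FG           residue to which the functional group attaches
linkAtt2FG          that residue's own linkage to its parent
targetBranch        ancestor chain the acted-on residue must sit on
acceptor_context    subtree the acted-on residue must already carry
substNAResidue      residues whose presence anywhere blocks the enzyme
substNABranch       reducing-end-anchored motifs whose presence blocks
substMinStruct      reducing-end-anchored motif the substrate must carry
==================  =====================================================

A built-in database of 14 enzymes (12 glycosyltransferases, 2
glycosidases) covering O-linked core-2 elaboration and N-linked antennary
processing ships with the package; databases round-trip through a simple
stanza text format (see :func:`load_db`/:func:`save_db`).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .glycan import Linkage
from .linear import parse_linear, write_linear
from .motif import GlycanMotif
from .residues import Monosaccharide, resolve_residue

__all__ = [
    "Enz",
    "TfEnz",
    "HlEnz",
    "GTEnz",
    "GHEnz",
    "EnzymeDB",
    "EnzymeSchemaError",
    "builtin_database",
    "load_db",
    "save_db",
]


class EnzymeSchemaError(ValueError):
    pass


def _motif_branch(text: str) -> GlycanMotif:
    """A reducing-end-anchored motif from linear notation."""
    return GlycanMotif(parse_linear(text), anchor="at_reducing_end")


def _motif_target(text: str, to_root: bool = False) -> GlycanMotif:
    """A targetBranch motif: linear chain, acted-on residue first."""
    return GlycanMotif(
        parse_linear(text),
        anchor="at_target_residue",
        direction="toward_root",
        to_root=to_root,
    )


def _motif_context(text: str) -> GlycanMotif:
    """An acceptor-context motif matched into the acted-on residue's subtree."""
    return GlycanMotif(
        parse_linear(text), anchor="at_target_residue", direction="toward_leaves"
    )


@dataclasses.dataclass(kw_only=True)
class Enz:
    """Generic enzyme record (EC number, names, reaction description)."""

    ecno: tuple[int, int, int, int]
    name_systematic: str = ""
    name_recommended: str = ""
    names_alternative: tuple[str, ...] = ()
    reaction_description: str = ""

    def __post_init__(self) -> None:
        self.ecno = tuple(int(x) for x in self.ecno)  # type: ignore[assignment]
        if len(self.ecno) != 4:
            raise EnzymeSchemaError("ecno must have exactly 4 fields")
        if self.ecno[0] not in (2, 3):
            raise EnzymeSchemaError(
                "only transferases (EC 2) and hydrolases (EC 3) are supported"
            )


@dataclasses.dataclass(kw_only=True)
class TfEnz(Enz):
    """Transferase: donor + acceptor descriptions."""

    donor: str = ""
    acceptor: str = ""
    donorprod: str = ""
    acceptorprod: str = ""


@dataclasses.dataclass(kw_only=True)
class HlEnz(Enz):
    """Hydrolase: the two hydrolysis products."""

    prod_h: str = ""
    prod_oh: str = ""


@dataclasses.dataclass(kw_only=True)
class GTEnz(TfEnz):
    """Glycosyltransferase with structural substrate-specificity fields."""

    resfuncgroup: Monosaccharide
    linkFG: Linkage
    resAtt2FG: Optional[Monosaccharide] = None
    linkAtt2FG: Optional[Linkage] = None
    targetBranch: Optional[GlycanMotif] = None
    acceptor_context: Optional[GlycanMotif] = None
    substNAResidue: tuple[Monosaccharide, ...] = ()
    substNABranch: tuple[GlycanMotif, ...] = ()
    substMinStruct: Optional[GlycanMotif] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.donor:
            raise EnzymeSchemaError("glycosyltransferase requires a sugar-nucleotide donor")
        if self.linkFG.donor_pos != self.resfuncgroup.donor_pos:
            raise EnzymeSchemaError(
                f"{self.resfuncgroup} links through C{self.resfuncgroup.donor_pos}"
            )


@dataclasses.dataclass(kw_only=True)
class GHEnz(HlEnz):
    """Glycosidase; ``linkFG`` is an ordered tuple of cleavable linkages."""

    resfuncgroup: Monosaccharide
    linkFG: tuple[Linkage, ...]
    resAtt2FG: Optional[Monosaccharide] = None
    linkAtt2FG: Optional[Linkage] = None
    targetBranch: Optional[GlycanMotif] = None
    substNAResidue: tuple[Monosaccharide, ...] = ()
    substNABranch: tuple[GlycanMotif, ...] = ()
    substMinStruct: Optional[GlycanMotif] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if isinstance(self.linkFG, Linkage):
            self.linkFG = (self.linkFG,)
        if not self.linkFG:
            raise EnzymeSchemaError("glycosidase requires at least one linkFG linkage")


class EnzymeDB:
    """Collection of enzymes addressable by short name or alternative name."""

    def __init__(self, records: dict[str, GTEnz | GHEnz] | None = None) -> None:
        self.records: dict[str, GTEnz | GHEnz] = {}
        for name, enz in (records or {}).items():
            self.add(name, enz)

    def add(self, name: str, enz: GTEnz | GHEnz) -> None:
        if name in self.records:
            raise EnzymeSchemaError(f"duplicate enzyme short name {name!r}")
        self.records[name] = enz

    def __getitem__(self, name: str) -> GTEnz | GHEnz:
        if name in self.records:
            return self.records[name]
        for short, enz in self.records.items():
            if name in enz.names_alternative:
                return enz
        raise KeyError(f"no enzyme named {name!r}")

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
            return True
        except KeyError:
            return False

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, names) -> list[tuple[str, GTEnz | GHEnz]]:
        """Resolve short/alternative names to ``(short_name, record)`` pairs."""
        out = []
        for name in names:
            enz = self[name]
            short = next(s for s, e in self.records.items() if e is enz)
            out.append((short, enz))
        return out


# ---------------------------------------------------------------------------
# Built-in database
# ---------------------------------------------------------------------------

# Reducing-end-anchored chain marking the bisecting GlcNAc on the N-glycan
# core: its presence shuts down ManII and GnT II/IV/V.
_BISECT = "GlcNAc(b1,4)Man(b1,4)GlcNAc(b1,4)GlcNAc"
# Untrimmed 6-arm (either remaining mannose) — blocks GnT II.
_SIXARM_MAN_A3 = "Man(a1,3)Man(a1,6)Man(b1,4)GlcNAc(b1,4)GlcNAc"
_SIXARM_MAN_A6 = "Man(a1,6)Man(a1,6)Man(b1,4)GlcNAc(b1,4)GlcNAc"
# Products marking completed earlier steps.
_GNT1_PRODUCT = "GlcNAc(b1,2)Man(a1,3)Man(b1,4)GlcNAc(b1,4)GlcNAc"
_GNT2_PRODUCT = "GlcNAc(b1,2)Man(a1,6)Man(b1,4)GlcNAc(b1,4)GlcNAc"


def builtin_database() -> EnzymeDB:
    """The 14-enzyme database (12 glycosyltransferases, 2 glycosidases).

    The N-glycan branching rules (GnT I–V, ManII, GalT) encode the classic
    antennary-processing constraints: the bisecting GlcNAc blocks ManII and
    GnT II/IV/V; GnT II requires the fully trimmed 6-arm; GnT IV/V require
    the GnT II product; galactosylation caps GnT and ManII action.  The
    O-glycan set (GalT-IV, B3GnT, ST3Gal-I/II, ST3Gal-IV, FT-VII) covers
    core-2 elaboration up to sialyl-Lewis-X.
    """
    db = EnzymeDB()
    GlcNAc, Gal, Man, Fuc, Neu = (
        Monosaccharide.GlcNAc,
        Monosaccharide.Gal,
        Monosaccharide.Man,
        Monosaccharide.Fuc,
        Monosaccharide.Neu5Ac,
    )
    L = Linkage.parse

    db.add(
        "GnTI",
        GTEnz(
            ecno=(2, 4, 1, 101),
            name_recommended="alpha-1,3-mannosyl-glycoprotein 2-beta-N-acetylglucosaminyltransferase",
            names_alternative=("GnT-I", "MGAT1"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,2"),
            resAtt2FG=Man,
            linkAtt2FG=L("a1,3"),
            targetBranch=_motif_target("Man(a1,3)Man(b1,4)GlcNAc(b1,4)GlcNAc"),
            substNAResidue=(Gal, Neu),
            substNABranch=(_motif_branch(_BISECT),),
        ),
    )
    db.add(
        "GnTII",
        GTEnz(
            ecno=(2, 4, 1, 143),
            name_recommended="alpha-1,6-mannosyl-glycoprotein 2-beta-N-acetylglucosaminyltransferase",
            names_alternative=("GnT-II", "MGAT2"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,2"),
            resAtt2FG=Man,
            linkAtt2FG=L("a1,6"),
            targetBranch=_motif_target("Man(a1,6)Man(b1,4)GlcNAc(b1,4)GlcNAc"),
            substNAResidue=(Gal,),
            substNABranch=(
                _motif_branch(_BISECT),
                _motif_branch(_SIXARM_MAN_A3),
                _motif_branch(_SIXARM_MAN_A6),
            ),
            substMinStruct=_motif_branch(_GNT1_PRODUCT),
        ),
    )
    db.add(
        "GnTIII",
        GTEnz(
            ecno=(2, 4, 1, 144),
            name_recommended="beta-1,4-mannosyl-glycoprotein 4-beta-N-acetylglucosaminyltransferase",
            names_alternative=("GnT-III", "MGAT3"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,4"),
            resAtt2FG=Man,
            linkAtt2FG=L("b1,4"),
            targetBranch=_motif_target("Man(b1,4)GlcNAc(b1,4)GlcNAc"),
            substNAResidue=(Gal,),
            substMinStruct=_motif_branch(_GNT1_PRODUCT),
        ),
    )
    db.add(
        "GnTIV",
        GTEnz(
            ecno=(2, 4, 1, 145),
            name_recommended="alpha-1,3-mannosyl-glycoprotein 4-beta-N-acetylglucosaminyltransferase",
            names_alternative=("GnT-IV", "MGAT4"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,4"),
            resAtt2FG=Man,
            linkAtt2FG=L("a1,3"),
            targetBranch=_motif_target("Man(a1,3)Man(b1,4)GlcNAc(b1,4)GlcNAc"),
            substNAResidue=(Gal,),
            substNABranch=(_motif_branch(_BISECT),),
            substMinStruct=_motif_branch(_GNT2_PRODUCT),
        ),
    )
    db.add(
        "GnTV",
        GTEnz(
            ecno=(2, 4, 1, 155),
            name_recommended="alpha-1,6-mannosyl-glycoprotein 6-beta-N-acetylglucosaminyltransferase",
            names_alternative=("GnT-V", "MGAT5"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,6"),
            resAtt2FG=Man,
            linkAtt2FG=L("a1,6"),
            targetBranch=_motif_target("Man(a1,6)Man(b1,4)GlcNAc(b1,4)GlcNAc"),
            substNAResidue=(Gal,),
            substNABranch=(_motif_branch(_BISECT),),
            substMinStruct=_motif_branch(_GNT2_PRODUCT),
        ),
    )
    db.add(
        "ManI",
        GHEnz(
            ecno=(3, 2, 1, 113),
            name_recommended="mannosyl-oligosaccharide 1,2-alpha-mannosidase",
            names_alternative=("Man-I",),
            resfuncgroup=Man,
            linkFG=(L("a1,2"),),
            resAtt2FG=Man,
        ),
    )
    db.add(
        "ManII",
        GHEnz(
            ecno=(3, 2, 1, 114),
            name_recommended="mannosyl-oligosaccharide 1,3-1,6-alpha-mannosidase",
            names_alternative=("Man-II",),
            resfuncgroup=Man,
            linkFG=(L("a1,3"), L("a1,6")),  # ordered preference: a1,3 first
            resAtt2FG=Man,
            linkAtt2FG=L("a1,6"),
            substNAResidue=(Gal,),
            substNABranch=(_motif_branch(_BISECT),),
            substMinStruct=_motif_branch(_GNT1_PRODUCT),
        ),
    )
    db.add(
        "GalT",
        GTEnz(
            ecno=(2, 4, 1, 38),
            name_recommended="beta-N-acetylglucosaminylglycopeptide beta-1,4-galactosyltransferase",
            names_alternative=("GalT-I", "B4GALT1"),
            donor="UDP-Gal",
            resfuncgroup=Gal,
            linkFG=L("b1,4"),
            resAtt2FG=GlcNAc,
            # restricted to the GlcNAc on the lower (a1,3) antenna
            targetBranch=_motif_target(_GNT1_PRODUCT),
        ),
    )
    db.add(
        "GalT-IV",
        GTEnz(
            ecno=(2, 4, 1, 90),
            name_recommended="N-acetyllactosamine synthase",
            names_alternative=("B4GALT4",),
            donor="UDP-Gal",
            resfuncgroup=Gal,
            linkFG=L("b1,4"),
            resAtt2FG=GlcNAc,
        ),
    )
    db.add(
        "B3GnT",
        GTEnz(
            ecno=(2, 4, 1, 149),
            name_recommended="N-acetyllactosaminide beta-1,3-N-acetylglucosaminyltransferase",
            names_alternative=("beta3GlcNAc-T", "b3GnT"),
            donor="UDP-GlcNAc",
            resfuncgroup=GlcNAc,
            linkFG=L("b1,3"),
            resAtt2FG=Gal,
        ),
    )
    db.add(
        "ST3Gal-I/II",
        GTEnz(
            ecno=(2, 4, 99, 4),
            name_recommended="beta-galactoside alpha-2,3-sialyltransferase (core 1)",
            names_alternative=("ST3GalI", "ST3GalII"),
            donor="CMP-Neu5Ac",
            resfuncgroup=Neu,
            linkFG=L("a2,3"),
            resAtt2FG=Gal,
            linkAtt2FG=L("b1,3"),
            targetBranch=_motif_target("Gal(b1,3)GalNAc"),
        ),
    )
    db.add(
        "ST3Gal-IV",
        GTEnz(
            ecno=(2, 4, 99, 6),
            name_recommended="N-acetyllactosaminide alpha-2,3-sialyltransferase",
            names_alternative=("ST3GalIV", "SiaT"),
            donor="CMP-Neu5Ac",
            resfuncgroup=Neu,
            linkFG=L("a2,3"),
            resAtt2FG=Gal,
            linkAtt2FG=L("b1,4"),
            targetBranch=_motif_target("Gal(b1,4)GlcNAc"),
        ),
    )
    db.add(
        "FT-VII",
        GTEnz(
            ecno=(2, 4, 1, 152),
            name_recommended="4-galactosyl-N-acetylglucosaminide 3-alpha-L-fucosyltransferase",
            names_alternative=("FucT-VII", "FUT7"),
            donor="GDP-Fuc",
            resfuncgroup=Fuc,
            linkFG=L("a1,3"),
            resAtt2FG=GlcNAc,
            # only GlcNAc whose own galactose is already a2,3-sialylated
            acceptor_context=_motif_context("Neu5Ac(a2,3)Gal(b1,4)GlcNAc"),
        ),
    )
    db.add(
        "FucT",
        GTEnz(
            ecno=(2, 4, 1, 68),
            name_recommended="glycoprotein 6-alpha-L-fucosyltransferase",
            names_alternative=("FUT8", "core-FucT"),
            donor="GDP-Fuc",
            resfuncgroup=Fuc,
            linkFG=L("a1,6"),
            resAtt2FG=GlcNAc,
            targetBranch=_motif_target("GlcNAc", to_root=True),
            substMinStruct=_motif_branch(_GNT1_PRODUCT),
        ),
    )
    return db


# ---------------------------------------------------------------------------
# Stanza text format
# ---------------------------------------------------------------------------

_GLYCAN_FIELDS = ("targetBranch", "acceptor_context", "substNABranch", "substMinStruct")


def _format_motif(m: GlycanMotif) -> str:
    return write_linear(m.pattern)


def save_db(db: EnzymeDB, path) -> None:
    """Write a database to the stanza text format."""
    lines: list[str] = []
    for name, e in db.records.items():
        lines.append(f"[{name}]")
        lines.append(f"class: {'GT' if isinstance(e, GTEnz) else 'GH'}")
        lines.append("ecno: " + ".".join(str(x) for x in e.ecno))
        if e.name_systematic:
            lines.append(f"name_systematic: {e.name_systematic}")
        if e.name_recommended:
            lines.append(f"name_recommended: {e.name_recommended}")
        if e.names_alternative:
            lines.append("names_alternative: " + "; ".join(e.names_alternative))
        if e.reaction_description:
            lines.append(f"reaction: {e.reaction_description}")
        if isinstance(e, GTEnz):
            lines.append(f"donor: {e.donor}")
            lines.append(f"resfuncgroup: {e.resfuncgroup}")
            lines.append(f"linkFG: {e.linkFG}")
        else:
            lines.append(f"resfuncgroup: {e.resfuncgroup}")
            lines.append("linkFG: " + "; ".join(str(l) for l in e.linkFG))
        if e.resAtt2FG is not None:
            lines.append(f"resAtt2FG: {e.resAtt2FG}")
        if e.linkAtt2FG is not None:
            lines.append(f"linkAtt2FG: {e.linkAtt2FG}")
        if e.targetBranch is not None:
            lines.append(f"targetBranch: {_format_motif(e.targetBranch)}")
            if e.targetBranch.to_root:
                lines.append("targetBranchToRoot: true")
        if isinstance(e, GTEnz) and e.acceptor_context is not None:
            lines.append(f"acceptor_context: {_format_motif(e.acceptor_context)}")
        if e.substNAResidue:
            lines.append("substNAResidue: " + "; ".join(str(r) for r in e.substNAResidue))
        if e.substNABranch:
            lines.append(
                "substNABranch: " + "; ".join(_format_motif(m) for m in e.substNABranch)
            )
        if e.substMinStruct is not None:
            lines.append(f"substMinStruct: {_format_motif(e.substMinStruct)}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def load_db(path) -> EnzymeDB:
    """Load a database from the stanza text format."""
    with open(path) as fh:
        text = fh.read()
    db = EnzymeDB()
    stanza: dict[str, str] = {}
    name: Optional[str] = None
    for raw in text.splitlines() + ["[end]"]:
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        if line.startswith("["):
            if name is not None:
                db.add(name, _record_from_stanza(name, stanza))
            name = line.strip("[]").strip()
            stanza = {}
        else:
            if ":" not in line:
                raise EnzymeSchemaError(f"bad stanza line {line!r}")
            key, _, value = line.partition(":")
            stanza[key.strip()] = value.strip()
    return db


def _record_from_stanza(name: str, s: dict[str, str]) -> GTEnz | GHEnz:
    cls = s.get("class")
    if cls not in ("GT", "GH"):
        raise EnzymeSchemaError(f"enzyme {name}: class must be GT or GH")
    for field in ("resfuncgroup", "linkFG"):
        if field not in s:
            raise EnzymeSchemaError(f"enzyme {name}: missing obligatory field {field!r}")
    try:
        common = dict(
            ecno=tuple(int(x) for x in s.get("ecno", "0.0.0.0").split(".")),
            name_systematic=s.get("name_systematic", ""),
            name_recommended=s.get("name_recommended", ""),
            names_alternative=tuple(
                x.strip() for x in s.get("names_alternative", "").split(";") if x.strip()
            ),
            reaction_description=s.get("reaction", ""),
            resfuncgroup=resolve_residue(s["resfuncgroup"]),
            resAtt2FG=resolve_residue(s["resAtt2FG"]) if "resAtt2FG" in s else None,
            linkAtt2FG=Linkage.parse(s["linkAtt2FG"]) if "linkAtt2FG" in s else None,
            targetBranch=(
                _motif_target(
                    s["targetBranch"],
                    to_root=s.get("targetBranchToRoot", "").lower() == "true",
                )
                if "targetBranch" in s
                else None
            ),
            substNAResidue=tuple(
                resolve_residue(x.strip())
                for x in s.get("substNAResidue", "").split(";")
                if x.strip()
            ),
            substNABranch=tuple(
                _motif_branch(x.strip())
                for x in s.get("substNABranch", "").split(";")
                if x.strip()
            ),
            substMinStruct=(
                _motif_branch(s["substMinStruct"]) if "substMinStruct" in s else None
            ),
        )
        if cls == "GT":
            return GTEnz(
                donor=s.get("donor", ""),
                acceptor=s.get("acceptor", ""),
                donorprod=s.get("donorprod", ""),
                acceptorprod=s.get("acceptorprod", ""),
                linkFG=Linkage.parse(s["linkFG"]),
                acceptor_context=(
                    _motif_context(s["acceptor_context"])
                    if "acceptor_context" in s
                    else None
                ),
                **common,
            )
        return GHEnz(
            prod_h=s.get("prod_h", ""),
            prod_oh=s.get("prod_oh", ""),
            linkFG=tuple(
                Linkage.parse(x.strip()) for x in s["linkFG"].split(";") if x.strip()
            ),
            **common,
        )
    except (ValueError, KeyError) as exc:
        if isinstance(exc, EnzymeSchemaError):
            raise
        raise EnzymeSchemaError(f"enzyme {name}: {exc}") from exc
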