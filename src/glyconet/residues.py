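"""Monosaccharide residues and their generic classes.

Only the eight residues that occur in mammalian N- and O-glycan
biosynthesis handled by this package are supported.  Each residue maps to
exactly one generic composition class (Hex, HexNAc, dHex, NeuAc) used for
composition counting and mass-spectrometric annotation.
"""

from __future__ import annotations

import enum


class GenericClass(str, enum.Enum):
    """Generic monosaccharide class used in composition counting."""

    Hex = "Hex"
    HexNAc = "HexNAc"
    dHex = "dHex"
    NeuAc = "NeuAc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Monosaccharide(str, enum.Enum):
    """Enumerated residue names.

    ``donor_pos`` is the anomeric carbon through which the residue links to
    its parent (C2 for sialic acid, C1 for everything else).
    """

    Glc = "Glc"
    Gal = "Gal"
    Man = "Man"
    GlcNAc = "GlcNAc"
    GalNAc = "GalNAc"
    Fuc = "Fuc"
    Neu5Ac = "Neu5Ac"
    Xyl = "Xyl"

    @property
    def generic_class(self) -> GenericClass:
        return _GENERIC[self]

    @property
    def donor_pos(self) -> int:
        return 2 if self is Monosaccharide.Neu5Ac else 1

    def __str__(self) -> str:
        return self.value


_GENERIC = {
    Monosaccharide.Glc: GenericClass.Hex,
    Monosaccharide.Gal: GenericClass.Hex,
    Monosaccharide.Man: GenericClass.Hex,
    Monosaccharide.GlcNAc: GenericClass.HexNAc,
    Monosaccharide.GalNAc: GenericClass.HexNAc,
    Monosaccharide.Fuc: GenericClass.dHex,
    Monosaccharide.Neu5Ac: GenericClass.NeuAc,
    Monosaccharide.Xyl: GenericClass.Hex,
}


def resolve_residue(name: str) -> Monosaccharide:
    """Look up a residue by name, raising ``KeyError`` with the bad token."""
    try:
        return Monosaccharide(name)
    except ValueError:
        raise KeyError(f"unknown monosaccharide {name!r}") from None
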