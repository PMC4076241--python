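"""Glycan tree structure, notation round trips and canonicalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glyconet as gn
from glyconet.glycan import Linkage, StructureError
from glyconet.residues import Monosaccharide
from glyconet.simulate import random_glycan, shuffled_copy

CORE2 = "Gal(b1,3)[GlcNAc(b1,6)]GalNAc"
SLEX = "Neu5Ac(a2,3)Gal(b1,4)[Fuc(a1,3)]GlcNAc"


def brute_force_isomorphic(a, b) -> bool:
    """Tree isomorphism by exhaustive child-permutation matching."""

    def links_equal(x, y):
        if (x is None) != (y is None):
            return False
        return x is None or (x.anomer, x.donor_pos, x.acceptor_pos) == (
            y.anomer,
            y.donor_pos,
            y.acceptor_pos,
        )

    def match(na, nb):
        if na.residue != nb.residue or not links_equal(na.parent_link, nb.parent_link):
            return False
        if len(na.children) != len(nb.children):
            return False

        def assign(i, used):
            if i == len(na.children):
                return True
            for j, cb in enumerate(nb.children):
                if not used & (1 << j) and match(na.children[i], cb):
                    if assign(i + 1, used | (1 << j)):
                        return True
            return False

        return assign(0, 0)

    return match(a.root, b.root)


class TestLinearNotation:
    def test_core2_trisaccharide_shape(self):
        g = gn.parse_linear(CORE2)
        assert len(g) == 3
        assert g.root.residue is Monosaccharide.GalNAc
        assert len(g.root.children) == 2

    def test_singleton(self):
        g = gn.parse_linear("Man")
        assert len(g) == 1 and not g.root.children

    def test_linkage_text_round_trip(self):
        for text in ("b1,4", "a2,3", "?1,?", "b1,?"):
            assert str(Linkage.parse(text)) == text
        # Greek anomers are accepted on input
        assert str(Linkage.parse("β1,4")) == "b1,4"
        assert str(Linkage.parse("α2,3")) == "a2,3"

    @pytest.mark.parametrize(
        "bad, fragment",
        [
            ("Gal(b1,3)[GlcNAc(b1,6)GalNAc", "unclosed"),
            ("Frobnose", "unknown monosaccharide"),
            ("Gal(q1,3)GalNAc", "anomer"),
            ("", "empty"),
            ("Gal GalNAc", "lacks a linkage"),
        ],
    )
    def test_parse_errors_name_the_problem(self, bad, fragment):
        with pytest.raises(ValueError, match=fragment):
            gn.parse_linear(bad)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_random_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        g = random_glycan(rng, n_residues=int(rng.integers(1, 9)), p_undetermined=0.2)
        assert gn.parse_linear(gn.write_linear(g)) == g


class TestCanonicalString:
    def test_sibling_order_invariance(self):
        a = gn.parse_linear("Gal(b1,4)[Fuc(a1,3)]GlcNAc")
        b = gn.parse_linear("Fuc(a1,3)[Gal(b1,4)]GlcNAc")
        assert a.canonical == b.canonical

    def test_distinct_isomers_distinct_strings(self):
        a = gn.parse_linear("Gal(b1,3)GalNAc")
        b = gn.parse_linear("Gal(b1,4)GalNAc")
        assert a.canonical != b.canonical

    def test_undetermined_is_not_determined(self):
        a = gn.parse_linear("Gal(b1,3)GalNAc")
        b = gn.parse_linear("Gal(b1,?)GalNAc")
        c = gn.parse_linear("Gal(?1,3)GalNAc")
        assert len({a.canonical, b.canonical, c.canonical}) == 3

    def test_corpus_against_isomorphism_oracle(self, rng):
        """Canonical equality must coincide with brute-force isomorphism."""
        corpus = [
            random_glycan(rng, n_residues=int(rng.integers(2, 8)), p_undetermined=0.1)
            for _ in range(100)
        ]
        canon = {}
        for g in corpus:
            for _ in range(5):
                assert shuffled_copy(rng, g).canonical == g.canonical
            canon.setdefault(g.canonical, g)
        keys = sorted(canon)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                assert not brute_force_isomorphic(canon[ka], canon[kb])
        for g in corpus:
            assert brute_force_isomorphic(g, canon[g.canonical])


class TestEdits:
    def test_attach_adds_one_residue_and_preserves_input(self):
        g = gn.parse_linear(CORE2)
        before = g.canonical
        site = next(p for p, n in g.walk() if n.residue is Monosaccharide.GlcNAc)
        g2 = g.attach(site, Monosaccharide.Gal, Linkage.parse("b1,4"))
        assert len(g2) == len(g) + 1
        assert g.canonical == before  # value semantics

    def test_attach_occupied_position_fails(self):
        g = gn.parse_linear(CORE2)
        with pytest.raises(StructureError, match="occupied"):
            g.attach((), Monosaccharide.Gal, Linkage.parse("b1,3"))

    def test_attach_then_remove_is_identity(self, rng):
        for _ in range(20):
            g = random_glycan(rng, n_residues=5)
            node_paths = [p for p, _n in g.walk()]
            site = node_paths[int(rng.integers(len(node_paths)))]
            try:
                g2 = g.attach(site, Monosaccharide.Fuc, Linkage.parse("a1,3"))
            except StructureError:
                continue
            new_path = next(
                p
                for p, n in g2.walk()
                if len(p) == len(site) + 1
                and p[: len(site)] == site
                and n.residue is Monosaccharide.Fuc
                and n.is_terminal()
            )
            assert g2.remove(new_path) == g

    def test_remove_internal_or_root_fails(self):
        g = gn.parse_linear("Gal(b1,3)GalNAc")
        with pytest.raises(StructureError):
            g.remove(())  # root
        g3 = gn.parse_linear("Neu5Ac(a2,3)Gal(b1,3)GalNAc")
        internal = next(
            p for p, n in g3.walk() if n.residue is Monosaccharide.Gal
        )
        with pytest.raises(StructureError, match="non-terminal"):
            g3.remove(internal)


class TestComposition:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (SLEX, {"Hex": 1, "HexNAc": 1, "dHex": 1, "NeuAc": 1}),
            ("Man", {"Hex": 1}),
            (
                "GlcNAc(b1,2)Man(a1,3)[Man(a1,3)[Man(a1,6)]Man(a1,6)]"
                "Man(b1,4)GlcNAc(b1,4)GlcNAc",
                {"Hex": 5, "HexNAc": 3},
            ),
        ],
    )
    def test_known_compositions(self, text, expected):
        comp = gn.parse_linear(text).composition()
        assert {str(k): v for k, v in comp} == expected

    def test_composition_tracks_attachment(self, rng):
        g = random_glycan(rng, n_residues=4)
        link = Linkage.parse("b1,2")
        while g.root.position_occupied(link.acceptor_pos, link.anomer):
            g = random_glycan(rng, n_residues=4)
        g2 = g.attach((), Monosaccharide.Xyl, link)
        base = dict(g.composition())
        grown = dict(g2.composition())
        base[Monosaccharide.Xyl.generic_class] = (
            base.get(Monosaccharide.Xyl.generic_class, 0) + 1
        )
        assert grown == base
        assert g2.composition().total() == len(g) + 1
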