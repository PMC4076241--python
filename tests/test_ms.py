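"""Spectrum ingestion, four-step peak processing, composition annotation."""

import itertools

import numpy as np
import pytest

import glyconet as gn
from glyconet.ms import (
    Peak,
    PeakList,
    Spectrum,
    annotate_compositions,
    composition_mz,
    ms_process,
    read_ms,
    synth_spectrum,
    write_ms,
)
from glyconet.residues import GenericClass


class TestReadMs:
    def test_three_line_file(self, tmp_path):
        f = tmp_path / "tiny.msd"
        f.write_text("1500 0\n1500.1 10\n1500.2 0\n")
        s = read_ms(f)
        assert len(s) == 3

    def test_unsorted_rows_are_sorted(self, tmp_path):
        f = tmp_path / "rev.msd"
        f.write_text("1500.2 1\n1500.0 2\n1500.1 3\n")
        s = read_ms(f)
        assert list(s.mz) == [1500.0, 1500.1, 1500.2]
        assert sorted(s.intensity) == [1, 2, 3]

    def test_comma_delimited_and_comments(self, tmp_path):
        f = tmp_path / "c.msd"
        f.write_text("# a comment\n1500,5\n1501, 6\n")
        assert len(read_ms(f)) == 2

    def test_non_numeric_row_names_line(self, tmp_path):
        f = tmp_path / "bad.msd"
        f.write_text("1500 1\nbogus row\n")
        with pytest.raises(ValueError, match="line 2"):
            read_ms(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.msd"
        f.write_text("# nothing\n")
        with pytest.raises(ValueError, match="no data"):
            read_ms(f)

    def test_writer_reader_round_trip(self, tmp_path, rng):
        mz = np.sort(rng.uniform(1500, 3000, 100))
        mz = np.unique(mz)
        s = Spectrum(mz, rng.uniform(0, 50, mz.size))
        f = tmp_path / "rt.msd"
        write_ms(s, f)
        back = read_ms(f)
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-6)
        np.testing.assert_allclose(back.intensity, s.intensity, atol=1e-6)


FIVE_COMPS = [
    {"Hex": 5, "HexNAc": 2},
    {"Hex": 5, "HexNAc": 3},
    {"Hex": 5, "HexNAc": 4},
    {"Hex": 5, "HexNAc": 4, "dHex": 1},
    {"Hex": 5, "HexNAc": 4, "dHex": 1, "NeuAc": 1},
]


class TestMsProcess:
    def test_five_gaussians_recovered(self):
        spec, truth = synth_spectrum(
            FIVE_COMPS, [40, 60, 80, 100, 50], noise_sigma=2.0, seed=7
        )
        pl = ms_process(spec)
        assert len(pl) == 5
        for (center, _h), peak in zip(truth, pl):
            assert abs(peak.centroid_mz - center) < 0.1
            assert 0.2 < peak.fwhm < 0.6  # 2.355 * sigma = 0.35 Th

    def test_flat_zero_spectrum(self):
        mz = np.arange(1500, 1600, 0.05)
        pl = ms_process(Spectrum(mz, np.zeros_like(mz)))
        assert list(pl) == []

    def test_intensity_scaling_invariance(self):
        spec, _ = synth_spectrum(FIVE_COMPS, [40, 60, 80, 100, 50], noise_sigma=1.0, seed=3)
        a = ms_process(spec)
        b = ms_process(Spectrum(spec.mz, spec.intensity * 1000.0))
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert abs(pa.centroid_mz - pb.centroid_mz) < 1e-9
            assert abs(pa.height - pb.height) < 1e-6

    def test_constant_offset_invariance(self):
        spec, _ = synth_spectrum(FIVE_COMPS, [40, 60, 80, 100, 50], noise_sigma=1.0, seed=3)
        a = ms_process(spec)
        b = ms_process(Spectrum(spec.mz, spec.intensity + 25.0))
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert abs(pa.centroid_mz - pb.centroid_mz) < 0.02

    def test_recall_and_fdr_on_seeded_replicates(self):
        """Peak recall >= 0.9 and FDR <= 0.1 at SNR >= 10, 20 replicates."""
        heights = np.linspace(20, 100, 12)
        comps = [{"Hex": 4 + i, "HexNAc": 2} for i in range(6)] + [
            {"Hex": 4 + i, "HexNAc": 3, "dHex": 1} for i in range(6)
        ]
        noise = min(heights) / 10.0  # SNR exactly 10 for the weakest peak
        recalls, fdrs = [], []
        for seed in range(20):
            spec, truth = synth_spectrum(
                comps, heights, mz_range=(1300.0, 3300.0), noise_sigma=noise, seed=seed
            )
            pl = ms_process(spec)
            t = np.array([x[0] for x in truth])
            f = pl.centroids
            recalls.append(
                sum(1 for x in t if f.size and np.min(np.abs(f - x)) < 0.2) / t.size
            )
            fdrs.append(
                sum(1 for x in f if np.min(np.abs(t - x)) > 0.2) / max(1, f.size)
            )
        assert np.mean(recalls) >= 0.9
        assert np.mean(fdrs) <= 0.1

    def test_two_seeds_same_truth_different_noise(self):
        a, truth_a = synth_spectrum(FIVE_COMPS, [40, 60, 80, 100, 50], seed=1)
        b, truth_b = synth_spectrum(FIVE_COMPS, [40, 60, 80, 100, 50], seed=2)
        assert truth_a == truth_b
        assert not np.allclose(a.intensity, b.intensity)


class TestCompositionMass:
    def test_hex5hexnac2_permethylated_sodiated(self):
        """Independent mass oracle: sum residue formulas from atomic masses."""
        H, C, N, O, Na, e = (
            1.0078250319,
            12.0,
            14.0030740052,
            15.9949146221,
            22.98976928,
            0.00054858,
        )
        hex_pm = 9 * C + 16 * H + 5 * O  # permethylated anhydro-hexose
        hexnac_pm = 11 * C + 19 * H + N + 5 * O
        expected = 5 * hex_pm + 2 * hexnac_pm + (2 * H + O) + 2 * (C + 2 * H) + Na - e
        assert composition_mz({"Hex": 5, "HexNAc": 2}) == pytest.approx(expected, abs=1e-6)
        assert composition_mz({"Hex": 5, "HexNAc": 2}) == pytest.approx(1579.78, abs=0.01)

    def test_native_proton_adduct(self):
        # native LacNAc [M+H]+: Gal+GlcNAc anhydro + H2O + proton
        got = composition_mz({"Hex": 1, "HexNAc": 1}, "native", "[M+H]+")
        assert got == pytest.approx(384.1506, abs=0.001)


class TestAnnotate:
    def test_known_composition_recovered(self):
        mz = composition_mz({"Hex": 5, "HexNAc": 2})
        pl = PeakList([Peak(mz, 100.0, 0.35)])
        ann = annotate_compositions(pl, tol_ppm=20)
        comps = [dict(c) for c, _m, _p in ann[0].candidates]
        assert {GenericClass.Hex: 5, GenericClass.HexNAc: 2} in comps

    def test_nominal_one_decimal_peak_label(self):
        """A tri-antennary bisected fucosylated N-glycan peak reported at
        one-decimal nominal precision (2937.9) still resolves to its
        composition at a 250 ppm window."""
        pl = PeakList([Peak(2937.9, 50.0, 0.35)])
        ann = annotate_compositions(pl, tol_ppm=250)
        comps = [dict(c) for c, _m, _p in ann[0].candidates]
        assert {
            GenericClass.Hex: 6,
            GenericClass.HexNAc: 6,
            GenericClass.dHex: 1,
        } in comps

    def test_zero_tolerance_only_exact(self):
        mz = composition_mz({"Hex": 3, "HexNAc": 2})
        ann = annotate_compositions(PeakList([Peak(mz, 10.0, 0.3)]), tol_ppm=0.0)
        assert len(ann[0].candidates) == 1
        ann_off = annotate_compositions(PeakList([Peak(mz + 0.01, 10.0, 0.3)]), tol_ppm=0.0)
        assert ann_off[0].candidates == ()

    def test_every_candidate_within_tolerance(self, rng):
        peaks = PeakList([Peak(float(m), 10.0, 0.3) for m in rng.uniform(1500, 3000, 10)])
        for tol in (5.0, 50.0, 500.0):
            for a in annotate_compositions(peaks, tol_ppm=tol):
                for comp, m, ppm in a.candidates:
                    assert abs(ppm) <= tol
                    assert composition_mz(comp) == pytest.approx(m)

    def test_equals_brute_force_lattice_enumeration(self, rng):
        """Candidate sets equal a plain quadruple-loop enumeration."""
        bounds = {"Hex": 6, "HexNAc": 4, "dHex": 2, "NeuAc": 2}
        peaks = PeakList(
            [Peak(float(m), 10.0, 0.3) for m in rng.uniform(1500, 2500, 8)]
        )
        ann = annotate_compositions(peaks, tol_ppm=200, bounds=bounds)
        for a in ann:
            brute = set()
            for h, n, d, s in itertools.product(
                range(7), range(5), range(3), range(3)
            ):
                if h + n + d + s == 0:
                    continue
                comp = {
                    k: v
                    for k, v in zip(("Hex", "HexNAc", "dHex", "NeuAc"), (h, n, d, s))
                    if v
                }
                m = composition_mz(comp)
                if abs(a.peak.centroid_mz - m) / m * 1e6 <= 200:
                    brute.add(str(gn.GlycanComposition(comp)))
            assert {str(c) for c, _m, _p in a.candidates} == brute
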