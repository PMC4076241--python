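"""MALDI-TOF glycomics spectrum handling.

Covers the MS leg of network synthesis: reading raw two-column m/z /
intensity traces (the ``.msd`` dialect: whitespace- or comma-delimited
text, ``#`` comments tolerated), the four-step peak-processing method
(background adjustment, normalisation, noise removal, peak finding),
composition annotation of centroids against a bounded Hex/HexNAc/dHex/
NeuAc lattice, and a seeded synthetic-spectrum generator used as ground
truth in tests.

Mass calculation is monoisotopic from atomic masses.  The default
conventions are those of permethylated, sodiated ([M+Na]+, singly
charged) glycan profiling; native (underivatised) masses and [M+H]+ are
also supported.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .glycan import GlycanComposition
from .residues import GenericClass

__all__ = [
    "Spectrum",
    "Peak",
    "PeakList",
    "AnnotatedPeak",
    "MsProcessParams",
    "read_ms",
    "write_ms",
    "ms_process",
    "annotate_compositions",
    "composition_mz",
    "synth_spectrum",
]

# monoisotopic atomic masses (u)
_H = 1.0078250319
_C = 12.0
_N = 14.0030740052
_O = 15.9949146221
_NA = 22.98976928
_ELECTRON = 0.00054858

_H2O = 2 * _H + _O
_CH2 = _C + 2 * _H


def _formula_mass(c: int, h: int, n: int, o: int) -> float:
    return c * _C + h * _H + n * _N + o * _O


# residue (in-chain, anhydro) masses per generic class
_NATIVE_RESIDUE = {
    GenericClass.Hex: _formula_mass(6, 10, 0, 5),
    GenericClass.HexNAc: _formula_mass(8, 13, 1, 5),
    GenericClass.dHex: _formula_mass(6, 10, 0, 4),
    GenericClass.NeuAc: _formula_mass(11, 17, 1, 8),
}
# methylation sites per residue when permethylated and chain-internal
_METHYL_SITES = {
    GenericClass.Hex: 3,
    GenericClass.HexNAc: 3,
    GenericClass.dHex: 2,
    GenericClass.NeuAc: 5,
}

_ADDUCT_MASS = {"[M+Na]+": _NA - _ELECTRON, "[M+H]+": _H - _ELECTRON}


def composition_mz(
    comp: GlycanComposition | Mapping,
    derivatization: str = "permethylated",
    adduct: str = "[M+Na]+",
) -> float:
    """Theoretical singly-charged m/z of a glycan composition."""
    counts = dict(comp) if isinstance(comp, GlycanComposition) else dict(comp)
    counts = {
        (k if isinstance(k, GenericClass) else GenericClass(k)): v
        for k, v in counts.items()
    }
    if derivatization not in ("permethylated", "native"):
        raise ValueError(f"unknown derivatization {derivatization!r}")
    if adduct not in _ADDUCT_MASS:
        raise ValueError(f"unknown adduct {adduct!r}")
    mass = _H2O  # terminal H / OH
    for cls, n in counts.items():
        mass += n * _NATIVE_RESIDUE[cls]
        if derivatization == "permethylated":
            mass += n * _METHYL_SITES[cls] * _CH2
    if derivatization == "permethylated":
        # the two chain termini gain one methyl each
        mass += 2 * _CH2
    return mass + _ADDUCT_MASS[adduct]


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Raw m/z-versus-intensity trace (ascending m/z)."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if mz.size == 0:
            raise ValueError("empty spectrum")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        inten = inten[order]
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.mz.size


@dataclasses.dataclass(frozen=True)
class Peak:
    centroid_mz: float
    height: float
    fwhm: float


class PeakList(list):
    """Centroided peaks, ascending by m/z."""

    def __init__(self, peaks: Sequence[Peak] = ()):
        peaks = sorted(peaks, key=lambda p: p.centroid_mz)
        if any(p.height <= 0 for p in peaks):
            raise ValueError("peak heights must be positive")
        super().__init__(peaks)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid_mz for p in self])


@dataclasses.dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    candidates: tuple  # of (GlycanComposition, theoretical m/z, ppm error)


def read_ms(path) -> Spectrum:
    """Load a two-column m/z / intensity text file (.msd dialect)."""
    mz, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", ";")):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric row {line!r}") from None
    if not mz:
        raise ValueError("no data rows found")
    return Spectrum(np.array(mz), np.array(inten))


def write_ms(s: Spectrum, path) -> None:
    with open(path, "w") as fh:
        for m, i in zip(s.mz, s.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


@dataclasses.dataclass(frozen=True)
class MsProcessParams:
    """Tuning parameters of the four-step peak processing.

    Windows are in data points.  ``snr_threshold`` multiplies a robust
    noise estimate (1.4826 x median absolute deviation of the smoothed
    residual); ``min_height`` is the reporting floor in normalised
    intensity units (max = 100).
    """

    baseline_window: int = 501
    baseline_smooth: int = 201
    smooth_window: int = 5
    snr_threshold: float = 3.0
    min_height: float = 1.0
    min_width_points: int = 5


def ms_process(s: Spectrum, params: MsProcessParams | None = None) -> PeakList:
    """Convert a raw trace into centroided peaks with FWHM.

    Steps: (1) background adjustment — moving-minimum (morphological
    opening) followed by moving-average baseline, subtracted and floored
    at zero; (2)
    normalisation to max 100; (3) noise removal — moving-average smoothing
    plus zeroing of points below ``snr_threshold`` times the robust noise
    level; (4) peak finding — local maxima above ``min_height``, centroid
    and full width at half maximum measured on the smoothed trace.
    """
    p = params or MsProcessParams()
    y = s.intensity.astype(float)
    n = y.size
    if n < 3:
        return PeakList()
    w_base = max(3, min(p.baseline_window, n) | 1)
    w_basesmooth = max(3, min(p.baseline_smooth, n) | 1)
    # morphological opening (minimum then maximum filter) tracks the
    # baseline under the peaks without following isolated downward noise
    # excursions; the opening runs on a lightly pre-smoothed trace so that
    # single-point dips (e.g. detector zeros) cannot capture the minimum,
    # and a moving average smooths the staircase the opening leaves
    pre = uniform_filter1d(y, max(3, min(21, n) | 1))
    baseline = uniform_filter1d(
        maximum_filter1d(minimum_filter1d(pre, w_base), w_base), w_basesmooth
    )
    y = np.clip(y - baseline, 0.0, None)
    top = y.max()
    if top <= 0:
        return PeakList()
    y *= 100.0 / top
    w_smooth = max(1, min(p.smooth_window, n) | 1)
    ys = uniform_filter1d(y, w_smooth) if w_smooth > 1 else y
    # robust noise floor of the smoothed trace: peaks are sparse, so the
    # median tracks the baseline region and the MAD its fluctuation
    floor_level = float(np.median(ys))
    noise = 1.4826 * float(np.median(np.abs(ys - floor_level)))
    threshold = floor_level + p.snr_threshold * noise
    ys = np.where(ys >= threshold, ys, 0.0)
    floor = max(p.min_height, threshold)
    idx, _props = signal.find_peaks(
        ys,
        height=floor,
        width=p.min_width_points,
        prominence=p.snr_threshold * noise,
    )
    if idx.size == 0:
        return PeakList()
    widths, _wh, lips, rips = signal.peak_widths(ys, idx, rel_height=0.5)
    peaks = []
    step = np.median(np.diff(s.mz))
    for i, w, lip, rip in zip(idx, widths, lips, rips):
        lo = int(np.floor(lip))
        hi = int(np.ceil(rip)) + 1
        seg_y = ys[lo:hi]
        seg_x = s.mz[lo:hi]
        total = seg_y.sum()
        centroid = float((seg_x * seg_y).sum() / total) if total > 0 else float(s.mz[i])
        peaks.append(Peak(centroid, float(ys[i]), float(w * step)))
    return PeakList(peaks)


def annotate_compositions(
    pl: PeakList,
    tol_ppm: float = 20.0,
    derivatization: str = "permethylated",
    adduct: str = "[M+Na]+",
    bounds: Optional[Mapping] = None,
) -> list[AnnotatedPeak]:
    """Assign glycan compositions to peak centroids.

    Enumerates every composition within ``bounds`` (per-class maximum
    counts, default Hex<=12, HexNAc<=8, dHex<=4, NeuAc<=4) whose
    theoretical m/z lies within ``tol_ppm`` of the centroid.
    """
    default_bounds = {
        GenericClass.Hex: 12,
        GenericClass.HexNAc: 8,
        GenericClass.dHex: 4,
        GenericClass.NeuAc: 4,
    }
    if bounds:
        for k, v in dict(bounds).items():
            default_bounds[k if isinstance(k, GenericClass) else GenericClass(k)] = int(v)
    classes = [GenericClass.Hex, GenericClass.HexNAc, GenericClass.dHex, GenericClass.NeuAc]
    lattice = []
    for counts in itertools.product(*(range(default_bounds[c] + 1) for c in classes)):
        if sum(counts) < 1:
            continue
        comp = {c: n for c, n in zip(classes, counts) if n}
        lattice.append(
            (composition_mz(comp, derivatization, adduct), GlycanComposition(comp))
        )
    lattice.sort(key=lambda t: t[0])
    masses = np.array([m for m, _c in lattice])
    out = []
    for peak in pl:
        tol = peak.centroid_mz * tol_ppm * 1e-6
        lo = np.searchsorted(masses, peak.centroid_mz - tol, side="left")
        hi = np.searchsorted(masses, peak.centroid_mz + tol, side="right")
        cands = []
        for m, comp in lattice[lo:hi]:
            ppm = (peak.centroid_mz - m) / m * 1e6
            cands.append((comp, m, ppm))
        cands.sort(key=lambda t: abs(t[2]))
        out.append(AnnotatedPeak(peak, tuple(cands)))
    return out


def synth_spectrum(
    compositions: Sequence,
    heights: Sequence[float],
    mz_range: tuple[float, float] = (1500.0, 3250.0),
    grid_step: float = 0.05,
    peak_sigma: float = 0.15,
    baseline_params: tuple[float, float] = (5.0, 2.0),
    noise_sigma: float = 0.5,
    seed: int = 0,
    derivatization: str = "permethylated",
    adduct: str = "[M+Na]+",
) -> tuple[Spectrum, list[tuple[float, float]]]:
    """Generate a synthetic MALDI-TOF-like trace with known ground truth.

    Gaussian peaks are placed at the theoretical m/z of each composition;
    a sloping baseline (``offset + slope`` decaying linearly across the
    range, in the same relative units as ``heights``) and seeded Gaussian
    noise are added.  Returns the spectrum and the ground-truth
    ``(m/z, height)`` table.  Compositions closer than twice the peak
    sigma trigger a resolution warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    mz = np.arange(mz_range[0], mz_range[1] + grid_step / 2, grid_step)
    y = np.zeros_like(mz)
    truth = []
    centers = []
    for comp, h in zip(compositions, heights):
        center = composition_mz(comp, derivatization, adduct)
        if not (mz_range[0] <= center <= mz_range[1]):
            raise ValueError(f"composition m/z {center:.2f} outside the grid range")
        centers.append(center)
        truth.append((center, float(h)))
        y += h * np.exp(-0.5 * ((mz - center) / peak_sigma) ** 2)
    centers.sort()
    if any(b - a < 2 * peak_sigma for a, b in zip(centers, centers[1:])):
        warnings.warn("compositions closer than the peak resolution", stacklevel=2)
    offset, slope = baseline_params
    y += offset + slope * (mz_range[1] - mz) / (mz_range[1] - mz_range[0])
    y += rng.normal(0.0, noise_sigma, size=mz.size)
    y = np.clip(y, 0.0, None)
    return Spectrum(mz, y), sorted(truth)
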