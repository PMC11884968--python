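"""Quantitative spectral statistics: peaks, SNR, depth sensitivity.

Covers the analysis layer of the multimodal probe: detecting and assigning
Raman peaks to biomolecular vibrational modes, the replicate-based
signal-to-noise ratio, the R635/R730 reflectance ratio used to track a dye
absorption trough through overlying tissue, and normalized depth-sensitivity
curves for the lensed (zero-offset) vs spatially offset fiber
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import pandas as pd
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_widths

from .errors import (
    AxisRangeError,
    DegenerateInputError,
    InsufficientReplicatesError,
    NormalizationError,
    NoTroughError,
    UnitError,
)
from .spectra import Spectrum, mean_spectrum, parabolic_refine

#: Default peak-assignment tolerance (cm^-1): half the closest spacing in
#: the shipped assignment table.
DEFAULT_ASSIGN_TOLERANCE_CM1 = 8.0


@dataclass(frozen=True)
class Peak:
    """A detected spectral peak."""

    center: float
    height: float
    prominence: float
    fwhm: float

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.prominence > 0 and self.fwhm > 0):
            raise ValueError("height, prominence and fwhm must be positive")


@dataclass(frozen=True)
class PeakAssignment:
    """One row of the biomolecular peak-assignment library."""

    center_cm1: float
    biomolecule: str
    vibrational_mode: str
    present_lensed: bool
    present_offset_1p5: bool


class PeakAssignmentTable:
    """Library of Raman peak assignments (center, biomolecule, mode, flags)."""

    def __init__(self, rows: Sequence[PeakAssignment]):
        rows = sorted(rows, key=lambda r: r.center_cm1)
        centers = [r.center_cm1 for r in rows]
        if len(set(centers)) != len(centers):
            raise ValueError("assignment centers must be unique")
        self.rows: tuple[PeakAssignment, ...] = tuple(rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def centers(self) -> np.ndarray:
        return np.array([r.center_cm1 for r in self.rows])

    @classmethod
    def from_tsv(cls, path_or_buf) -> "PeakAssignmentTable":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#")
        required = {"center_cm1", "biomolecule", "vibrational_mode", "lensed", "offset_1p5"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"assignment table missing columns: {sorted(missing)}")
        rows = [
            PeakAssignment(
                center_cm1=float(r.center_cm1),
                biomolecule=str(r.biomolecule),
                vibrational_mode=str(r.vibrational_mode),
                present_lensed=bool(int(r.lensed)),
                present_offset_1p5=bool(int(r.offset_1p5)),
            )
            for r in df.itertuples()
        ]
        return cls(rows)

    @classmethod
    def default(cls) -> "PeakAssignmentTable":
        """The shipped human-skin assignment library."""
        ref = resources.files("mmspec.data").joinpath("peak_assignments.tsv")
        with ref.open("r") as fh:
            return cls.from_tsv(fh)


@dataclass(frozen=True)
class DepthCurve:
    """Normalized probe value vs overlying-layer thickness."""

    thicknesses_mm: np.ndarray
    values: np.ndarray
    normalization_reference: str

    def __post_init__(self) -> None:
        t = np.asarray(self.thicknesses_mm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "thicknesses_mm", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise ValueError("thicknesses and values must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("thicknesses must be strictly increasing")


def detect_peaks(
    spec: Spectrum,
    min_prominence: float = 0.05,
    min_separation: float = 10.0,
) -> list[Peak]:
    """Locate peaks in a baseline-free spectrum.

    Local maxima with prominence of at least ``min_prominence`` times the
    maximum intensity, separated by at least ``min_separation`` axis units,
    are returned with sub-channel center refinement: a parabola is fit to
    the channels within half the estimated FWHM of the maximum (falling
    back to the classic 3-point parabola for single-channel-wide peaks).
    Using the full half-maximum region rather than only 3 channels
    averages channel noise down, which matters for weak tissue bands.

    An empty list is a valid result (e.g. a flat spectrum).
    """
    y = spec.y
    ymax = float(np.max(y)) if len(y) else 0.0
    if ymax <= 0:
        return []
    spacing = float(np.median(np.diff(spec.x)))
    distance = max(1, int(round(min_separation / spacing)))
    idx, props = find_peaks(y, prominence=min_prominence * ymax, distance=distance)
    if idx.size == 0:
        return []
    widths_ch = peak_widths(y, idx, rel_height=0.5)[0]
    peaks = []
    for i, prom, w_ch in zip(idx, props["prominences"], widths_ch):
        center, height = _refine_quadratic(spec.x, y, int(i), max(1, int(round(0.5 * w_ch))))
        peaks.append(
            Peak(
                center=center,
                height=height,
                prominence=float(prom),
                fwhm=float(max(w_ch * spacing, spacing)),
            )
        )
    return peaks


def _refine_quadratic(x: np.ndarray, y: np.ndarray, i: int, halfwin: int) -> tuple[float, float]:
    """Quadratic vertex fit over ``i +/- halfwin`` channels (clipped)."""
    lo = max(0, i - halfwin)
    hi = min(len(y), i + halfwin + 1)
    if hi - lo < 3:
        return parabolic_refine(x, y, i)
    xs = x[lo:hi] - x[i]
    c = np.polynomial.polynomial.polyfit(xs, y[lo:hi], 2)
    if not c[2] < 0:
        return parabolic_refine(x, y, i)
    dx = -c[1] / (2.0 * c[2])
    span = float(x[hi - 1] - x[lo])
    if abs(dx) > span:  # pathological fit; keep the grid maximum
        return float(x[i]), float(y[i])
    return float(x[i] + dx), float(c[0] - c[1] ** 2 / (4.0 * c[2]))


def assign_peaks(
    peaks: Sequence[Peak],
    table: PeakAssignmentTable | None = None,
    tolerance_cm1: float = DEFAULT_ASSIGN_TOLERANCE_CM1,
) -> list[tuple[Peak, PeakAssignment | None]]:
    """Match detected peaks to the assignment library.

    Greedy matching by ascending |detected - reference| distance; each
    library row is used at most once; peaks without a row within
    ``tolerance_cm1`` come back labelled ``None`` (unassigned).
    """
    table = table or PeakAssignmentTable.default()
    candidates = []
    for pi, peak in enumerate(peaks):
        for ri, row in enumerate(table.rows):
            delta = abs(peak.center - row.center_cm1)
            if delta <= tolerance_cm1:
                candidates.append((delta, row.center_cm1, pi, ri))
    candidates.sort()
    matched_p: dict[int, int] = {}
    used_r: set[int] = set()
    for _, _, pi, ri in candidates:
        if pi in matched_p or ri in used_r:
            continue
        matched_p[pi] = ri
        used_r.add(ri)
    return [
        (peak, table.rows[matched_p[pi]] if pi in matched_p else None)
        for pi, peak in enumerate(peaks)
    ]


def compute_snr(
    replicates: Sequence[Spectrum],
    peak_center: float,
    window: float = 20.0,
) -> float:
    """Replicate-based SNR of a Raman peak.

    The peak height of each replicate is the maximum (baseline-subtracted)
    intensity within ``peak_center +/- window/2``; the SNR is the mean
    height divided by the sample (n-1) standard deviation of the heights.
    Replicates are expected baseline-subtracted but *not* vector-normalized,
    so across-replicate variance is physical.
    """
    if len(replicates) < 3:
        raise InsufficientReplicatesError("SNR needs at least 3 replicates")
    first = replicates[0]
    for s in replicates[1:]:
        if s.axis != first.axis:
            raise UnitError("replicates must share a common axis")
    lo, hi = peak_center - window / 2.0, peak_center + window / 2.0
    sel = (first.x >= lo) & (first.x <= hi)
    if not np.any(sel):
        raise AxisRangeError(f"no channels within {peak_center} +/- {window / 2}")
    heights = np.array([float(np.max(s.y[sel])) for s in replicates])
    sd = float(np.std(heights, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("replicate heights are identical (sd = 0)")
    return float(np.mean(heights)) / sd


def reflectance_ratio(
    spec: Spectrum,
    lambda_abs: float = 635.0,
    lambda_ref: float = 730.0,
    band_halfwidth_nm: float = 0.0,
) -> float:
    """Ratio R(lambda_abs) / R(lambda_ref) of a reflectance spectrum.

    Each reflectance value is linearly interpolated at the requested
    wavelength, or averaged over ``+/- band_halfwidth_nm`` when a band
    half-width is given.
    """
    spec.axis.require_kind("wavelength_nm")

    def value_at(lam: float) -> float:
        if lam < spec.x[0] or lam > spec.x[-1]:
            raise AxisRangeError(f"{lam} nm outside axis [{spec.x[0]}, {spec.x[-1]}]")
        if band_halfwidth_nm > 0:
            sel = (spec.x >= lam - band_halfwidth_nm) & (spec.x <= lam + band_halfwidth_nm)
            return float(np.mean(spec.y[sel]))
        return float(np.interp(lam, spec.x, spec.y))

    ref = value_at(lambda_ref)
    if ref == 0.0:
        raise ZeroDivisionError(f"reference reflectance at {lambda_ref} nm is zero")
    return value_at(lambda_abs) / ref


def find_absorption_trough(
    spec: Spectrum,
    search_band: tuple[float, float] = (550.0, 700.0),
    smooth_channels: int = 5,
    refine_halfwidth_channels: int = 10,
) -> float:
    """Wavelength of an absorption trough in a reflectance spectrum.

    The reflectance is lightly smoothed (moving average over
    ``smooth_channels``), the global minimum within the band is located,
    and the center is refined by a parabola fit over
    ``refine_halfwidth_channels`` channels on each side of the minimum —
    absorption troughs are broad compared to the sampling grid, so a wide
    symmetric fit is far less noise-sensitive than a 3-point vertex.

    Raises
    ------
    NoTroughError
        When the band minimum sits on the band edge (monotone spectrum,
        no interior trough).
    """
    spec.axis.require_kind("wavelength_nm")
    lo, hi = search_band
    if lo < spec.x[0] or hi > spec.x[-1]:
        raise AxisRangeError(f"band [{lo}, {hi}] outside axis range")
    sub = spec.crop(lo, hi)
    y = uniform_filter1d(sub.y, size=max(1, smooth_channels), mode="nearest")
    i = int(np.nanargmin(y))
    if i == 0 or i == len(y) - 1:
        raise NoTroughError("reflectance is monotone over the band; no interior trough")
    center, _ = _refine_quadratic(sub.x, -y, i, max(1, refine_halfwidth_channels))
    return center


def depth_sensitivity_curve(
    measurements: Sequence[tuple[float, Sequence[Spectrum]]],
    probe_value: Callable[[Spectrum], float],
    normalization_reference: str = "thickness 0",
) -> DepthCurve:
    """Normalized probe value as a function of overlying-layer thickness.

    Replicates at each thickness are averaged into one spectrum before the
    probe value (e.g. a peak height or reflectance ratio) is evaluated; all
    values are normalized by the thickness-0 value, which must be present.
    """
    if not measurements:
        raise NormalizationError("no measurements given")
    thicknesses = np.array([float(t) for t, _ in measurements])
    order = np.argsort(thicknesses)
    values = []
    for i in order:
        _, reps = measurements[i]
        values.append(float(probe_value(mean_spectrum(list(reps)))))
    thicknesses = thicknesses[order]
    values = np.asarray(values)
    if not np.isclose(thicknesses[0], 0.0):
        raise NormalizationError("missing thickness-0 reference measurement")
    v0 = values[0]
    if v0 == 0.0:
        raise NormalizationError("thickness-0 probe value is zero")
    return DepthCurve(thicknesses, values / v0, normalization_reference)


def compare_fiber_configurations(
    peaks_lensed: Sequence[Peak],
    peaks_offset: Sequence[Peak],
    tolerance_cm1: float = DEFAULT_ASSIGN_TOLERANCE_CM1,
) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Classify peaks as common to both fiber configurations or unique.

    Peaks from the two lists are greedily matched by ascending center
    distance within ``tolerance_cm1``; matched pairs are *common*, the
    remainder are returned as ``lensed_only`` and ``offset_only``.
    """
    candidates = []
    for li, lp in enumerate(peaks_lensed):
        for oi, op in enumerate(peaks_offset):
            delta = abs(lp.center - op.center)
            if delta <= tolerance_cm1:
                candidates.append((delta, li, oi))
    candidates.sort()
    used_l: set[int] = set()
    used_o: set[int] = set()
    common: list[tuple[Peak, Peak]] = []
    for _, li, oi in candidates:
        if li in used_l or oi in used_o:
            continue
        used_l.add(li)
        used_o.add(oi)
        common.append((peaks_lensed[li], peaks_offset[oi]))
    lensed_only = [p for i, p in enumerate(peaks_lensed) if i not in used_l]
    offset_only = [p for i, p in enumerate(peaks_offset) if i not in used_o]
    return common, lensed_only, offset_only
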