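"""Raw-count calibration: diffuse reflectance and the Raman wavenumber axis.

Diffuse reflectance is computed as the ratio of the background-subtracted
sample measurement to the background-subtracted measurement of a diffuse
reflectance standard of known reflectivity (80% Spectralon by default):

    R(lambda) = (I_sample - I_bg) / (I_standard - I_bg)

The result is a *relative* reflectance; multiplying by the standard's
reflectivity (``absolute=True``) converts to absolute reflectance.  An
optional optical-density correction ``10**(-OD)`` undoes a neutral-density
filter placed in the standard arm during its acquisition.

The Raman wavenumber axis is calibrated against acetaminophen, a standard
solid calibrant with well-known Raman shifts.  Peak pixel positions are
detected in the measured calibrant spectrum and fit by least squares to the
reference shifts with a low-order polynomial (pixel -> cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import find_peaks

from .errors import CalibrationError, UnitError
from .spectra import (
    SpectralAxis,
    Spectrum,
    parabolic_refine,
    resample_to_axis,
)

#: Published acetaminophen Raman calibration shifts (cm^-1), the community
#: standard positions for this calibrant (ASTM E1840 values).
ACETAMINOPHEN_SHIFTS_CM1 = (651.6, 797.2, 857.9, 1168.5, 1236.8, 1323.9, 1648.4)

#: Default reported band for diffuse reflectance (nm).
DEFAULT_DRS_BAND_NM = (475.0, 600.0)


@dataclass(frozen=True)
class WavenumberMap:
    """Polynomial map from detector pixel to Raman shift (cm^-1).

    ``coefficients`` are in ascending power order over raw pixel index.
    The map must be strictly increasing over the calibrated pixel range.
    """

    coefficients: np.ndarray
    residual_rms: float = 0.0
    pixel_range: tuple[float, float] = (0.0, 1023.0)

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs.size < 2 or coeffs.size > 4:
            raise ValueError("wavenumber map must have degree 1..3")
        lo, hi = self.pixel_range
        grid = np.linspace(lo, hi, 512)
        if not np.all(np.diff(self(grid)) > 0):
            raise CalibrationError(
                "wavenumber map is not strictly increasing over the pixel range"
            )

    @property
    def degree(self) -> int:
        return int(self.coefficients.size - 1)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return npoly.polyval(np.asarray(pixels, dtype=float), self.coefficients)

    def invert(self, shifts_cm1: np.ndarray) -> np.ndarray:
        """Pixel positions producing the given shifts (monotone inversion)."""
        lo, hi = self.pixel_range
        grid = np.linspace(lo, hi, 8192)
        return np.interp(np.asarray(shifts_cm1, dtype=float), self(grid), grid)


@dataclass(frozen=True)
class CalibrationBundle:
    """Daily calibration set: backgrounds, reflectance standard, calibrant.

    ``standard_reflectivity`` is the nominal reflectivity of the diffuse
    standard (0.80 for the 80% Spectralon standard).
    """

    background_drs: Spectrum
    standard: Spectrum
    standard_reflectivity: float = 0.80
    background_rs: Spectrum | None = None
    acetaminophen: Spectrum | None = None
    reference_peaks: tuple[float, ...] = ACETAMINOPHEN_SHIFTS_CM1

    def __post_init__(self) -> None:
        if not (0.0 < self.standard_reflectivity <= 1.0):
            raise ValueError("standard_reflectivity must be in (0, 1]")
        refs = tuple(float(r) for r in self.reference_peaks)
        object.__setattr__(self, "reference_peaks", refs)
        if len(refs) < 3 or not np.all(np.diff(refs) > 0):
            raise ValueError("reference_peaks must be >= 3 strictly increasing shifts")
        if self.background_drs.axis.kind != self.standard.axis.kind:
            raise UnitError("DRS background and standard must share an axis kind")


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Element-wise background subtraction on identical axes.

    Metadata is propagated from the sample.
    """
    if sample.axis != background.axis:
        raise UnitError("sample and background axes differ")
    return sample.with_intensities(sample.y - background.y)


def compute_reflectance(
    sample: Spectrum,
    bundle: CalibrationBundle,
    od_correction: float | None = None,
    band_nm: tuple[float, float] | None = DEFAULT_DRS_BAND_NM,
    absolute: bool = False,
) -> Spectrum:
    """Diffuse reflectance from raw sample counts and a calibration bundle.

    R = (sample - background) / (standard - background), evaluated after
    resampling the standard and background onto the sample axis.  Channels
    whose denominator is not strictly positive are masked with NaN; their
    count is recorded in ``meta.extras['n_masked']``.

    Parameters
    ----------
    od_correction
        Optical density of a neutral-density filter present during the
        standard measurement; when given, the ratio is multiplied by
        ``10**(-od_correction)``.
    band_nm
        Inclusive wavelength band over which reflectance is reported
        (default 475-600 nm); ``None`` reports the full sample axis.
    absolute
        Multiply by the standard's nominal reflectivity to obtain absolute
        reflectance instead of reflectance relative to the standard.
    """
    sample.axis.require_kind("wavelength_nm")
    standard = resample_to_axis(bundle.standard, sample.axis)
    background = resample_to_axis(bundle.background_drs, sample.axis)
    num = sample.y - background.y
    den = standard.y - background.y
    bad = ~(den > 0)
    ratio = np.full_like(num, np.nan)
    np.divide(num, den, out=ratio, where=~bad)
    if od_correction is not None:
        ratio = ratio * 10.0 ** (-od_correction)
    if absolute:
        ratio = ratio * bundle.standard_reflectivity
    out = sample.with_intensities(ratio, n_masked=int(bad.sum()), quantity="reflectance")
    if band_nm is not None:
        out = out.crop(*band_nm)
    return out


def _detect_calibrant_peaks(spec: Spectrum, n_expected: int) -> np.ndarray:
    """Positions (axis units) of the ``n_expected`` most prominent peaks."""
    y = spec.y
    span = float(np.ptp(y))
    if span <= 0:
        return np.empty(0)
    idx, props = find_peaks(y, prominence=0.02 * span)
    if idx.size == 0:
        return np.empty(0)
    order = np.argsort(props["prominences"])[::-1][:n_expected]
    chosen = np.sort(idx[order])
    return np.array([parabolic_refine(spec.x, y, int(i))[0] for i in chosen])


def calibrate_wavenumber_axis(
    acetaminophen: Spectrum,
    reference_peaks: tuple[float, ...] = ACETAMINOPHEN_SHIFTS_CM1,
    degree: int = 2,
) -> WavenumberMap:
    """Fit the pixel -> cm^-1 map from a measured calibrant spectrum.

    The ``len(reference_peaks)`` most prominent peaks are located (with
    sub-pixel parabolic refinement) and paired in ascending order with the
    reference shifts; a least-squares polynomial of the requested degree is
    fit through the pairs.

    Raises
    ------
    CalibrationError
        If fewer than ``degree + 1`` peaks are detectable, or the number of
        detected peaks does not match the reference list, or the fitted map
        is not monotone.
    """
    refs = np.asarray(reference_peaks, dtype=float)
    if not (1 <= degree <= 3):
        raise ValueError("degree must be 1..3")
    detected = _detect_calibrant_peaks(acetaminophen, len(refs))
    if detected.size < degree + 1:
        raise CalibrationError(
            f"only {detected.size} calibrant peaks detected; "
            f"need at least {degree + 1} for degree {degree}"
        )
    if detected.size != refs.size:
        raise CalibrationError(
            f"detected {detected.size} peaks but have {refs.size} reference "
            "shifts; cannot pair unambiguously"
        )
    coeffs = npoly.polyfit(detected, refs, degree)
    fitted = npoly.polyval(detected, coeffs)
    rms = float(np.sqrt(np.mean((fitted - refs) ** 2)))
    pix = acetaminophen.x
    return WavenumberMap(coeffs, residual_rms=rms, pixel_range=(float(pix[0]), float(pix[-1])))


def apply_wavenumber_map(spec: Spectrum, wmap: WavenumberMap) -> Spectrum:
    """Transform a pixel-axis spectrum onto the calibrated cm^-1 axis.

    Intensities are untouched; only the axis is remapped.
    """
    spec.axis.require_kind("pixel")
    shifts = wmap(spec.x)
    return Spectrum(SpectralAxis(shifts, "raman_shift_cm-1"), spec.y, spec.meta)
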