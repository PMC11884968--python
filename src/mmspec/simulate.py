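"""Forward simulator of the multimodal probe and two-layer tissue phantoms.

Generates raw Raman and diffuse-reflectance spectra, replicate series, CCD
frames, and two-layer (dyed fat under muscle) phantom sweeps with the
statistical structure the rest of the toolkit assumes: narrow Raman peaks
on a smooth autofluorescence background, Gaussian read noise, optional
Poisson shot noise, rare single-channel cosmic spikes, and a dye absorption
band in the reflectance.

Depth weighting of the two-layer phantom is a phenomenological
single-exponential: the bottom (fat) layer contributes
``w(d) = exp(-d / delta)`` of its bare signal under ``d`` mm of muscle,
where ``delta`` is an effective sensing depth per fiber configuration.
The default depths (4.48 mm spatially offset, 2.80 mm lensed) encode the
deeper sampling of the offset fibers: at 2 mm of muscle they retain ~64%
and ~49% of the bare-fat signal respectively.  This is a monotone stand-in
for layered radiative transport, not a transport model.

All generators are bit-reproducible given a seed; replicate ``r`` uses the
stream seeded by ``seed XOR r``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .calibration import ACETAMINOPHEN_SHIFTS_CM1, WavenumberMap
from .errors import ConfigError
from .spectra import (
    AcquisitionMeta,
    CCDFrame,
    FiberROI,
    SpectralAxis,
    Spectrum,
)

#: Muscle Raman fixture library: protein bands (phenylalanine ring,
#: CH2/CH3 wag, amide I).
MUSCLE_PEAKS: tuple["RamanPeakSpec", ...]
#: Fat Raman fixture library: lipid bands (CH2 bending dominant, C=O ester).
FAT_PEAKS: tuple["RamanPeakSpec", ...]


@dataclass(frozen=True)
class RamanPeakSpec:
    """One simulated Raman band."""

    center: float
    amplitude: float
    fwhm: float = 12.0
    profile: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.fwhm > 0):
            raise ConfigError("amplitude and fwhm must be positive")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        u = (x - self.center) / self.fwhm
        if self.profile == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * u**2)
        if self.profile == "lorentzian":
            return self.amplitude / (1.0 + 4.0 * u**2)
        raise ConfigError(f"unknown profile {self.profile!r}")


MUSCLE_PEAKS = (
    RamanPeakSpec(1002.0, 60.0, 10.0),
    RamanPeakSpec(1339.0, 80.0, 14.0),
    RamanPeakSpec(1645.0, 70.0, 18.0),
)
FAT_PEAKS = (
    RamanPeakSpec(1448.0, 100.0, 14.0),
    RamanPeakSpec(1736.0, 55.0, 14.0),
)


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model: Gaussian read noise, shot noise, cosmic spikes."""

    additive_sd: float = 0.0
    shot_noise: bool = False
    spike_rate: float = 0.0  #: expected cosmic spikes per spectrum
    spike_amplitude_range: tuple[float, float] = (500.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.spike_rate < 0:
            raise ConfigError("additive_sd and spike_rate must be >= 0")
        lo, hi = self.spike_amplitude_range
        if not (0 <= lo <= hi):
            raise ConfigError("invalid spike_amplitude_range")

    def rng(self, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed) ^ int(replicate)) & 0x7FFFFFFF)

    def apply(self, clean: np.ndarray, replicate: int = 0) -> np.ndarray:
        """Noisy realization of a clean spectrum (deterministic per seed)."""
        rng = self.rng(replicate)
        y = np.asarray(clean, dtype=float)
        if self.shot_noise:
            y = rng.poisson(np.clip(y, 0.0, None)).astype(float)
        if self.additive_sd > 0:
            y = y + rng.normal(0.0, self.additive_sd, size=y.size)
        if self.spike_rate > 0:
            n_spikes = rng.poisson(self.spike_rate)
            if n_spikes > 0:
                channels = rng.integers(0, y.size, size=n_spikes)
                lo, hi = self.spike_amplitude_range
                y = y.copy()
                y[channels] += rng.uniform(lo, hi, size=n_spikes)
        return y


@dataclass(frozen=True)
class PhantomSpec:
    """Two-layer phantom: dyed fat below a muscle layer of given thickness."""

    muscle_thickness_mm: float = 0.0
    dye_band_center_nm: float = 635.0
    dye_band_fwhm_nm: float = 50.0
    dye_strength: float = 1.5
    sensing_depth_lensed_mm: float = 2.80
    sensing_depth_offset_mm: float = 4.48
    throughput_factor: float = 0.45

    def __post_init__(self) -> None:
        if self.muscle_thickness_mm < 0:
            raise ConfigError("muscle_thickness_mm must be >= 0")
        if not (self.sensing_depth_lensed_mm > 0 and self.sensing_depth_offset_mm > 0):
            raise ConfigError("sensing depths must be > 0")
        if not (0.0 < self.throughput_factor <= 1.0):
            raise ConfigError("throughput_factor must be in (0, 1]")

    def bottom_layer_weight(self, config: Literal["lensed", "offset"]) -> float:
        """w(d) = exp(-d / delta_config): surviving fraction of fat signal."""
        if config == "lensed":
            delta = self.sensing_depth_lensed_mm
        elif config == "offset":
            delta = self.sensing_depth_offset_mm
        else:
            raise ConfigError(f"unknown fiber configuration {config!r}")
        return float(np.exp(-self.muscle_thickness_mm / delta))


#: Muscle-layer thickness series of the phantom study, mm.
PHANTOM_THICKNESSES_MM = (0.0, 0.5, 1.1, 1.7, 2.3, 2.9, 3.5, 4.1, 4.7, 5.3, 5.9)


def default_raman_axis(lo: float = 350.0, hi: float = 1900.0, step: float = 1.0) -> SpectralAxis:
    return SpectralAxis(np.arange(lo, hi + step / 2, step), "raman_shift_cm-1")


def default_drs_axis(lo: float = 450.0, hi: float = 800.0, step: float = 1.0) -> SpectralAxis:
    return SpectralAxis(np.arange(lo, hi + step / 2, step), "wavelength_nm")


def _eval_peaks(peaks: Sequence[RamanPeakSpec], x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for p in peaks:
        y = y + p.evaluate(x)
    return y


def _eval_baseline(coeffs: Sequence[float], x: np.ndarray) -> np.ndarray:
    """Polynomial background in ascending powers of the normalized
    coordinate u = (x - x0) / (x1 - x0), keeping coefficients O(counts)."""
    u = (x - x[0]) / (x[-1] - x[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(coeffs, dtype=float))


def simulate_raman_measurement(
    peaks: Sequence[RamanPeakSpec],
    baseline_coeffs: Sequence[float] = (0.0,),
    noise: NoiseSpec | None = None,
    n_replicates: int = 1,
    axis: SpectralAxis | None = None,
    meta: AcquisitionMeta | None = None,
) -> list[Spectrum]:
    """Simulate replicate Raman spectra: peaks + autofluorescence + noise.

    ``baseline_coeffs`` are ascending-power polynomial coefficients over
    the normalized axis coordinate (0 at the first channel, 1 at the
    last).  Replicate ``r`` uses the noise stream seeded with
    ``noise.seed XOR r``; identical seeds give bit-identical output.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    noise = noise or NoiseSpec()
    axis = axis or default_raman_axis()
    meta = meta or AcquisitionMeta(modality="RS", integration_time_s=5.0, laser_power_mW=40.0)
    clean = _eval_peaks(peaks, axis.values) + _eval_baseline(baseline_coeffs, axis.values)
    out = []
    for r in range(n_replicates):
        y = noise.apply(clean, replicate=r)
        out.append(Spectrum(axis, y, replace(meta, replicate_index=r)))
    return out


def simulate_two_layer_raman(
    phantom: PhantomSpec,
    config: Literal["lensed", "offset"],
    noise: NoiseSpec | None = None,
    fat_peaks: Sequence[RamanPeakSpec] = FAT_PEAKS,
    muscle_peaks: Sequence[RamanPeakSpec] = MUSCLE_PEAKS,
    baseline_coeffs: Sequence[float] = (0.0,),
    axis: SpectralAxis | None = None,
    replicate: int = 0,
) -> Spectrum:
    """Raman spectrum of dyed fat under ``muscle_thickness_mm`` of muscle.

    The fat (bottom-layer) library is weighted by ``w(d) = exp(-d/delta)``
    and the muscle (top-layer) library by ``1 - w(d)``; at zero thickness
    the spectrum is pure fat.  Intensities are scaled by the optical
    throughput of the probe chain.
    """
    noise = noise or NoiseSpec()
    axis = axis or default_raman_axis()
    w = phantom.bottom_layer_weight(config)
    x = axis.values
    clean = phantom.throughput_factor * (
        w * _eval_peaks(fat_peaks, x) + (1.0 - w) * _eval_peaks(muscle_peaks, x)
    )
    clean = clean + _eval_baseline(baseline_coeffs, x)
    fiber = "lensed" if config == "lensed" else "offset_1p5mm"
    meta = AcquisitionMeta(
        modality="RS",
        fiber_config=fiber,
        integration_time_s=5.0,
        laser_power_mW=40.0,
        replicate_index=replicate,
        extras={"muscle_thickness_mm": phantom.muscle_thickness_mm},
    )
    return Spectrum(axis, noise.apply(clean, replicate=replicate), meta)


def _lamp_spectrum(lam: np.ndarray) -> np.ndarray:
    """Smooth halogen-like broadband illumination profile (counts)."""
    return 4000.0 * np.exp(-(((lam - 640.0) / 220.0) ** 2))


def _reflectance_shape(lam: np.ndarray) -> np.ndarray:
    """Common featureless spectral shape of the undyed tissue layers.

    Fat and muscle share one gently sloped shape and differ only in albedo,
    so without the dye the mixture reflectance keeps the same spectral
    profile at every thickness (the R635/R730 ratio is then exactly
    thickness-independent, isolating the dye as the only ratio signal).
    """
    return 1.0 + 0.15 * (lam - lam[0]) / (lam[-1] - lam[0])


def _muscle_reflectance(lam: np.ndarray) -> np.ndarray:
    return 0.35 * _reflectance_shape(lam)


def _fat_reflectance(lam: np.ndarray) -> np.ndarray:
    return 0.58 * _reflectance_shape(lam)


def simulate_two_layer_drs(
    phantom: PhantomSpec,
    noise: NoiseSpec | None = None,
    axis: SpectralAxis | None = None,
    replicate: int = 0,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Raw DRS triplet (sample, standard, background) for the phantom.

    The phantom reflectance mixes the two layers with the same exponential
    depth weight as the Raman model (offset geometry):

        R(lam, d) = R_muscle(lam) (1 - w(d))
                    + R_fat(lam) exp(-dye_strength B(lam)) w(d)

    with ``B`` a unit-height Gaussian dye band at ``dye_band_center_nm``.
    Raw counts are ``lamp * R + dark`` for the sample and ``lamp * 0.8 +
    dark`` for the 80% standard, so the triplet feeds straight into the
    reflectance calibration.
    """
    noise = noise or NoiseSpec()
    axis = axis or default_drs_axis()
    lam = axis.values
    w = phantom.bottom_layer_weight("offset")
    band = np.exp(
        -4.0 * np.log(2.0) * ((lam - phantom.dye_band_center_nm) / phantom.dye_band_fwhm_nm) ** 2
    )
    reflectance = _muscle_reflectance(lam) * (1.0 - w) + _fat_reflectance(lam) * np.exp(
        -phantom.dye_strength * band
    ) * w
    lamp = _lamp_spectrum(lam) * phantom.throughput_factor
    dark = 30.0
    meta = AcquisitionMeta(
        modality="DRS",
        fiber_config="offset_2p5mm",
        integration_time_s=0.5,
        replicate_index=replicate,
        extras={"muscle_thickness_mm": phantom.muscle_thickness_mm},
    )
    sample = Spectrum(axis, noise.apply(dark + lamp * reflectance, replicate=3 * replicate), meta)
    standard = Spectrum(
        axis,
        noise.apply(dark + lamp * 0.8, replicate=3 * replicate + 1),
        replace(meta, extras={**meta.extras, "role": "standard"}),
    )
    background = Spectrum(
        axis,
        noise.apply(np.full_like(lam, dark), replicate=3 * replicate + 2),
        replace(meta, extras={**meta.extras, "role": "background"}),
    )
    return sample, standard, background


def simulate_ccd_frame(
    spectrum: Spectrum,
    rois: Sequence[FiberROI],
    per_fiber_gain: Sequence[float],
    noise: NoiseSpec | None = None,
    n_rows: int = 256,
) -> CCDFrame:
    """Render a spectrum into a CCD frame with per-fiber row blocks.

    Rows inside each ROI carry the spectrum scaled by that fiber group's
    gain (divided across its rows so vertical binning recovers
    ``gain * spectrum``); rows outside any ROI carry read noise only.
    """
    if len(rois) != len(per_fiber_gain):
        raise ConfigError("need one gain per fiber ROI")
    if any(g <= 0 for g in per_fiber_gain):
        raise ConfigError("gains must be positive")
    noise = noise or NoiseSpec()
    frame = np.zeros((n_rows, len(spectrum)))
    for roi, gain in zip(rois, per_fiber_gain):
        if roi.row_end >= n_rows:
            raise ConfigError("ROI exceeds frame rows")
        frame[roi.row_start : roi.row_end + 1, :] = gain * spectrum.y / roi.n_rows
    if noise.additive_sd > 0:
        rng = noise.rng()
        frame = frame + rng.normal(0.0, noise.additive_sd, size=frame.shape)
    return CCDFrame(frame, spectrum.axis, tuple(rois))


def simulate_acetaminophen(
    map_truth: WavenumberMap,
    noise: NoiseSpec | None = None,
    n_pixels: int = 1024,
    reference_peaks: Sequence[float] = ACETAMINOPHEN_SHIFTS_CM1,
    fwhm_cm1: float = 8.0,
) -> Spectrum:
    """Calibrant spectrum rendered on the pixel axis.

    Peaks are placed at the reference Raman shifts as seen through the
    *inverse* of the true pixel-to-wavenumber map, so running the
    wavenumber calibration on the result should recover ``map_truth``.
    """
    noise = noise or NoiseSpec()
    pixels = np.arange(float(n_pixels))
    shifts = map_truth(pixels)
    amplitudes = 1000.0 * (1.0 + 0.1 * np.arange(len(reference_peaks)))
    clean = np.zeros_like(pixels)
    for ref, amp in zip(reference_peaks, amplitudes):
        clean = clean + amp * np.exp(-4.0 * np.log(2.0) * ((shifts - ref) / fwhm_cm1) ** 2)
    meta = AcquisitionMeta(modality="RS", integration_time_s=1.0, laser_power_mW=40.0)
    return Spectrum(SpectralAxis(pixels, "pixel"), noise.apply(clean), meta)
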