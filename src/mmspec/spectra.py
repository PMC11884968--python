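"""Core spectral data model and CCD fiber-region binning.

The universal currency of the toolkit is the :class:`Spectrum`: a strictly
increasing spectral axis (wavelength in nm, Raman shift in cm^-1, or raw
detector pixel index) together with intensity counts and acquisition
metadata.  Raw detector output is represented by :class:`CCDFrame`, a 2-D
counts matrix whose fiber image regions are summed row-wise ("vertically
binned") into one spectrum per fiber group.

Row ranges of a :class:`FiberROI` are inclusive on both ends and 0-indexed:
rows 22..92 cover 71 detector rows.  Binning sums counts rather than
averaging them, so Poisson statistics of the photon counts are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import AxisRangeError, BoundsError, UnitError

AxisKind = Literal["wavelength_nm", "raman_shift_cm-1", "pixel"]
Modality = Literal["DRS", "RS"]
FiberConfig = Literal["lensed", "offset_1p5mm", "offset_2p5mm"]

#: Default lensed-fiber row range on the 256-row detector (inclusive).
DEFAULT_LENSED_ROWS = (22, 92)
#: Default spatially offset fiber row range (inclusive).
DEFAULT_OFFSET_ROWS = (93, 201)


@dataclass(frozen=True)
class SpectralAxis:
    """An ordered spectral axis with an explicit unit kind."""

    values: np.ndarray
    kind: AxisKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least 2 values in a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("axis values must be finite")
        if not np.all(np.diff(values) > 0):
            raise ValueError("axis values must be strictly increasing")
        if self.kind not in ("wavelength_nm", "raman_shift_cm-1", "pixel"):
            raise UnitError(f"unknown axis kind: {self.kind!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.kind == other.kind and np.array_equal(self.values, other.values)

    def require_kind(self, kind: AxisKind) -> None:
        if self.kind != kind:
            raise UnitError(f"expected {kind} axis, got {self.kind}")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings attached to every spectrum.

    ``extras`` carries free-form provenance (e.g. masked-channel counts,
    pipeline stage names) without widening the schema.
    """

    modality: Modality = "RS"
    fiber_config: FiberConfig = "lensed"
    integration_time_s: float = 1.0
    laser_power_mW: float = 0.0
    replicate_index: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("DRS", "RS"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.fiber_config not in ("lensed", "offset_1p5mm", "offset_2p5mm"):
            raise ValueError(f"unknown fiber_config: {self.fiber_config!r}")
        if not self.integration_time_s > 0:
            raise ValueError("integration_time_s must be > 0")
        if self.laser_power_mW < 0:
            raise ValueError("laser_power_mW must be >= 0")
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")


@dataclass(frozen=True)
class Spectrum:
    """A spectral axis plus intensities and acquisition metadata.

    Intensities must be free of infinities; NaN is permitted only as an
    explicit masked-channel marker set by operations that document it
    (e.g. reflectance channels with a nonpositive denominator).
    """

    axis: SpectralAxis
    intensities: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intens)
        if intens.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if intens.size != len(self.axis):
            raise ValueError(
                f"length mismatch: {intens.size} intensities vs "
                f"{len(self.axis)} axis values"
            )
        if np.any(np.isinf(intens)):
            raise ValueError("intensities must not be infinite")

    def __len__(self) -> int:
        return int(self.intensities.size)

    @property
    def x(self) -> np.ndarray:
        return self.axis.values

    @property
    def y(self) -> np.ndarray:
        return self.intensities

    def with_intensities(self, values: np.ndarray, **meta_extras) -> "Spectrum":
        """Copy of this spectrum with new intensities (same axis).

        Keyword arguments are merged into ``meta.extras``.
        """
        meta = self.meta
        if meta_extras:
            meta = replace(meta, extras={**meta.extras, **meta_extras})
        return Spectrum(self.axis, np.asarray(values, dtype=float), meta)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Channels with lo <= x <= hi (inclusive bounds)."""
        keep = (self.x >= lo) & (self.x <= hi)
        if not np.any(keep):
            from .errors import EmptyResultError

            raise EmptyResultError(
                f"no channels in [{lo}, {hi}] on axis "
                f"[{self.x[0]}, {self.x[-1]}]"
            )
        return Spectrum(
            SpectralAxis(self.x[keep], self.axis.kind), self.y[keep], self.meta
        )


@dataclass(frozen=True)
class FiberROI:
    """Inclusive detector row range imaged by one fiber group."""

    label: Literal["lensed", "offset"]
    row_start: int
    row_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start <= self.row_end):
            raise ValueError(
                f"need 0 <= row_start <= row_end, got [{self.row_start}, {self.row_end}]"
            )

    @property
    def n_rows(self) -> int:
        return self.row_end - self.row_start + 1


@dataclass(frozen=True)
class CCDFrame:
    """2-D detector counts (rows x spectral columns) with fiber ROIs."""

    counts: np.ndarray
    column_axis: SpectralAxis
    fiber_rois: tuple[FiberROI, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "fiber_rois", tuple(self.fiber_rois))
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape[1] != len(self.column_axis):
            raise ValueError(
                f"frame has {counts.shape[1]} columns but axis has "
                f"{len(self.column_axis)} values"
            )
        for roi in self.fiber_rois:
            if roi.row_end >= counts.shape[0]:
                raise BoundsError(
                    f"ROI rows [{roi.row_start}, {roi.row_end}] exceed "
                    f"{counts.shape[0]} detector rows"
                )
        spans = sorted((r.row_start, r.row_end) for r in self.fiber_rois)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi:
                raise ValueError("fiber ROIs must not overlap")

    @property
    def n_rows(self) -> int:
        return int(self.counts.shape[0])


def bin_ccd_rows(frame: CCDFrame, roi: FiberROI, meta: AcquisitionMeta | None = None) -> Spectrum:
    """Vertically bin an inclusive row range of a CCD frame into a spectrum.

    Each output channel is the *sum* of counts over rows
    ``row_start..row_end`` inclusive (summation preserves Poisson counting
    statistics; averaging would not).

    Parameters
    ----------
    frame
        Detector frame to bin.
    roi
        Inclusive, 0-indexed row range; must lie within the frame.
    meta
        Optional acquisition metadata for the resulting spectrum.

    Raises
    ------
    BoundsError
        If the ROI extends beyond the detector rows.
    """
    if roi.row_end >= frame.n_rows:
        raise BoundsError(
            f"ROI rows [{roi.row_start}, {roi.row_end}] exceed "
            f"{frame.n_rows} detector rows"
        )
    binned = frame.counts[roi.row_start : roi.row_end + 1, :].sum(axis=0)
    if meta is None:
        meta = AcquisitionMeta(extras={"binned_rows": f"{roi.row_start}-{roi.row_end}"})
    return Spectrum(frame.column_axis, binned, meta)


def resample_to_axis(spec: Spectrum, target: SpectralAxis) -> Spectrum:
    """Linearly interpolate a spectrum onto a new axis of the same kind.

    The target axis must lie within the source axis range; extrapolation is
    refused.  Where the grids coincide the original samples are preserved
    exactly.
    """
    if target.kind != spec.axis.kind:
        raise UnitError(
            f"cannot resample {spec.axis.kind} spectrum onto {target.kind} axis"
        )
    if target.values[0] < spec.x[0] or target.values[-1] > spec.x[-1]:
        raise AxisRangeError(
            f"target range [{target.values[0]}, {target.values[-1]}] exceeds "
            f"source range [{spec.x[0]}, {spec.x[-1]}]"
        )
    if target == spec.axis:
        return spec
    resampled = np.interp(target.values, spec.x, spec.y)
    return Spectrum(target, resampled, spec.meta)


def parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine an extremum location by fitting a parabola through 3 samples.

    Returns the refined ``(x, y)`` of the extremum around index ``i``.
    Falls back to the grid point at the array boundary or for a degenerate
    (flat) triple.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    # Assumes locally uniform spacing; adequate for sub-channel refinement.
    step = 0.5 * (x[i + 1] - x[i - 1])
    x_ref = float(x[i] + delta * step)
    y_ref = float(y1 - 0.25 * (y0 - y2) * delta)
    return x_ref, y_ref


def mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Element-wise mean of replicate spectra sharing one axis."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.axis != first.axis:
            raise UnitError("replicates must share a common axis")
    stack = np.vstack([s.y for s in spectra])
    return first.with_intensities(stack.mean(axis=0))
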