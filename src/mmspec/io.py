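"""Plain-text file formats: spectra, CCD frames, manifests, config files.

Spectra travel as two-column delimited text (axis value, intensity) with
"#"-prefixed ``key=value`` metadata header lines; the writer emits keys in
sorted order and full float precision so write -> read round-trips are
bit-exact and identical inputs give identical bytes.  CCD frames are
delimited numeric matrices (one detector row per line) with the same
header convention.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SpectrumIOError
from .spectra import AcquisitionMeta, CCDFrame, FiberROI, SpectralAxis, Spectrum

_REQUIRED_KEYS = ("axis_kind", "modality", "fiber_config", "integration_time_s")

_META_FIELDS = {
    "modality": str,
    "fiber_config": str,
    "integration_time_s": float,
    "laser_power_mW": float,
    "replicate_index": int,
}


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _parse_header(lines: list[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    return header


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as headered two-column text (deterministic bytes)."""
    meta = spec.meta
    header = {
        "axis_kind": spec.axis.kind,
        "modality": meta.modality,
        "fiber_config": meta.fiber_config,
        "integration_time_s": meta.integration_time_s,
        "laser_power_mW": meta.laser_power_mW,
        "replicate_index": meta.replicate_index,
    }
    for k, v in meta.extras.items():
        header[str(k)] = v
    buf = _io.StringIO()
    for key in sorted(header):
        buf.write(f"# {key}={_format_value(header[key])}\n")
    for x, y in zip(spec.x, spec.y):
        buf.write(f"{float(x)!r}\t{float(y)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a headered two-column spectrum file.

    Raises :class:`SpectrumIOError` with line numbers for malformed rows,
    missing required metadata keys, an empty data section, or a
    non-monotone axis.
    """
    path = Path(path)
    header_lines: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            header_lines.append(line)
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise SpectrumIOError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumIOError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    header = _parse_header(header_lines)
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise SpectrumIOError(f"{path}: missing required metadata keys: {missing}")
    if len(xs) < 2:
        raise SpectrumIOError(f"{path}: no spectral data (need >= 2 rows)")
    x = np.asarray(xs)
    if not np.all(np.diff(x) > 0):
        raise SpectrumIOError(f"{path}: axis values are not strictly increasing")
    kind = header.pop("axis_kind")
    meta_kwargs = {}
    extras = {}
    for key, value in header.items():
        if key in _META_FIELDS:
            meta_kwargs[key] = _META_FIELDS[key](value)
        else:
            extras[key] = value
    try:
        axis = SpectralAxis(x, kind)  # type: ignore[arg-type]
        meta = AcquisitionMeta(extras=extras, **meta_kwargs)
        return Spectrum(axis, np.asarray(ys), meta)
    except (ValueError, TypeError) as exc:
        raise SpectrumIOError(f"{path}: {exc}") from None


def write_ccd_frame(frame: CCDFrame, path: str | Path) -> None:
    """Write a CCD frame as a delimited matrix with a metadata header."""
    buf = _io.StringIO()
    buf.write(f"# axis_kind={frame.column_axis.kind}\n")
    buf.write(
        "# axis_values=" + ",".join(repr(float(v)) for v in frame.column_axis.values) + "\n"
    )
    for roi in frame.fiber_rois:
        buf.write(f"# roi_{roi.label}={roi.row_start}-{roi.row_end}\n")
    for row in frame.counts:
        buf.write("\t".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_ccd_frame(path: str | Path) -> CCDFrame:
    path = Path(path)
    header_lines: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            header_lines.append(line)
            continue
        try:
            rows.append([float(v) for v in line.split()])
        except ValueError as exc:
            raise SpectrumIOError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    header = _parse_header(header_lines)
    if "axis_kind" not in header or "axis_values" not in header:
        raise SpectrumIOError(f"{path}: frame header needs axis_kind and axis_values")
    if not rows:
        raise SpectrumIOError(f"{path}: no matrix data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise SpectrumIOError(f"{path}: ragged matrix rows (widths {sorted(widths)})")
    axis = SpectralAxis(
        np.array([float(v) for v in header["axis_values"].split(",")]),
        header["axis_kind"],  # type: ignore[arg-type]
    )
    rois = []
    for key, value in header.items():
        if key.startswith("roi_"):
            start, _, end = value.partition("-")
            rois.append(FiberROI(key[4:], int(start), int(end)))  # type: ignore[arg-type]
    return CCDFrame(np.asarray(rows), axis, tuple(rois))


def read_config(path: str | Path, known_keys: Sequence[str]) -> dict[str, str]:
    """Parse a flat ``key = value`` config file.

    Unknown keys are a hard error, so typos fail loudly instead of
    silently running with defaults.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SpectrumIOError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known_keys:
            raise SpectrumIOError(f"{path}:{lineno}: unknown config key {key!r}")
        out[key] = value.strip()
    return out


def read_manifest(path: str | Path) -> list[dict]:
    """Read a tab-separated manifest mapping spectra to roles/thicknesses.

    Columns: ``path`` (required), ``role``, ``thickness_mm``,
    ``fiber_config``.  Paths are resolved relative to the manifest file.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise SpectrumIOError(f"{path}: empty manifest")
    columns = lines[0].split("\t")
    if "path" not in columns:
        raise SpectrumIOError(f"{path}: manifest must have a 'path' column")
    roles = {"sample", "background", "standard", "acetaminophen", "replicate"}
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        values = line.split("\t")
        if len(values) != len(columns):
            raise SpectrumIOError(f"{path}:{lineno}: expected {len(columns)} columns")
        entry = dict(zip(columns, values))
        spath = (path.parent / entry["path"]).resolve()
        if not spath.exists():
            raise SpectrumIOError(f"{path}:{lineno}: no such file {entry['path']}")
        entry["path"] = spath
        if "role" in entry and entry["role"] not in roles:
            raise SpectrumIOError(f"{path}:{lineno}: unknown role {entry['role']!r}")
        if "thickness_mm" in entry and entry["thickness_mm"] != "":
            entry["thickness_mm"] = float(entry["thickness_mm"])
        entries.append(entry)
    return entries


def write_manifest(entries: Sequence[dict], path: str | Path) -> None:
    columns = ["path", "role", "thickness_mm"]
    lines = ["\t".join(columns)]
    for e in entries:
        lines.append("\t".join(str(e.get(c, "")) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")
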