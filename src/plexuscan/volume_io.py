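"""Volume reading/writing and acquisition quality-control gates.

A volume on disk is a directory holding two multi-page TIFF stacks
(``flow.tif`` and ``structural.tif``, one B-scan per page as a depth x
A-scan image) plus a ``meta.json`` sidecar with the scan geometry and
acquisition metadata.  The sidecar field list ships as
``sidecar.schema.json`` next to this module.

Quality gates follow the acquisition protocol: a volume enters analysis only
with signal strength >= 9/10 and with manual segmentation corrections on at
most 5% of its B-scans (15 of 300).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .core import OctaVolume, ScanGeometry
from .errors import FormatError, ValidationError

__all__ = ["OctaVolume", "QCReport", "read_volume", "write_volume",
           "write_labels", "read_labels", "qc_gate", "px_to_mm", "mm_to_px",
           "SIGNAL_STRENGTH_MIN", "CORRECTED_BSCAN_FRACTION_MAX"]

SIGNAL_STRENGTH_MIN = 9
CORRECTED_BSCAN_FRACTION_MAX = 0.05

_GEOMETRY_FIELDS = ("extent_x_mm", "extent_y_mm", "n_ascans", "n_bscans",
                    "n_depth", "axial_px_um", "centre_offset_mm")


@dataclass(frozen=True)
class QCReport:
    """Outcome of the acquisition quality gates.

    ``passed`` is true iff ``reasons`` is empty; each reason is a failed-gate
    label (``"signal_strength"`` or ``"segmentation_correction"``).
    """

    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("passed must equal 'no failure reasons'")


def qc_gate(volume: OctaVolume) -> QCReport:
    """Apply the signal-strength and segmentation-correction gates.

    The correction cap is ``floor(0.05 x n_bscans)`` (exactly 15 B-scans for
    a 300 B-scan cube); both boundary values pass.
    """
    reasons = []
    if volume.signal_strength < SIGNAL_STRENGTH_MIN:
        reasons.append("signal_strength")
    cap = int(np.floor(CORRECTED_BSCAN_FRACTION_MAX * volume.geometry.n_bscans))
    if volume.n_corrected_bscans > cap:
        reasons.append("segmentation_correction")
    return QCReport(passed=not reasons, reasons=tuple(reasons))


def max_corrected_bscans(geometry: ScanGeometry) -> int:
    """Largest number of manually corrected B-scans the QC gate accepts."""
    return int(np.floor(CORRECTED_BSCAN_FRACTION_MAX * geometry.n_bscans))


# --------------------------------------------------------------------------
# Pixel <-> physical coordinates
# --------------------------------------------------------------------------

def px_to_mm(px, geometry: ScanGeometry, axis: str = "x") -> float:
    """Distance (mm) from the volume's first pixel along ``axis`` ('x'|'y')."""
    n, pitch = ((geometry.n_ascans, geometry.pitch_x_mm) if axis == "x"
                else (geometry.n_bscans, geometry.pitch_y_mm))
    px = np.asarray(px)
    if np.any((px < 0) | (px >= n)):
        raise ValidationError(f"pixel index outside 0..{n - 1}")
    out = px * pitch
    return out if out.ndim else float(out)


def mm_to_px(mm, geometry: ScanGeometry, axis: str = "x") -> int:
    """Inverse of :func:`px_to_mm` (nearest grid index)."""
    n, pitch = ((geometry.n_ascans, geometry.pitch_x_mm) if axis == "x"
                else (geometry.n_bscans, geometry.pitch_y_mm))
    px = np.round(np.asarray(mm) / pitch).astype(np.int64)
    if np.any((px < 0) | (px >= n)):
        raise ValidationError("coordinate outside the scan grid")
    return px if px.ndim else int(px)


# --------------------------------------------------------------------------
# Disk format
# --------------------------------------------------------------------------

def write_volume(volume: OctaVolume, path) -> Path:
    """Write a volume directory: flow.tif + structural.tif + meta.json.

    TIFF pages are B-scans (depth x A-scan), so ``(z, y, x)`` grids are
    stored transposed to ``(y, z, x)``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, grid in (("flow", volume.flow), ("structural", volume.structural)):
        tifffile.imwrite(path / f"{name}.tif",
                         np.ascontiguousarray(grid.transpose(1, 0, 2)),
                         compression="zlib")
    geo = volume.geometry
    meta = {f: getattr(geo, f) for f in _GEOMETRY_FIELDS}
    meta.update(signal_strength=int(volume.signal_strength),
                n_corrected_bscans=int(volume.n_corrected_bscans),
                seed=volume.seed)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def write_labels(labels: np.ndarray, path) -> Path:
    """Store a truth-label volume as a zlib-compressed multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(labels.transpose(1, 0, 2)),
                     compression="zlib")
    return path


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).transpose(1, 0, 2)


def _read_sidecar(path: Path) -> dict:
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc
    missing = [f for f in _GEOMETRY_FIELDS if f not in meta]
    if missing:
        raise FormatError(f"sidecar misses geometry fields: {missing}")
    return meta


def read_volume(path) -> OctaVolume:
    """Read a volume directory; reject shape/sidecar mismatches and
    out-of-range intensities."""
    path = Path(path)
    meta = _read_sidecar(path)
    geometry = ScanGeometry(**{f: (tuple(meta[f]) if f == "centre_offset_mm"
                                   else meta[f]) for f in _GEOMETRY_FIELDS})
    grids = {}
    for name in ("flow", "structural"):
        f = path / f"{name}.tif"
        if not f.exists():
            raise FormatError(f"missing {f}")
        stack = tifffile.imread(f)
        if stack.ndim == 2:
            stack = stack[np.newaxis]
        if stack.shape != (geometry.n_bscans, geometry.n_depth,
                           geometry.n_ascans):
            raise FormatError(
                f"{name}.tif shape {stack.shape} does not match sidecar "
                f"({geometry.n_bscans} pages of "
                f"{geometry.n_depth}x{geometry.n_ascans})")
        if float(stack.min()) < 0.0 or float(stack.max()) > 1.0:
            raise FormatError(f"{name} intensities outside [0, 1]")
        grids[name] = stack.transpose(1, 0, 2)
    try:
        return OctaVolume(flow=grids["flow"], structural=grids["structural"],
                          geometry=geometry,
                          signal_strength=meta.get("signal_strength", 10),
                          n_corrected_bscans=meta.get("n_corrected_bscans", 0),
                          seed=meta.get("seed"))
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc
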