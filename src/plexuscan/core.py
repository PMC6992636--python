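"""Shared domain types: scan geometry, layer surfaces, OCTA volumes.

Conventions
-----------
* Volume grids are indexed ``[z, y, x]``: ``z`` is depth (axial), ``y`` the
  B-scan index (slow axis), ``x`` the A-scan index within a B-scan (fast
  axis).  A multi-page TIFF stores one B-scan (a ``z`` x ``x`` image) per
  page.
* Physical retinal coordinates are in mm, signed relative to the foveal
  centre: +x temporal, -x nasal, +y superior, -y inferior (right-eye
  convention).  ``ScanGeometry.centre_offset_mm`` places a volume's centre in
  that frame.
* Depths are in µm from the top of the volume grid unless a function says
  "below the ILM".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SECTORS = ("temporal", "nasal", "superior", "inferior")
PLEXUSES = ("SVP", "ICP", "DCP")


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of one OCTA acquisition.

    Defaults model a 3 x 3-mm cube of 300 B-scans x 300 A-scans (10 µm
    transverse pitch) sampled at 2 µm axially.
    """

    extent_x_mm: float = 3.0
    extent_y_mm: float = 3.0
    n_ascans: int = 300
    n_bscans: int = 300
    n_depth: int = 224
    axial_px_um: float = 2.0
    centre_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.extent_x_mm <= 0 or self.extent_y_mm <= 0:
            raise ValidationError("scan extents must be positive")
        if self.n_ascans < 1 or self.n_bscans < 1 or self.n_depth < 1:
            raise ValidationError("grid sizes must be >= 1")
        if self.axial_px_um <= 0:
            raise ValidationError("axial_px_um must be positive")
        object.__setattr__(self, "centre_offset_mm",
                           (float(self.centre_offset_mm[0]),
                            float(self.centre_offset_mm[1])))

    @property
    def pitch_x_mm(self) -> float:
        return self.extent_x_mm / self.n_ascans

    @property
    def pitch_y_mm(self) -> float:
        return self.extent_y_mm / self.n_bscans

    @property
    def pitch_x_um(self) -> float:
        return 1000.0 * self.pitch_x_mm

    @property
    def pitch_y_um(self) -> float:
        return 1000.0 * self.pitch_y_mm

    @property
    def depth_um(self) -> float:
        """Total axial extent of the grid in µm."""
        return self.n_depth * self.axial_px_um

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_depth, self.n_bscans, self.n_ascans)

    # --- coordinate helpers -------------------------------------------------
    def x_mm(self) -> np.ndarray:
        """Retinal x coordinate (mm from fovea) of each A-scan centre."""
        ox = self.centre_offset_mm[0]
        return ox + (np.arange(self.n_ascans) + 0.5) * self.pitch_x_mm \
            - self.extent_x_mm / 2.0

    def y_mm(self) -> np.ndarray:
        """Retinal y coordinate (mm from fovea) of each B-scan centre."""
        oy = self.centre_offset_mm[1]
        return oy + (np.arange(self.n_bscans) + 0.5) * self.pitch_y_mm \
            - self.extent_y_mm / 2.0

    def z_um(self) -> np.ndarray:
        """Depth (µm from volume top) of each voxel centre."""
        return (np.arange(self.n_depth) + 0.5) * self.axial_px_um

    def eccentricity_mm(self) -> np.ndarray:
        """Radial eccentricity map, shape (n_bscans, n_ascans)."""
        x = self.x_mm()[np.newaxis, :]
        y = self.y_mm()[:, np.newaxis]
        return np.hypot(x, y)

    def sector_map(self) -> np.ndarray:
        """Dominant-axis sector index per (y, x) pixel (index into SECTORS)."""
        x = self.x_mm()[np.newaxis, :]
        y = self.y_mm()[:, np.newaxis]
        x, y = np.broadcast_arrays(x, y)
        out = np.where(np.abs(x) >= np.abs(y),
                       np.where(x >= 0, 0, 1),
                       np.where(y >= 0, 2, 3))
        return out.astype(np.int8)


_SURFACE_NAMES = ("ilm", "ipl_two_thirds", "inl_opl", "opl_onl", "rpe")


@dataclass
class LayerSurfaces:
    """Per-(y, x) depth maps (µm from volume top) of the retinal interfaces.

    ``ipl_two_thirds`` is the boundary at the inner two-thirds of the IPL
    (the outer boundary of the superficial vascular plexus slab).
    """

    ilm: np.ndarray
    ipl_two_thirds: np.ndarray
    inl_opl: np.ndarray
    opl_onl: np.ndarray
    rpe: np.ndarray

    def __post_init__(self):
        maps = [np.asarray(getattr(self, n), dtype=np.float64) for n in _SURFACE_NAMES]
        shape = maps[0].shape
        for n, m in zip(_SURFACE_NAMES, maps):
            if m.shape != shape:
                raise ValidationError("surface maps must share one shape")
            setattr(self, n, m)
        for a, b in zip(_SURFACE_NAMES[:-1], _SURFACE_NAMES[1:]):
            if not np.all(getattr(self, a) < getattr(self, b)):
                raise ValidationError(
                    f"surfaces out of order: {a} must lie above {b} everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm.shape

    def thickness(self) -> np.ndarray:
        """Retinal thickness map (RPE - ILM), µm."""
        return self.rpe - self.ilm

    def names(self) -> tuple[str, ...]:
        return _SURFACE_NAMES

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _SURFACE_NAMES}


@dataclass
class OctaVolume:
    """Paired flow/structural grids with geometry and acquisition metadata.

    Intensities are normalized to [0, 1]; ``signal_strength`` is the device
    quality index (0-10) and ``n_corrected_bscans`` the number of B-scans
    whose layer segmentation was manually corrected.
    """

    flow: np.ndarray
    structural: np.ndarray
    geometry: ScanGeometry
    signal_strength: int = 10
    n_corrected_bscans: int = 0
    seed: int | None = None
    surfaces: LayerSurfaces | None = field(default=None, repr=False)

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=np.float32)
        self.structural = np.asarray(self.structural, dtype=np.float32)
        if self.flow.shape != self.structural.shape:
            raise ValidationError("flow and structural grids must share a shape")
        if self.flow.shape != self.geometry.shape:
            raise ValidationError(
                f"grid shape {self.flow.shape} does not match geometry "
                f"{self.geometry.shape}")
        for name, grid in (("flow", self.flow), ("structural", self.structural)):
            lo, hi = float(grid.min(initial=0.0)), float(grid.max(initial=0.0))
            if lo < 0.0 or hi > 1.0:
                raise ValidationError(
                    f"{name} intensities outside [0, 1] (range {lo:.3g}..{hi:.3g})")
        if not (0 <= int(self.signal_strength) <= 10):
            raise ValidationError("signal_strength must be in 0..10")
        if int(self.n_corrected_bscans) < 0:
            raise ValidationError("n_corrected_bscans must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flow.shape
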