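"""Layer-surface segmentation, plexus slabs, projection removal, en face.

The three plexus slabs tile the inner retina with no overlap:

* SVP — from the ILM to the inner two-thirds of the IPL;
* ICP — from the SVP's outer boundary to just behind (default +6 µm) the
  INL-OPL interface;
* DCP — from the ICP's outer boundary to just behind the OPL-ONL interface.

Projection artifacts are removed with the projection-resolved rule: a flow
voxel survives only if it strictly exceeds the maximum of all shallower
voxels of its A-line.  The rule is idempotent and never increases a voxel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .core import LayerSurfaces, OctaVolume, ScanGeometry
from .errors import SegmentationError, ValidationError

__all__ = ["SegmentationConfig", "SlabDefinition", "EnFaceImage",
           "segment_surfaces", "define_slabs", "remove_projection", "enface"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Structural-volume segmentation knobs.

    The ILM is the first axial gradient maximum from the top exceeding
    ``ilm_gradient_threshold``; the RPE is the brightest (axially smoothed)
    band.  Intermediate interfaces sit at fixed fractional depths of the
    ILM-RPE span — fractions calibrated on the phantom's layer model.
    """

    ilm_gradient_threshold: float = 0.12
    rpe_min_intensity: float = 0.30
    max_invalid_fraction: float = 0.05
    axial_smooth_sigma_px: float = 1.5
    surface_median_um: float = 50.0
    f_ipl_two_thirds: float = 0.30
    f_inl_opl: float = 0.43
    f_opl_onl: float = 0.62


def segment_surfaces(structural: np.ndarray, geometry: ScanGeometry,
                     config: SegmentationConfig | None = None) -> LayerSurfaces:
    """Derive the five interface maps from a structural grid.

    Raises :class:`SegmentationError` when more than
    ``config.max_invalid_fraction`` of A-lines lack an ILM edge or an RPE
    band (e.g. an all-zero grid).
    """
    config = config or SegmentationConfig()
    vol = np.asarray(structural, dtype=np.float32)
    if vol.shape != geometry.shape:
        raise ValidationError("structural grid does not match geometry")
    nz = vol.shape[0]
    axial = geometry.axial_px_um
    smooth = gaussian_filter1d(vol, config.axial_smooth_sigma_px, axis=0)

    # The ILM edge is sharp (one or two voxels): detect it on the raw grid —
    # axial smoothing would dilute it below the threshold while leaving the
    # much stronger RPE edge as the first candidate.
    grad = np.diff(vol, axis=0)                         # (nz-1, ny, nx)
    candidate = grad > config.ilm_gradient_threshold
    has_ilm = candidate.any(axis=0)
    first = np.argmax(candidate, axis=0)
    # climb to the local gradient peak (the edge centre)
    for _ in range(4):
        nxt = np.minimum(first + 1, nz - 2)
        better = np.take_along_axis(grad, nxt[np.newaxis], 0)[0] > \
            np.take_along_axis(grad, first[np.newaxis], 0)[0]
        first = np.where(better & has_ilm, nxt, first)
    ilm = (first + 1.0) * axial

    rpe_z = np.argmax(smooth, axis=0)
    rpe_peak = np.max(smooth, axis=0)
    has_rpe = (rpe_peak >= config.rpe_min_intensity) & (rpe_z * axial > ilm)
    valid = has_ilm & has_rpe
    invalid_fraction = 1.0 - valid.mean()
    if invalid_fraction > config.max_invalid_fraction:
        raise SegmentationError(
            f"{invalid_fraction:.1%} of A-lines lack ILM/RPE signal")
    rpe = rpe_z * axial

    if not valid.all():
        ilm = np.where(valid, ilm, np.median(ilm[valid]))
        rpe = np.where(valid, rpe, np.median(rpe[valid]))

    # smooth the surface maps over ~surface_median_um laterally
    kx = max(1, int(round(config.surface_median_um / geometry.pitch_x_um)))
    ky = max(1, int(round(config.surface_median_um / geometry.pitch_y_um)))
    ilm = median_filter(ilm, size=(ky, kx), mode="nearest")
    rpe = median_filter(rpe, size=(ky, kx), mode="nearest")
    rpe = np.maximum(rpe, ilm + 4 * axial)   # keep ordering under noise

    span = rpe - ilm
    return LayerSurfaces(
        ilm=ilm,
        ipl_two_thirds=ilm + config.f_ipl_two_thirds * span,
        inl_opl=ilm + config.f_inl_opl * span,
        opl_onl=ilm + config.f_opl_onl * span,
        rpe=rpe,
    )


@dataclass
class SlabDefinition:
    """A depth slab [inner, outer) in µm-from-volume-top maps."""

    name: str
    inner: np.ndarray
    outer: np.ndarray

    def __post_init__(self):
        self.inner = np.asarray(self.inner, dtype=np.float64)
        self.outer = np.asarray(self.outer, dtype=np.float64)
        if self.inner.shape != self.outer.shape:
            raise ValidationError("slab boundary maps must share a shape")
        if not np.all(self.inner < self.outer):
            raise ValidationError(
                f"slab {self.name}: inner boundary must lie above outer")

    def thickness(self) -> np.ndarray:
        return self.outer - self.inner

    def voxel_mask(self, geometry: ScanGeometry) -> np.ndarray:
        """Boolean (z, y, x) membership mask (half-open in depth)."""
        z = geometry.z_um()[:, np.newaxis, np.newaxis]
        return (z >= self.inner) & (z < self.outer)


def define_slabs(surfaces: LayerSurfaces,
                 delta_um: float = 6.0) -> dict[str, SlabDefinition]:
    """Build the three non-overlapping plexus slabs from the surfaces.

    ``delta_um`` is the "just behind" offset added to the INL-OPL and
    OPL-ONL interfaces (default one axial resolution element, 6 µm).
    With half-open depth intervals the slabs tile
    [ILM, OPL-ONL + delta) exactly.
    """
    return {
        "SVP": SlabDefinition("SVP", surfaces.ilm, surfaces.ipl_two_thirds),
        "ICP": SlabDefinition("ICP", surfaces.ipl_two_thirds,
                              surfaces.inl_opl + delta_um),
        "DCP": SlabDefinition("DCP", surfaces.inl_opl + delta_um,
                              surfaces.opl_onl + delta_um),
    }


def remove_projection(flow: np.ndarray) -> np.ndarray:
    """Projection-resolved artifact removal.

    Per A-line, a voxel is retained iff it strictly exceeds the maximum of
    all shallower voxels; otherwise it is set to 0.  Output <= input
    voxelwise; applying the rule twice changes nothing.
    """
    flow = np.asarray(flow)
    running = np.maximum.accumulate(flow, axis=0)
    shallower = np.zeros_like(flow)
    shallower[1:] = running[:-1]
    return np.where(flow > shallower, flow, 0).astype(flow.dtype)


@dataclass
class EnFaceImage:
    """Normalized en face projection of a slab.

    ``valid`` marks pixels whose slab has non-zero thickness; invalid pixels
    hold 0 and are excluded downstream.
    """

    data: np.ndarray
    valid: np.ndarray
    pitch_x_um: float
    pitch_y_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ValidationError("en face data/valid shapes differ")
        sel = self.data[self.valid]
        if sel.size and (sel.min() < 0.0 or sel.max() > 1.0):
            raise ValidationError("en face intensities outside [0, 1]")

    @property
    def shape(self):
        return self.data.shape


def enface(flow: np.ndarray, slab: SlabDefinition, geometry: ScanGeometry,
           method: str = "max", provenance: dict | None = None) -> EnFaceImage:
    """Project the flow voxels between the slab surfaces to an en face image.

    ``method`` is ``"max"`` (default: robust to slab thickness for
    voxel-thin capillaries) or ``"mean"``.  The image is min-max normalized
    over its valid pixels.
    """
    if method not in ("max", "mean"):
        raise ValidationError("en face method must be 'max' or 'mean'")
    flow = np.asarray(flow, dtype=np.float32)
    if flow.shape != geometry.shape:
        raise ValidationError("flow grid does not match geometry")
    mask = slab.voxel_mask(geometry)
    counts = mask.sum(axis=0)
    valid = counts > 0
    if method == "max":
        img = np.where(mask, flow, -np.inf).max(axis=0)
        img[~valid] = 0.0
    else:
        img = np.where(mask, flow, 0.0).sum(axis=0)
        img = np.divide(img, counts, out=np.zeros_like(img),
                        where=valid)
    sel = img[valid]
    if sel.size:
        lo, hi = float(sel.min()), float(sel.max())
        if hi > lo:
            img = (img - lo) / (hi - lo)
        else:
            img = np.zeros_like(img)
        img[~valid] = 0.0
    return EnFaceImage(data=np.clip(img, 0.0, 1.0), valid=valid,
                       pitch_x_um=geometry.pitch_x_um,
                       pitch_y_um=geometry.pitch_y_um,
                       provenance=provenance or {"slab": slab.name,
                                                 "method": method})
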