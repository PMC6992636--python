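"""Synthetic OCTA phantom generator with known plexus geometry and density.

The phantom emulates a healthy posterior pole imaged as 3 x 3-mm OCTA cubes:
three capillary plexuses (SVP, ICP, DCP) whose depth below the ILM and whose
en face capillary density (CD) vary with eccentricity, large retinal vessels
confined to the superficial slab, projection tails cast by every flow voxel
onto deeper voxels of the same A-line, and speckle/salt noise on the flow
grid.  Default density anchors are the published healthy-cohort means per
sector and eccentricity; default depth anchors put the plexuses at 67, 115
and 157 µm below the ILM at 1 mm and let them converge peripherally until the
ICP vanishes (density 0 at ``icp_extinction_mm``), leaving two plexuses
spaced 55 µm.

Capillary patterns are rasterized on a *global* retinal pixel grid, tiled in
0.25-mm tiles whose RNG is keyed on (seed, plexus, tile index): two volumes
of the same subject that overlap on the retina therefore contain the same
vasculature, which makes montage registration against ground truth possible.

Labels: 0 background, 1 SVP, 2 ICP, 3 DCP, 4 large vessel, 5 projection tail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.interpolate import PchipInterpolator
from skimage.draw import disk as draw_disk

from .core import LayerSurfaces, OctaVolume, PLEXUSES, ScanGeometry, SECTORS
from .errors import ValidationError

__all__ = [
    "ScanGeometry", "LayerSurfaces", "ThicknessProfile", "TruthConfig",
    "NoiseConfig", "PhantomTruth", "PhantomAnnotations",
    "make_layer_surfaces", "make_plexus_truth", "synthesize_volume",
    "LABEL_BG", "LABEL_SVP", "LABEL_ICP", "LABEL_DCP", "LABEL_VESSEL",
    "LABEL_TAIL",
]

LABEL_BG, LABEL_SVP, LABEL_ICP, LABEL_DCP, LABEL_VESSEL, LABEL_TAIL = range(6)
PLEXUS_LABELS = {"SVP": LABEL_SVP, "ICP": LABEL_ICP, "DCP": LABEL_DCP}

# Disjoint flow-amplitude bands, increasing with plexus depth.  In-situ flow
# then always strictly dominates both projected tails (tail_coeff x a
# shallower amplitude) and any shallower capillary in the same A-line, even
# after additive speckle of up to 0.05 — the behaviour projection-resolved
# OCTA shows on real retinas.  Capillary amplitudes sit well below the
# large-vessel level (1.0) so that the smoothed capillary field cannot cross
# the 0.4 vessel-mask threshold.
AMPLITUDE_BANDS = {"SVP": (0.40, 0.52), "ICP": (0.58, 0.70), "DCP": (0.76, 0.88)}
VESSEL_AMPLITUDE = 1.0
DEPTH_JITTER_UM = 4.0   # per-capillary-segment axial jitter (plexus thickness)
TILE_PX = 25            # 0.25 mm at the default 10 µm pitch
_SUBCELL_PX = 5         # density-exactness scale (0.05 mm)
_TILE_IDX_OFFSET = 1 << 20


# --------------------------------------------------------------------------
# Retinal thickness / layer-surface model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThicknessProfile:
    """Radial retinal-thickness model: foveal pit, parafoveal bulge,
    progressive peripheral thinning; plus fixed fractional depths of the
    inner-layer interfaces (calibrated on this phantom's layer model).

    Thickness (µm) at eccentricity ``e`` (mm)::

        T(e) = base(e) - pit_depth_um * exp(-(e / pit_sigma_mm)^2)
        base(e) = peripheral_um + (parafoveal_max_um - peripheral_um)
                  * exp(-(max(e - decline_start_mm, 0) / decline_scale_mm)^2)
    """

    pit_depth_um: float = 120.0
    pit_sigma_mm: float = 0.35
    parafoveal_max_um: float = 320.0
    peripheral_um: float = 160.0
    decline_start_mm: float = 1.5
    decline_scale_mm: float = 5.5
    rpe_depth_um: float = 420.0
    tilt_um_per_mm: tuple[float, float] = (0.0, 0.0)
    # fractional depths (of ILM..RPE thickness) of the inner interfaces
    f_ipl_two_thirds: float = 0.30
    f_inl_opl: float = 0.43
    f_opl_onl: float = 0.62

    def __post_init__(self):
        if not (0.0 < self.f_ipl_two_thirds < self.f_inl_opl
                < self.f_opl_onl < 1.0):
            raise ValidationError("interface fractions must satisfy "
                                  "0 < f_ipl23 < f_inl_opl < f_opl_onl < 1")
        if self.parafoveal_max_um <= 0 or self.peripheral_um <= 0:
            raise ValidationError("thicknesses must be positive")
        if self.pit_depth_um < 0 or self.pit_sigma_mm <= 0:
            raise ValidationError("invalid foveal pit parameters")
        if self.thickness(0.0) <= 0:
            raise ValidationError(
                "pit depth produces non-positive central thickness "
                "(crossing surfaces)")

    @classmethod
    def flat(cls, thickness_um: float = 300.0,
             rpe_depth_um: float = 420.0) -> "ThicknessProfile":
        """Uniform retina: all surfaces are constant planes."""
        return cls(pit_depth_um=0.0, parafoveal_max_um=thickness_um,
                   peripheral_um=thickness_um, rpe_depth_um=rpe_depth_um)

    def thickness(self, ecc_mm):
        e = np.asarray(ecc_mm, dtype=np.float64)
        base = self.peripheral_um + (self.parafoveal_max_um - self.peripheral_um) \
            * np.exp(-(np.maximum(e - self.decline_start_mm, 0.0)
                       / self.decline_scale_mm) ** 2)
        pit = self.pit_depth_um * np.exp(-(e / self.pit_sigma_mm) ** 2)
        return base - pit


def make_layer_surfaces(geometry: ScanGeometry,
                        profile: ThicknessProfile | None = None) -> LayerSurfaces:
    """Build the five interface depth maps for a volume.

    The RPE is a (possibly tilted) plane at ``profile.rpe_depth_um``; the ILM
    sits ``thickness`` above it; inner interfaces lie at fixed fractions of
    the local thickness below the ILM.
    """
    profile = profile or ThicknessProfile()
    ecc = geometry.eccentricity_mm()
    t = profile.thickness(ecc)
    if np.any(t <= 0):
        raise ValidationError("thickness profile produces crossing surfaces")
    tx, ty = profile.tilt_um_per_mm
    plane = profile.rpe_depth_um + tx * geometry.x_mm()[np.newaxis, :] \
        + ty * geometry.y_mm()[:, np.newaxis]
    rpe = np.broadcast_to(plane, ecc.shape).astype(np.float64).copy()
    ilm = rpe - t
    if np.any(ilm <= 0) or np.any(rpe + 12.0 >= geometry.depth_um):
        raise ValidationError("surfaces fall outside the volume depth range")
    return LayerSurfaces(
        ilm=ilm,
        ipl_two_thirds=ilm + profile.f_ipl_two_thirds * t,
        inl_opl=ilm + profile.f_inl_opl * t,
        opl_onl=ilm + profile.f_opl_onl * t,
        rpe=rpe,
    )


# --------------------------------------------------------------------------
# Plexus truth (anchored density/depth functions)
# --------------------------------------------------------------------------

# Healthy-cohort capillary density anchors, % at eccentricities in mm.
# The nasal 4-mm cell is unavailable (optic nerve head).
DEFAULT_DENSITY_ANCHORS = {
    "temporal": {
        "SVP": [(1, 33.0), (2, 32.7), (4, 25.5), (8, 15.9), (10, 11.7)],
        "ICP": [(1, 17.2), (2, 19.0), (4, 12.0), (8, 1.9), (10, 0.4)],
        "DCP": [(1, 18.7), (2, 18.4), (4, 17.7), (8, 15.2), (10, 11.8)],
    },
    "nasal": {
        "SVP": [(1, 33.2), (2, 35.0), (8, 21.0), (10, 15.2)],
        "ICP": [(1, 21.5), (2, 19.3), (8, 8.5), (10, 3.9)],
        "DCP": [(1, 20.5), (2, 19.5), (8, 13.2), (10, 10.3)],
    },
    "superior": {
        "SVP": [(1, 29.3), (2, 35.8), (4, 36.5), (8, 14.3), (10, 11.5)],
        "ICP": [(1, 24.8), (2, 24.0), (4, 17.9), (8, 3.3), (10, 1.6)],
        "DCP": [(1, 29.1), (2, 18.4), (4, 16.7), (8, 16.4), (10, 10.3)],
    },
    "inferior": {
        "SVP": [(1, 32.5), (2, 34.2), (4, 35.7), (8, 13.6), (10, 10.7)],
        "ICP": [(1, 22.2), (2, 18.5), (4, 13.9), (8, 0.8), (10, 0.9)],
        "DCP": [(1, 26.5), (2, 22.9), (4, 16.3), (8, 16.7), (10, 14.8)],
    },
}

# Matching inter-subject standard deviations (used for cohort jitter).
DEFAULT_DENSITY_SDS = {
    "temporal": {
        "SVP": [(1, 1.3), (2, 1.5), (4, 2.1), (8, 2.4), (10, 1.8)],
        "ICP": [(1, 2.4), (2, 5.0), (4, 2.2), (8, 0.9), (10, 0.1)],
        "DCP": [(1, 4.4), (2, 4.1), (4, 2.2), (8, 2.9), (10, 3.9)],
    },
    "nasal": {
        "SVP": [(1, 0.8), (2, 1.8), (8, 2.3), (10, 2.4)],
        "ICP": [(1, 2.9), (2, 2.8), (8, 3.0), (10, 1.8)],
        "DCP": [(1, 3.6), (2, 6.0), (8, 2.6), (10, 1.7)],
    },
    "superior": {
        "SVP": [(1, 2.0), (2, 1.7), (4, 3.5), (8, 2.2), (10, 1.4)],
        "ICP": [(1, 5.0), (2, 4.3), (4, 3.5), (8, 1.4), (10, 0.9)],
        "DCP": [(1, 4.0), (2, 7.1), (4, 5.7), (8, 3.3), (10, 2.5)],
    },
    "inferior": {
        "SVP": [(1, 1.6), (2, 2.2), (4, 2.7), (8, 3.0), (10, 2.6)],
        "ICP": [(1, 4.4), (2, 4.6), (4, 2.6), (8, 0.5), (10, 0.4)],
        "DCP": [(1, 3.0), (2, 3.3), (4, 3.5), (8, 2.9), (10, 4.7)],
    },
}

# Plexus centre depths below the ILM (µm): 67/115/157 at 1 mm, converging
# peripherally; SVP-DCP spacing is 55 µm throughout 9-11 mm.
DEFAULT_DEPTH_ANCHORS = {
    "SVP": [(1, 67.0), (3, 63.0), (5, 58.0), (7, 52.0), (9, 46.0), (11, 42.0)],
    "ICP": [(1, 115.0), (3, 107.0), (5, 100.0), (7, 88.0), (8, 80.0)],
    "DCP": [(1, 157.0), (3, 148.0), (5, 130.0), (7, 112.0), (9, 101.0),
            (11, 97.0)],
}

DEFAULT_ICP_EXTINCTION_MM = {"temporal": 8.5, "nasal": 9.5,
                             "superior": 8.5, "inferior": 8.5}


class AnchorCurve:
    """Monotone-between-anchors interpolant; constant beyond the end anchors.

    A single anchor yields a constant function.  Uses shape-preserving PCHIP,
    so the curve is monotone between every pair of consecutive anchors.
    """

    def __init__(self, anchors):
        anchors = sorted((float(e), float(v)) for e, v in anchors)
        if not anchors:
            raise ValidationError("anchor list is empty")
        self.ecc = np.array([a[0] for a in anchors])
        self.val = np.array([a[1] for a in anchors])
        if len(self.ecc) > 1 and np.any(np.diff(self.ecc) <= 0):
            raise ValidationError("anchor eccentricities must be distinct")
        self._interp = (PchipInterpolator(self.ecc, self.val)
                        if len(self.ecc) > 1 else None)

    def __call__(self, ecc_mm):
        e = np.clip(np.asarray(ecc_mm, dtype=np.float64),
                    self.ecc[0], self.ecc[-1])
        if self._interp is None:
            out = np.full_like(e, self.val[0])
        else:
            out = self._interp(e)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TruthConfig:
    """Overrides and free parameters for :func:`make_plexus_truth`."""

    density_anchors: dict | None = None      # sector -> plexus -> [(ecc, %)]
    density_sds: dict | None = None          # same structure (jitter scale)
    depth_anchors: dict | None = None        # plexus -> [(ecc, µm)] (all sectors)
    icp_extinction_mm: dict | float | None = None
    extinction_taper_mm: float = 1.5
    faz_radius_um: float = 250.0
    density_jitter_scale: float = 0.0        # 1.0 => jitter by the anchor SDs
    vessel_calibre_um: float = 60.0
    vessels_per_axis: int = 2
    tail_coeff: float = 0.6


@dataclass(frozen=True)
class NoiseConfig:
    """Flow-grid noise: additive uniform speckle plus sparse salt voxels.

    Salt models isolated decorrelation sparkle sitting just under the flow
    binarization threshold; a correct binarizer rejects every salt voxel
    while counting all true flow.
    """

    speckle_max: float = 0.05
    salt_rate: float = 1e-4
    salt_lo: float = 0.05
    salt_hi: float = 0.10

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(speckle_max=0.0, salt_rate=0.0)


@dataclass
class PhantomTruth:
    """Ground-truth plexus depth/density functions and large-vessel map.

    ``density`` applies the foveal avascular zone and (for the ICP) the
    extinction taper; pass ``apply_extinction=False`` for the raw anchored
    interpolation of the density table.
    """

    density_curves: dict            # sector -> plexus -> AnchorCurve
    depth_curves: dict              # plexus -> AnchorCurve
    icp_extinction_mm: dict         # sector -> mm
    extinction_taper_mm: float
    faz_radius_um: float
    large_vessel_centrelines: list  # [{"points_mm": (N,2) array, "calibre_um": f}]
    seed: int
    tail_coeff: float = 0.6

    def density(self, plexus, ecc_mm, sector, apply_extinction=True):
        """True capillary density (%) at radial eccentricity ``ecc_mm``."""
        e = np.asarray(ecc_mm, dtype=np.float64)
        d = np.asarray(self.density_curves[sector][plexus](e))
        if plexus == "ICP" and apply_extinction:
            ext = self.icp_extinction_mm[sector]
            ramp = np.clip((ext - e) / self.extinction_taper_mm, 0.0, 1.0)
            d = d * ramp
        d = np.where(e * 1000.0 < self.faz_radius_um, 0.0, d)
        d = np.clip(d, 0.0, 100.0)
        return d if d.ndim else float(d)

    def depth(self, plexus, ecc_mm, sector=None):
        """True plexus centre depth below the ILM (µm)."""
        return self.depth_curves[plexus](ecc_mm)

    def validate(self):
        """Check depth ordering wherever the ICP exists."""
        ecc = np.arange(0.5, 12.01, 0.1)
        svp, icp, dcp = (np.asarray(self.depth_curves[p](ecc)) for p in PLEXUSES)
        for sector in SECTORS:
            icp_d = np.asarray(self.density(
                "ICP", ecc, sector, apply_extinction=True))
            live = icp_d > 1.0
            if np.any(svp[live] >= icp[live]) or np.any(icp[live] >= dcp[live]):
                raise ValidationError(
                    "depth anchors violate SVP < ICP < DCP ordering")
            if np.any(svp >= dcp):
                raise ValidationError("depth anchors violate SVP < DCP ordering")
        return self


def _jittered(anchors, sds, scale, rng):
    sd_at = dict((float(e), float(s)) for e, s in sds)
    out = []
    for e, v in anchors:
        sd = sd_at.get(float(e), 0.0)
        out.append((e, max(0.0, v + scale * sd * rng.standard_normal())))
    return out


def _make_vessels(config: TruthConfig, rng) -> list:
    """Arcade-like large vessels: two roughly-horizontal and two roughly-
    vertical sinusoidal polylines offset ~0.75 mm from the foveal axes."""
    vessels = []
    t = np.arange(-12.0, 12.0 + 1e-9, 0.05)
    for axis in ("h", "v"):
        for i in range(config.vessels_per_axis):
            base = (0.75 if i % 2 == 0 else -0.75) * (1 + i // 2)
            off = base + rng.uniform(-0.1, 0.1)
            amp = rng.uniform(0.15, 0.3)
            lam = rng.uniform(4.0, 7.0)
            phase = rng.uniform(0, 2 * math.pi)
            wig = off + amp * np.sin(2 * math.pi * t / lam + phase)
            pts = np.column_stack([t, wig] if axis == "h" else [wig, t])
            vessels.append({"points_mm": pts,
                            "calibre_um": config.vessel_calibre_um})
    return vessels


def make_plexus_truth(config: TruthConfig | None = None,
                      seed: int = 0) -> PhantomTruth:
    """Build the anchored truth functions (optionally subject-jittered).

    With ``config.density_jitter_scale > 0`` every density anchor is
    perturbed by ``scale x SD x N(0,1)`` using the cohort SD table, which is
    how a synthetic cohort of subjects is drawn.
    """
    config = config or TruthConfig()
    rng = default_rng(SeedSequence((int(seed), 101)))
    dens_anchors = config.density_anchors or DEFAULT_DENSITY_ANCHORS
    sds = config.density_sds or DEFAULT_DENSITY_SDS
    depth_anchors = config.depth_anchors or DEFAULT_DEPTH_ANCHORS

    density_curves = {}
    for sector in SECTORS:
        sector_anchors = dens_anchors.get(sector, dens_anchors)
        density_curves[sector] = {}
        for plexus in PLEXUSES:
            anchors = sector_anchors[plexus]
            if config.density_jitter_scale > 0:
                sector_sds = sds.get(sector, {}).get(plexus, [])
                anchors = _jittered(anchors, sector_sds,
                                    config.density_jitter_scale, rng)
            density_curves[sector][plexus] = AnchorCurve(anchors)

    depth_curves = {p: AnchorCurve(depth_anchors[p]) for p in PLEXUSES}

    ext = config.icp_extinction_mm
    if ext is None:
        ext = dict(DEFAULT_ICP_EXTINCTION_MM)
    elif not isinstance(ext, dict):
        ext = {s: float(ext) for s in SECTORS}

    truth = PhantomTruth(
        density_curves=density_curves,
        depth_curves=depth_curves,
        icp_extinction_mm=ext,
        extinction_taper_mm=config.extinction_taper_mm,
        faz_radius_um=config.faz_radius_um,
        large_vessel_centrelines=_make_vessels(config, rng),
        seed=int(seed),
        tail_coeff=config.tail_coeff,
    )
    return truth.validate()


# --------------------------------------------------------------------------
# Volume synthesis
# --------------------------------------------------------------------------

@dataclass
class PhantomAnnotations:
    """Per-voxel ground-truth labels and per-pixel truth masks for a volume."""

    labels: np.ndarray                 # uint8 (z, y, x)
    capillary_masks: dict              # plexus -> bool (y, x)
    vessel_mask: np.ndarray            # bool (y, x)
    geometry: ScanGeometry
    truth: PhantomTruth = field(repr=False, default=None)


def _walk_path(rng, start):
    """Meandering open capillary segment (random direction walk).

    Segment lengths of 8-22 px (80-220 µm at the default pitch) match
    intercapillary segment lengths and keep the realized pattern close to
    spatially homogeneous at the density-window scale.
    """
    n = int(rng.integers(8, 23))
    theta = rng.uniform(0, 2 * math.pi) + np.cumsum(rng.normal(0, 0.35, n))
    steps = np.column_stack([np.cos(theta), np.sin(theta)])
    pos = np.asarray(start, dtype=np.float64) + np.cumsum(steps, axis=0)
    return np.round(pos).astype(np.int64)

def _loop_path(rng, start):
    """Closed lobular loop (the deep plexus' anastomotic units)."""
    cx, cy = start
    rx, ry = rng.uniform(2.5, 6.0, size=2)
    rot = rng.uniform(0, math.pi)
    n = max(12, int(2 * math.pi * max(rx, ry) * 1.5))
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ex, ey = rx * np.cos(t), ry * np.sin(t)
    x = cx + ex * math.cos(rot) - ey * math.sin(rot)
    y = cy + ex * math.sin(rot) + ey * math.cos(rot)
    return np.round(np.column_stack([x, y])).astype(np.int64)


def _render_tile(truth, plexus, plexus_idx, ti, tj, pitch_mm):
    """Rasterize one global tile of one plexus.

    Returns (gx, gy, depth_jitter_um, amplitude) arrays for the marked
    capillary pixels.  Deterministic in (truth.seed, plexus, ti, tj).
    """
    tile = TILE_PX
    gx0, gy0 = ti * tile, tj * tile
    xs = (gx0 + np.arange(tile) + 0.5) * pitch_mm
    ys = (gy0 + np.arange(tile) + 0.5) * pitch_mm
    xg, yg = np.meshgrid(xs, ys, indexing="xy")   # [row=y, col=x]
    ecc = np.hypot(xg, yg)
    sector_idx = np.where(np.abs(xg) >= np.abs(yg),
                          np.where(xg >= 0, 0, 1),
                          np.where(yg >= 0, 2, 3))
    dens = np.zeros_like(ecc)
    for s, sector in enumerate(SECTORS):
        m = sector_idx == s
        if np.any(m):
            dens[m] = truth.density(plexus, ecc[m], sector)
    target = int(round(dens.sum() / 100.0))
    if target <= 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),) * 2

    rng = default_rng(SeedSequence(
        (truth.seed, 5, plexus_idx, ti + _TILE_IDX_OFFSET,
         tj + _TILE_IDX_OFFSET)))
    marked = np.zeros((tile, tile), dtype=bool)
    allowed = dens > 0.0
    jit_grid = np.zeros((tile, tile))
    amp_grid = np.zeros((tile, tile))
    lo, hi = AMPLITUDE_BANDS[plexus]
    count, attempts = 0, 0
    make_path = _loop_path if plexus == "DCP" else _walk_path
    while count < target and attempts < 400:
        attempts += 1
        # start each stroke on a still-unmarked allowed pixel: capillary
        # beds are space-filling, and near-uniform coverage keeps the
        # smoothed capillary field well below the vessel-mask threshold
        open_y, open_x = np.nonzero(allowed & ~marked)
        if open_y.size == 0:
            break
        j = int(rng.integers(open_y.size))
        path = make_path(rng, (float(open_x[j]), float(open_y[j])))
        stroke_jit = rng.uniform(-DEPTH_JITTER_UM, DEPTH_JITTER_UM)
        stroke_amp = rng.uniform(lo, hi)
        for x, y in path:
            if 0 <= x < tile and 0 <= y < tile and allowed[y, x] \
                    and not marked[y, x]:
                marked[y, x] = True
                jit_grid[y, x] = stroke_jit
                amp_grid[y, x] = stroke_amp
                count += 1
                if count >= target:
                    break

    # Enforce the density at 5 x 5-px subcell resolution: integer subcell
    # targets by largest remainder, then trim/top-up each subcell.  The
    # realized pattern keeps its stroke structure but its local density is
    # exact at the scale of the 0.1-mm sampling windows.
    cell = _SUBCELL_PX
    n_cells = tile // cell
    raw = dens.reshape(n_cells, cell, n_cells, cell).sum(axis=(1, 3)) / 100.0
    cell_targets = np.floor(raw).astype(np.int64)
    remainder = target - int(cell_targets.sum())
    if remainder > 0:
        order = np.argsort(-(raw - np.floor(raw)), axis=None, kind="stable")
        for k in order[:remainder]:
            cell_targets.flat[k] += 1
    for cy in range(n_cells):
        for cx in range(n_cells):
            sl_ = (slice(cy * cell, (cy + 1) * cell),
                   slice(cx * cell, (cx + 1) * cell))
            m = marked[sl_]
            t = int(cell_targets[cy, cx])
            have = int(m.sum())
            if have > t:
                yy, xx = np.nonzero(m)
                drop = rng.choice(have, size=have - t, replace=False)
                marked[sl_][yy[drop], xx[drop]] = False
            elif have < t:
                yy, xx = np.nonzero(allowed[sl_] & ~m)
                if yy.size:
                    add = rng.choice(yy.size, size=min(t - have, yy.size),
                                     replace=False)
                    sub_m = marked[sl_]
                    sub_m[yy[add], xx[add]] = True
                    jit_grid[sl_][yy[add], xx[add]] = rng.uniform(
                        -DEPTH_JITTER_UM, DEPTH_JITTER_UM, size=add.size)
                    amp_grid[sl_][yy[add], xx[add]] = rng.uniform(
                        lo, hi, size=add.size)

    yy, xx = np.nonzero(marked)
    return (gx0 + xx.astype(np.int64), gy0 + yy.astype(np.int64),
            jit_grid[yy, xx], amp_grid[yy, xx])


def _global_origin(geometry: ScanGeometry):
    """Volume origin on the global pixel grid (snapped to whole pixels)."""
    pitch = geometry.pitch_x_mm
    if abs(geometry.pitch_x_mm - geometry.pitch_y_mm) > 1e-9:
        raise ValidationError("phantom requires equal x/y pixel pitch")
    ox, oy = geometry.centre_offset_mm
    gx0 = int(round((ox - geometry.extent_x_mm / 2.0) / pitch))
    gy0 = int(round((oy - geometry.extent_y_mm / 2.0) / pitch))
    return gx0, gy0, pitch


def _capillary_pixels(truth, plexus, geometry):
    """All capillary pixels of one plexus inside the volume footprint."""
    gx0, gy0, pitch = _global_origin(geometry)
    nx, ny = geometry.n_ascans, geometry.n_bscans
    plexus_idx = PLEXUSES.index(plexus)
    cols = [[], [], [], []]
    for tj in range(math.floor(gy0 / TILE_PX), math.floor((gy0 + ny - 1) / TILE_PX) + 1):
        for ti in range(math.floor(gx0 / TILE_PX), math.floor((gx0 + nx - 1) / TILE_PX) + 1):
            gx, gy, jit, amp = _render_tile(truth, plexus, plexus_idx,
                                            ti, tj, pitch)
            keep = (gx >= gx0) & (gx < gx0 + nx) & (gy >= gy0) & (gy < gy0 + ny)
            cols[0].append(gx[keep] - gx0)
            cols[1].append(gy[keep] - gy0)
            cols[2].append(jit[keep])
            cols[3].append(amp[keep])
    ix, iy, jit, amp = (np.concatenate(c) if c else np.empty(0)
                        for c in cols)
    return ix.astype(np.int64), iy.astype(np.int64), jit, amp


def _vessel_footprint(truth, geometry):
    """2D mask of large-vessel pixels inside the volume footprint."""
    gx0, gy0, pitch = _global_origin(geometry)
    nx, ny = geometry.n_ascans, geometry.n_bscans
    mask = np.zeros((ny, nx), dtype=bool)
    for vessel in truth.large_vessel_centrelines:
        pts = vessel["points_mm"]
        r_px = 0.5 * vessel["calibre_um"] / (pitch * 1000.0)
        gpx = pts / pitch
        near = ((gpx[:, 0] > gx0 - r_px - 1) & (gpx[:, 0] < gx0 + nx + r_px + 1)
                & (gpx[:, 1] > gy0 - r_px - 1) & (gpx[:, 1] < gy0 + ny + r_px + 1))
        for px, py in gpx[near]:
            rr, cc = draw_disk((py - gy0, px - gx0), r_px + 0.5,
                               shape=(ny, nx))
            mask[rr, cc] = True
    return mask


def _structural_grid(surfaces: LayerSurfaces, geometry: ScanGeometry, rng):
    """Layer-reflectivity model: dim vitreous, mid-bright inner retina, dark
    outer nuclear layer, bright RPE band."""
    z = geometry.z_um()[:, np.newaxis, np.newaxis]
    s = surfaces
    grid = np.select(
        [z < s.ilm, z < s.ipl_two_thirds, z < s.inl_opl, z < s.opl_onl,
         z < s.rpe, z < s.rpe + 10.0],
        [0.04, 0.34, 0.27, 0.36, 0.13, 0.90],
        default=0.07,
    ).astype(np.float32)
    grid += rng.uniform(0.0, 0.05, size=grid.shape).astype(np.float32)
    np.clip(grid, 0.0, 1.0, out=grid)
    return grid


def synthesize_volume(truth: PhantomTruth, surfaces: LayerSurfaces,
                      geometry: ScanGeometry,
                      noise: NoiseConfig | None = None,
                      seed: int | None = None,
                      signal_strength: int = 10,
                      n_corrected_bscans: int = 0,
                      ) -> tuple[OctaVolume, PhantomAnnotations]:
    """Render one OCTA volume (flow + structural) with per-voxel truth labels.

    ``seed`` is mandatory: phantoms must be reproducible.  The same
    (truth, geometry) always yields the same vasculature; the noise fields
    are keyed on (seed, volume position) so a re-run is bit-identical.
    """
    if seed is None:
        raise ValidationError("synthesize_volume requires an explicit seed")
    if surfaces.shape != (geometry.n_bscans, geometry.n_ascans):
        raise ValidationError("surfaces do not match the scan geometry")
    noise = noise or NoiseConfig()

    nz, ny, nx = geometry.shape
    flow = np.zeros((nz, ny, nx), dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    x_mm, y_mm = geometry.x_mm(), geometry.y_mm()
    axial = geometry.axial_px_um

    cap_masks = {}
    for plexus in PLEXUSES:
        ix, iy, jit, amp = _capillary_pixels(truth, plexus, geometry)
        mask2d = np.zeros((ny, nx), dtype=bool)
        if ix.size:
            mask2d[iy, ix] = True
            ecc = np.hypot(x_mm[ix], y_mm[iy])
            depth_um = np.asarray(truth.depth_curves[plexus](ecc)) + jit
            z = np.round((surfaces.ilm[iy, ix] + depth_um) / axial).astype(np.int64)
            ok = (z >= 0) & (z < nz)
            zi, yi, xi, ai = z[ok], iy[ok], ix[ok], amp[ok]
            np.maximum.at(flow, (zi, yi, xi), ai.astype(np.float32))
            free = labels[zi, yi, xi] == LABEL_BG
            labels[zi[free], yi[free], xi[free]] = PLEXUS_LABELS[plexus]
        cap_masks[plexus] = mask2d

    # Large vessels: SVP slab only, amplitude 1.0.
    vmask = _vessel_footprint(truth, geometry)
    viy, vix = np.nonzero(vmask)
    if viy.size:
        ilm_v = surfaces.ilm[viy, vix]
        svp_outer = surfaces.ipl_two_thirds[viy, vix]
        centre = ilm_v + 0.5 * (svp_outer - ilm_v)
        half = 0.5 * truth.large_vessel_centrelines[0]["calibre_um"] \
            if truth.large_vessel_centrelines else 30.0
        lo = np.maximum(ilm_v + 2.0, centre - half)
        hi = np.minimum(svp_outer - 2.0, centre + half)
        zg = geometry.z_um()[:, np.newaxis]
        inside = (zg >= lo[np.newaxis, :]) & (zg < hi[np.newaxis, :])
        zi, ci = np.nonzero(inside)
        flow[zi, viy[ci], vix[ci]] = VESSEL_AMPLITUDE
        labels[zi, viy[ci], vix[ci]] = LABEL_VESSEL

    # Projection tails: every deeper voxel of an A-line receives an
    # attenuated copy (tail_coeff x the running maximum of shallower flow).
    running = np.maximum.accumulate(flow, axis=0)
    shallower_max = np.zeros_like(flow)
    shallower_max[1:] = running[:-1]
    tails = (truth.tail_coeff * shallower_max).astype(np.float32)
    tail_voxels = (flow == 0.0) & (tails > 0.0)
    np.maximum(flow, tails, out=flow)
    labels[tail_voxels] = LABEL_TAIL

    # Noise, keyed on (seed, volume position) for reproducibility.
    gx0, gy0, _ = _global_origin(geometry)
    rng = default_rng(SeedSequence((int(seed), 7777,
                                    gx0 + _TILE_IDX_OFFSET,
                                    gy0 + _TILE_IDX_OFFSET)))
    if noise.speckle_max > 0:
        flow += rng.uniform(0.0, noise.speckle_max,
                            size=flow.shape).astype(np.float32)
    if noise.salt_rate > 0:
        n_salt = rng.binomial(flow.size, noise.salt_rate)
        if n_salt:
            idx = rng.choice(flow.size, size=n_salt, replace=False)
            salt = rng.uniform(noise.salt_lo, noise.salt_hi,
                               size=n_salt).astype(np.float32)
            # impulses add on top of existing flow; they never erase it
            flow.flat[idx] = np.maximum(flow.flat[idx], salt)
    np.clip(flow, 0.0, 1.0, out=flow)

    structural = _structural_grid(surfaces, geometry, rng)
    volume = OctaVolume(flow=flow, structural=structural, geometry=geometry,
                        signal_strength=signal_strength,
                        n_corrected_bscans=n_corrected_bscans,
                        seed=int(seed), surfaces=surfaces)
    annotations = PhantomAnnotations(labels=labels, capillary_masks=cap_masks,
                                     vessel_mask=vmask, geometry=geometry,
                                     truth=truth)
    return volume, annotations
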