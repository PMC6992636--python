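"""B-scan (depth-resolved) capillary density, plexus peaks and IPDs.

The procedure: align A-lines so the RPE is a constant plane, remove
projection artifacts, mask large vessels directly on each B-scan (20 x
20-pixel Gaussian window, threshold 0.4), then count flow voxels per 6-µm
depth bin inside a 0.3 x 0.3-mm sample column centred at the requested
eccentricity.  Depth is measured from the local ILM (bin 0 = [0, 6) µm).

Plexus peaks are the local maxima of the depth profile kept under two
constraints: a minimal peak CD of 0.05% and a minimal separation of 9 µm
(two plexuses closer than that merge into a unique entity, the higher one —
ties to the shallower).  Peaks are labelled by depth order: three peaks are
SVP/ICP/DCP, two are SVP/DCP.  The interplexus distance (IPD) is the depth
difference between labelled peaks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.signal import find_peaks as _scipy_find_peaks

from .core import LayerSurfaces, OctaVolume, ScanGeometry
from .errors import ValidationError
from .params import AnalysisParams

__all__ = ["DepthProfile", "PlexusPeaks", "IpdRecord", "AlignedVolume",
           "vessel_mask_bscan", "vessel_mask_volume", "align_and_reference",
           "depth_profile", "find_plexus_peaks", "select_peaks",
           "interplexus_distances", "plexus_count_curve", "transitional_zone"]


def vessel_mask_bscan(bscan_flow: np.ndarray,
                      params: AnalysisParams | None = None) -> np.ndarray:
    """Large-vessel mask of one B-scan (depth x A-scan flow image)."""
    params = params or AnalysisParams()
    w = params.bscan_mask_window_px
    smoothed = gaussian_filter(np.asarray(bscan_flow, dtype=np.float32),
                               sigma=w / 6.0, radius=w // 2, mode="nearest")
    mask = smoothed > params.bscan_mask_threshold
    if params.bscan_mask_dilate_px:
        mask = binary_dilation(mask, iterations=params.bscan_mask_dilate_px)
    return mask


def vessel_mask_volume(flow: np.ndarray,
                       params: AnalysisParams | None = None) -> np.ndarray:
    """Per-B-scan vessel masks for a whole (z, y, x) volume."""
    params = params or AnalysisParams()
    w = params.bscan_mask_window_px
    smoothed = gaussian_filter(np.asarray(flow, dtype=np.float32),
                               sigma=(w / 6.0, 0.0, w / 6.0),
                               radius=(w // 2, 0, w // 2), mode="nearest")
    mask = smoothed > params.bscan_mask_threshold
    if params.bscan_mask_dilate_px:
        structure = np.zeros((3, 1, 3), dtype=bool)
        structure[:, 0, :] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
        mask = binary_dilation(mask, structure=structure,
                               iterations=params.bscan_mask_dilate_px)
    return mask


@dataclass
class AlignedVolume:
    """A volume with every A-line shifted so the RPE is a constant plane.

    Depths reported downstream are measured from ``ilm_um`` (the post-
    alignment ILM map), so the alignment itself does not change
    ILM-referenced depths — it makes depth bins comparable across the
    sample column.
    """

    flow: np.ndarray
    geometry: ScanGeometry
    ilm_um: np.ndarray
    rpe_um: np.ndarray
    shifts_px: np.ndarray = field(repr=False, default=None)

    def apply_to(self, grid: np.ndarray) -> np.ndarray:
        """Apply the same axial shifts to another (z, y, x) grid."""
        return _axial_shift(grid, self.shifts_px)


def _axial_shift(grid: np.ndarray, shifts_px: np.ndarray) -> np.ndarray:
    nz = grid.shape[0]
    z = np.arange(nz)[:, np.newaxis, np.newaxis]
    src = z - shifts_px[np.newaxis, :, :]
    ok = (src >= 0) & (src < nz)
    src = np.clip(src, 0, nz - 1)
    out = np.take_along_axis(grid, src, axis=0)
    out[~ok] = 0
    return out


def align_and_reference(volume: OctaVolume | np.ndarray,
                        surfaces: LayerSurfaces,
                        geometry: ScanGeometry | None = None) -> AlignedVolume:
    """Flatten the RPE to the median RPE depth by integer A-line shifts."""
    if isinstance(volume, OctaVolume):
        flow, geometry = volume.flow, volume.geometry
    else:
        flow = np.asarray(volume)
        if geometry is None:
            raise ValidationError("geometry required for plain-array input")
    if surfaces is None:
        raise ValidationError("layer surfaces are required for alignment")
    if surfaces.shape != flow.shape[1:]:
        raise ValidationError("surfaces do not match the volume")
    axial = geometry.axial_px_um
    ref = float(np.median(surfaces.rpe))
    shifts = np.round((ref - surfaces.rpe) / axial).astype(np.int64)
    return AlignedVolume(
        flow=_axial_shift(flow, shifts),
        geometry=geometry,
        ilm_um=surfaces.ilm + shifts * axial,
        rpe_um=surfaces.rpe + shifts * axial,
        shifts_px=shifts,
    )


@dataclass
class DepthProfile:
    """CD (%) per 6-µm depth bin below the ILM at one eccentricity."""

    eccentricity_mm: float
    bin_centres_um: np.ndarray
    cd_pct: np.ndarray
    subject: str | int = 0
    n_columns: int = 0

    def __post_init__(self):
        self.bin_centres_um = np.asarray(self.bin_centres_um, dtype=np.float64)
        self.cd_pct = np.asarray(self.cd_pct, dtype=np.float64)
        if self.bin_centres_um.shape != self.cd_pct.shape:
            raise ValidationError("bin/CD arrays must share a shape")
        if np.any((self.cd_pct < 0) | (self.cd_pct > 100)):
            raise ValidationError("CD must lie in [0, 100]")


def depth_profile(aligned: AlignedVolume, eccentricity_mm: float,
                  params: AnalysisParams | None = None,
                  mask: np.ndarray | None = None,
                  centre_mm: tuple[float, float] | None = None,
                  max_depth_um: float = 240.0,
                  subject: str | int = 0) -> DepthProfile:
    """Depth-binned CD in a 0.3 x 0.3-mm column at an eccentricity.

    ``aligned.flow`` should already be projection-removed; ``mask`` is the
    (z, y, x) large-vessel mask whose voxels are excluded from both counts.
    The sample is centred at ``(eccentricity_mm, 0)`` on the temporal axis
    unless ``centre_mm`` gives an explicit retinal (x, y).
    """
    params = params or AnalysisParams()
    geom = aligned.geometry
    cx, cy = centre_mm if centre_mm is not None else (eccentricity_mm, 0.0)
    wx, wy = params.bscan_sample_mm
    x, y = geom.x_mm(), geom.y_mm()
    ix = np.nonzero(np.abs(x - cx) <= wx / 2.0)[0]
    iy = np.nonzero(np.abs(y - cy) <= wy / 2.0)[0]
    tol = 1e-9
    if ix.size == 0 or iy.size == 0 \
            or cx - wx / 2 < x[0] - geom.pitch_x_mm / 2 - tol \
            or cx + wx / 2 > x[-1] + geom.pitch_x_mm / 2 + tol \
            or cy - wy / 2 < y[0] - geom.pitch_y_mm / 2 - tol \
            or cy + wy / 2 > y[-1] + geom.pitch_y_mm / 2 + tol:
        raise ValidationError(
            f"sample at ({cx:.2f}, {cy:.2f}) mm lies outside the volume")

    sub = aligned.flow[:, iy[:, None], ix[None, :]]        # (z, ny_s, nx_s)
    ilm = aligned.ilm_um[iy[:, None], ix[None, :]]         # (ny_s, nx_s)
    z_um = geom.z_um()[:, np.newaxis, np.newaxis]
    depth = z_um - ilm[np.newaxis, :, :]
    bin_w = params.depth_bin_um
    n_bins = int(np.floor(max_depth_um / bin_w))
    bins = np.floor(depth / bin_w).astype(np.int64)
    in_range = (bins >= 0) & (bins < n_bins)
    if mask is not None:
        sub_mask = mask[:, iy[:, None], ix[None, :]]
        in_range &= ~sub_mask
    flow_voxel = sub > params.flow_binarization_threshold

    total = np.bincount(bins[in_range], minlength=n_bins)
    flowing = np.bincount(bins[in_range & flow_voxel], minlength=n_bins)
    cd = np.divide(100.0 * flowing, total,
                   out=np.zeros(n_bins), where=total > 0)
    centres = (np.arange(n_bins) + 0.5) * bin_w
    return DepthProfile(eccentricity_mm=float(eccentricity_mm),
                        bin_centres_um=centres, cd_pct=cd, subject=subject,
                        n_columns=int(ix.size * iy.size))


# --------------------------------------------------------------------------
# Peak identification
# --------------------------------------------------------------------------

@dataclass
class PlexusPeaks:
    """Detected flow peaks, ordered inner to outer.

    ``labels`` parallel ``depths_um``: three peaks are labelled
    SVP/ICP/DCP, two SVP/DCP; other counts leave labels of None except that
    with more than three peaks the three highest are labelled in depth
    order.
    """

    depths_um: tuple
    heights_pct: tuple
    labels: tuple

    @property
    def n_peaks(self) -> int:
        return len(self.depths_um)

    def depth_of(self, label: str):
        for d, lab in zip(self.depths_um, self.labels):
            if lab == label:
                return d
        return None


def select_peaks(depths_um, heights, min_distance_um):
    """Greedy peak selection under a minimal-separation constraint.

    Candidates are taken highest first (ties to the shallower) and kept only
    if at least ``min_distance_um`` from every already-kept peak — the
    usual peak-finder semantics for merging near-coincident peaks.
    Returns indices into the input arrays, sorted by depth.
    """
    depths_um = np.asarray(depths_um, dtype=np.float64)
    heights = np.asarray(heights, dtype=np.float64)
    order = sorted(range(len(depths_um)),
                   key=lambda i: (-heights[i], depths_um[i]))
    kept = []
    for i in order:
        if all(abs(depths_um[i] - depths_um[j]) >= min_distance_um
               for j in kept):
            kept.append(i)
    return sorted(kept, key=lambda i: depths_um[i])


def _label_peaks(n, heights_sorted_by_depth):
    if n == 3:
        return ("SVP", "ICP", "DCP")
    if n == 2:
        return ("SVP", "DCP")
    if n > 3:
        # label the three highest, in depth order
        idx = np.argsort(heights_sorted_by_depth)[-3:]
        idx = sorted(idx)
        labels = [None] * n
        for lab, i in zip(("SVP", "ICP", "DCP"), idx):
            labels[i] = lab
        return tuple(labels)
    return (None,) * n


def find_plexus_peaks(profile: DepthProfile,
                      params: AnalysisParams | None = None) -> PlexusPeaks:
    """Identify plexus flow peaks in a depth profile.

    Local maxima of the binned CD curve (plateau-aware) are filtered by the
    minimal CD (0.05%) and then merged under the 9-µm minimal separation by
    :func:`select_peaks`.
    """
    params = params or AnalysisParams()
    cd = profile.cd_pct
    idx, _ = _scipy_find_peaks(np.concatenate([[-1.0], cd, [-1.0]]))
    idx = idx - 1
    keep = cd[idx] >= params.peak_min_cd_pct
    idx = idx[keep]
    depths = profile.bin_centres_um[idx]
    heights = cd[idx]
    sel = select_peaks(depths, heights, params.peak_min_distance_um)
    depths = tuple(float(depths[i]) for i in sel)
    heights = tuple(float(heights[i]) for i in sel)
    labels = _label_peaks(len(depths), heights)
    return PlexusPeaks(depths_um=depths, heights_pct=heights, labels=labels)


@dataclass
class IpdRecord:
    """Interplexus distances (µm) at one eccentricity.

    ``svp_dcp_um = svp_icp_um + icp_dcp_um`` whenever all three peaks exist.
    """

    eccentricity_mm: float
    svp_icp_um: float | None
    icp_dcp_um: float | None
    svp_dcp_um: float | None

    def __post_init__(self):
        if None not in (self.svp_icp_um, self.icp_dcp_um, self.svp_dcp_um):
            if abs(self.svp_dcp_um - (self.svp_icp_um + self.icp_dcp_um)) > 1e-9:
                raise ValidationError("IPD additivity violated")


def interplexus_distances(peaks: PlexusPeaks,
                          eccentricity_mm: float = float("nan"),
                          ) -> IpdRecord | None:
    """Pairwise depth differences between labelled peaks; None if fewer than
    two peaks were detected (flagged upstream)."""
    if peaks.n_peaks < 2:
        return None
    svp = peaks.depth_of("SVP")
    icp = peaks.depth_of("ICP")
    dcp = peaks.depth_of("DCP")
    return IpdRecord(
        eccentricity_mm=eccentricity_mm,
        svp_icp_um=(icp - svp) if (svp is not None and icp is not None) else None,
        icp_dcp_um=(dcp - icp) if (icp is not None and dcp is not None) else None,
        svp_dcp_um=(dcp - svp) if (svp is not None and dcp is not None) else None,
    )


def plexus_count_curve(peaks_table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of subjects with three distinguishable plexuses per
    eccentricity.

    ``peaks_table`` needs columns subject, eccentricity_mm, n_peaks.
    Returns eccentricity_mm, proportion_three_pct, n_subjects.
    """
    if peaks_table.empty:
        raise ValidationError("at least one subject required")
    rows = []
    for ecc, grp in peaks_table.groupby("eccentricity_mm"):
        prop = 100.0 * (grp["n_peaks"] == 3).mean()
        rows.append({"eccentricity_mm": float(ecc),
                     "proportion_three_pct": prop,
                     "n_subjects": int(grp["subject"].nunique())})
    return pd.DataFrame(rows).sort_values("eccentricity_mm").reset_index(drop=True)


def transitional_zone(curve: pd.DataFrame) -> tuple[float, float] | None:
    """[first eccentricity with <100% three-plexus proportion, first with
    <=10%]; None when the proportion never drops below 100%."""
    below_100 = curve[curve["proportion_three_pct"] < 100.0]
    if below_100.empty:
        return None
    start = float(below_100["eccentricity_mm"].iloc[0])
    below_10 = curve[curve["proportion_three_pct"] <= 10.0]
    end = float(below_10["eccentricity_mm"].iloc[0]) if not below_10.empty \
        else float(curve["eccentricity_mm"].iloc[-1])
    return (start, end)
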