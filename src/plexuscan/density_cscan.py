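"""C-scan capillary density: vessel masking, binarization, windowed CD.

The published C-scan procedure: large vessels are masked on the SVP en face
(15 x 15-pixel Gaussian smoothing, intensity threshold 0.4) and the same
mask is applied to the ICP and DCP images of the same field; flow pixels are
counted in 0.1 x 0.8-mm windows stepped every 0.1 mm along the band (long
side across the band); windows covered more than 40% by the vessel mask are
excluded.  CD is reported in percent.

By default masked large-vessel pixels are removed from both the numerator
and the denominator (the masked area is not capillary bed);
``AnalysisParams.cd_denominator = "total"`` restores a raw-total-pixel
denominator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .montage import Band
from .params import AnalysisParams
from .slabs import EnFaceImage

__all__ = ["AnalysisParams", "VesselMask", "EXCLUDED", "vessel_mask_cscan",
           "binarize_flow", "sample_cd", "band_profile", "assign_sectors",
           "table_summary", "percent_decrease", "TABLE_ECCENTRICITIES_MM"]

TABLE_ECCENTRICITIES_MM = (1.0, 2.0, 4.0, 8.0, 10.0)


class _Excluded:
    """Sentinel for a sample window excluded by the large-vessel mask."""

    def __repr__(self):
        return "EXCLUDED"


EXCLUDED = _Excluded()


@dataclass
class VesselMask:
    """Binary large-vessel mask aligned to an en face image."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self):
        return self.mask.shape


def _smooth(img: np.ndarray, window_px: int) -> np.ndarray:
    """Gaussian window of ``window_px`` pixels: sigma = window / 6,
    kernel truncated to the window size."""
    sigma = window_px / 6.0
    return gaussian_filter(np.asarray(img, dtype=np.float32), sigma=sigma,
                           radius=window_px // 2, mode="nearest")


def vessel_mask_cscan(svp_enface, params: AnalysisParams | None = None,
                      ) -> VesselMask:
    """Threshold the Gaussian-smoothed SVP en face to mask large vessels.

    The mask derived from the SVP is reused for the ICP and DCP images of
    the same field.  Ties at the threshold are not vessel (strict ``>``).
    """
    params = params or AnalysisParams()
    img = svp_enface.data if isinstance(svp_enface, EnFaceImage) else svp_enface
    smoothed = _smooth(img, params.mask_window_px)
    return VesselMask(smoothed > params.mask_threshold)


def binarize_flow(enface, params: AnalysisParams | None = None) -> np.ndarray:
    """Flow pixels: normalized intensity strictly above the binarization
    threshold (default 0.10)."""
    params = params or AnalysisParams()
    if isinstance(enface, EnFaceImage):
        return (enface.data > params.flow_binarization_threshold) & enface.valid
    return np.asarray(enface) > params.flow_binarization_threshold


def sample_cd(flow_binary: np.ndarray, mask: VesselMask | np.ndarray,
              centre_px: tuple[int, int], params: AnalysisParams,
              pitch_mm: float, valid: np.ndarray | None = None):
    """CD (%) of one 0.1 x 0.8-mm window, or :data:`EXCLUDED`.

    ``centre_px`` is (col, row); the short window side runs along columns
    (the band axis).  A window whose vessel-masked fraction exceeds 40% is
    excluded; a window extending off the band raises
    :class:`ValidationError`.
    """
    flow_binary = np.asarray(flow_binary, dtype=bool)
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    if m.shape != flow_binary.shape:
        raise ValidationError("mask and flow grids must share a shape")
    w_along = max(1, int(round(params.sample_window_mm[0] / pitch_mm)))
    w_across = max(1, int(round(params.sample_window_mm[1] / pitch_mm)))
    c, r = centre_px
    c0, r0 = c - w_along // 2, r - w_across // 2
    c1, r1 = c0 + w_along, r0 + w_across
    ny, nx = flow_binary.shape
    if c0 < 0 or r0 < 0 or c1 > nx or r1 > ny:
        raise ValidationError("sample window extends off the band")
    if valid is not None and not np.all(valid[r0:r1, c0:c1]):
        raise ValidationError("sample window covers off-band pixels")
    win_flow = flow_binary[r0:r1, c0:c1]
    win_mask = m[r0:r1, c0:c1]
    if win_mask.mean() > params.mask_exclusion_fraction:
        return EXCLUDED
    if params.cd_denominator == "unmasked":
        denom = int((~win_mask).sum())
        num = int((win_flow & ~win_mask).sum())
    else:
        denom = win_flow.size
        num = int((win_flow & ~win_mask).sum())
    if denom == 0:
        return EXCLUDED
    return 100.0 * num / denom


def band_profile(band: Band, params: AnalysisParams | None = None,
                 onh_mask: np.ndarray | None = None,
                 subject: str | int = 0) -> pd.DataFrame:
    """Windowed CD along a stitched band for each plexus.

    Windows are centred every ``profile_step_mm`` along the band axis with
    the 0.8-mm side across the band, on the foveal centreline.  The vessel
    mask is computed once from the band's SVP image and applied to every
    plexus.  Windows intersecting ``onh_mask`` are flagged excluded.

    Returns a tidy frame: subject, band, eccentricity_mm, plexus, cd_pct,
    excluded.
    """
    params = params or AnalysisParams()
    pitch = band.layout.pitch_mm
    vmask = vessel_mask_cscan(band.images["SVP"], params)
    flows = {p: binarize_flow(img, params) & band.valid
             for p, img in band.images.items()}

    w_along = max(1, int(round(params.sample_window_mm[0] / pitch)))
    w_across = max(1, int(round(params.sample_window_mm[1] / pitch)))
    step = max(1, int(round(params.profile_step_mm / pitch)))
    rows_n, cols_n = band.valid.shape
    fc, fr = band.layout.fovea_px
    r0 = fr - w_across // 2
    if r0 < 0 or r0 + w_across > rows_n:
        raise ValidationError("band narrower than the sample window")

    records = []
    k_min = -(fc // step)
    k_max = (cols_n - 1 - fc) // step
    for k in range(k_min, k_max + 1):
        c = fc + k * step
        c0 = c - w_along // 2
        if c0 < 0 or c0 + w_along > cols_n:
            continue
        sl = (slice(r0, r0 + w_across), slice(c0, c0 + w_along))
        if not band.valid[sl].all():
            continue
        ecc = (1.0 if not band.layout.flip_sign else -1.0) * (c - fc) * pitch
        onh_hit = bool(onh_mask is not None and onh_mask[sl].any())
        for plexus in band.images:
            cd = sample_cd(flows[plexus], vmask, (c, fr), params, pitch)
            excluded = onh_hit or cd is EXCLUDED
            records.append({
                "subject": subject,
                "band": band.layout.axis,
                "eccentricity_mm": round(ecc, 6),
                "plexus": plexus,
                "cd_pct": (np.nan if excluded else cd),
                "excluded": excluded,
            })
    df = pd.DataFrame.from_records(records)
    return df.sort_values(["plexus", "eccentricity_mm"]).reset_index(drop=True)


_SECTOR_OF = {("horizontal", 1): "temporal", ("horizontal", -1): "nasal",
              ("vertical", 1): "superior", ("vertical", -1): "inferior"}


def assign_sectors(profile: pd.DataFrame) -> pd.DataFrame:
    """Add a ``sector`` column from the band axis and eccentricity sign.

    Zero eccentricity is assigned to the positive sector (temporal/superior).
    """
    out = profile.copy()
    sign = np.where(out["eccentricity_mm"] < 0, -1, 1)
    out["sector"] = [_SECTOR_OF[(b, s)] for b, s in zip(out["band"], sign)]
    return out


def table_summary(profiles: pd.DataFrame,
                  eccentricities_mm=TABLE_ECCENTRICITIES_MM,
                  sectors=("temporal", "nasal", "superior", "inferior"),
                  ) -> pd.DataFrame:
    """Cohort CD table: mean ± SD per (sector, plexus, eccentricity).

    For each subject the window nearest the requested |eccentricity| in the
    matching sector is used; excluded windows contribute nothing, and a cell
    with no contributing subject is NA (the nasal 4-mm cell is NA under the
    default optic-nerve-head exclusion).
    """
    df = profiles if "sector" in profiles.columns else assign_sectors(profiles)
    records = []
    for sector in sectors:
        sec = df[df["sector"] == sector]
        for plexus in sorted(df["plexus"].unique()):
            sp = sec[sec["plexus"] == plexus]
            for ecc in eccentricities_mm:
                values = []
                for _, sub in sp.groupby("subject"):
                    cand = sub.iloc[
                        (sub["eccentricity_mm"].abs() - ecc).abs().argsort()]
                    if cand.empty:
                        continue
                    nearest = cand.iloc[0]
                    # a subject's nearest window must actually be near the
                    # requested eccentricity and not excluded
                    if abs(abs(nearest["eccentricity_mm"]) - ecc) > 0.5 \
                            or nearest["excluded"]:
                        continue
                    values.append(float(nearest["cd_pct"]))
                if values:
                    arr = np.asarray(values)
                    mean = float(arr.mean())
                    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                    n = len(arr)
                else:
                    mean, sd, n = np.nan, np.nan, 0
                records.append({"sector": sector, "plexus": plexus,
                                "eccentricity_mm": ecc, "mean_cd_pct": mean,
                                "sd_cd_pct": sd, "n_subjects": n})
    return pd.DataFrame.from_records(records)


def percent_decrease(value_at_e1: float, value_at_e2: float) -> int:
    """Percent loss from the inner to the outer eccentricity, to the nearest
    integer: ``100 x (v1 - v2) / v1``.

    Undefined (raises) when the inner value is not positive.
    """
    v1, v2 = float(value_at_e1), float(value_at_e2)
    if not v1 > 0:
        raise ValidationError("percent decrease undefined for v(e1) <= 0")
    return int(round(100.0 * (v1 - v2) / v1))
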