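"""Stitch per-position volumes into fovea-centred bands.

Bands are stored with the band axis along image *columns*: a horizontal band
runs nasal (left) to temporal (right), a vertical band is rotated so that
superior-inferior also runs along columns.  The eccentricity of a band pixel
is signed: temporal/superior positive, nasal/inferior negative.

Registration is translation-only normalized cross-correlation seeded by the
nominal acquisition offsets (the protocol overlaps neighbouring cubes by
about 40%), with the search restricted to +-0.5 mm around the nominal
offset.

Polyak's anatomical zones partition eccentricity into foveola (0-350 µm),
foveal floor (350-400), parafovea (400-1250), perifovea (1250-2750), near
periphery (2750-4250), mid periphery (4250-7250) and far periphery (beyond
7250); intervals are half-open, boundaries belong to the outer zone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import CoverageError, RegistrationError, ValidationError
from .slabs import EnFaceImage

__all__ = ["MontageLayout", "Band", "PolyakZone", "POLYAK_ZONES",
           "register_pair", "build_band", "eccentricity_of", "polyak_zone",
           "onh_exclusion"]

# (label, inner bound µm, outer bound µm); half-open [lo, hi)
POLYAK_ZONES = (
    ("foveola", 0.0, 350.0),
    ("foveal_floor", 350.0, 400.0),
    ("parafovea", 400.0, 1250.0),
    ("perifovea", 1250.0, 2750.0),
    ("near_periphery", 2750.0, 4250.0),
    ("mid_periphery", 4250.0, 7250.0),
    ("far_periphery", 7250.0, float("inf")),
)


@dataclass(frozen=True)
class PolyakZone:
    label: str
    lo_um: float
    hi_um: float


def polyak_zone(eccentricity_um) -> str:
    """Polyak zone label for a (non-negative) radial eccentricity in µm."""
    e = float(eccentricity_um)
    if e < 0:
        raise ValidationError("eccentricity must be >= 0")
    for label, lo, hi in POLYAK_ZONES:
        if lo <= e < hi:
            return label
    raise AssertionError("unreachable: zones partition [0, inf)")


def polyak_zone_bounds(label: str) -> PolyakZone:
    for name, lo, hi in POLYAK_ZONES:
        if name == label:
            return PolyakZone(name, lo, hi)
    raise KeyError(label)


# --------------------------------------------------------------------------
# Registration
# --------------------------------------------------------------------------

def _standardize(img):
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _ncc_at(ref, mov, dx, dy):
    """Exact Pearson correlation of the overlap at integer offset (dx, dy)."""
    ny_r, nx_r = ref.shape
    ny_m, nx_m = mov.shape
    r0, r1 = max(0, dy), min(ny_r, ny_m + dy)
    c0, c1 = max(0, dx), min(nx_r, nx_m + dx)
    if r1 - r0 < 8 or c1 - c0 < 8:
        return 0.0
    a = ref[r0:r1, c0:c1].ravel()
    b = mov[r0 - dy:r1 - dy, c0 - dx:c1 - dx].ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def register_pair(ref_enface, moving_enface, expected_offset_mm,
                  pitch_mm: float | None = None, search_mm: float = 0.5,
                  min_score: float = 0.2) -> tuple[tuple[int, int], float]:
    """Find the integer-pixel translation aligning ``moving`` onto ``ref``.

    The returned offset ``(dx, dy)`` places the moving image's origin at
    ``(dx, dy)`` in the reference frame (``ref[y, x] ~ mov[y - dy, x - dx]``).
    The cross-correlation peak is searched within ``+-search_mm`` of the
    nominal offset; a peak with normalized correlation below ``min_score``
    raises :class:`RegistrationError`.
    """
    if isinstance(ref_enface, EnFaceImage):
        if pitch_mm is None:
            pitch_mm = ref_enface.pitch_x_um / 1000.0
        ref_img = ref_enface.data
    else:
        ref_img = np.asarray(ref_enface)
    mov_img = (moving_enface.data if isinstance(moving_enface, EnFaceImage)
               else np.asarray(moving_enface))
    if pitch_mm is None:
        raise ValidationError("pitch_mm required for plain-array inputs")

    ref = _standardize(ref_img)
    mov = _standardize(mov_img)
    ny_m, nx_m = mov.shape
    # corr[dy + ny_m - 1, dx + nx_m - 1] = sum_p ref(p) * mov(p - (dx, dy))
    corr = fftconvolve(ref, mov[::-1, ::-1], mode="full")

    ex = int(round(expected_offset_mm[0] / pitch_mm))
    ey = int(round(expected_offset_mm[1] / pitch_mm))
    s = max(1, int(round(search_mm / pitch_mm)))
    dys = np.arange(corr.shape[0]) - (ny_m - 1)
    dxs = np.arange(corr.shape[1]) - (nx_m - 1)
    window = ((np.abs(dys - ey) <= s)[:, None]
              & (np.abs(dxs - ex) <= s)[None, :])
    if not window.any():
        raise RegistrationError("search window outside correlation support")
    masked = np.where(window, corr, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(masked)), masked.shape)
    dx, dy = int(dxs[ix]), int(dys[iy])
    score = _ncc_at(ref_img.astype(np.float64), mov_img.astype(np.float64),
                    dx, dy)
    if score < min_score:
        raise RegistrationError(
            f"correlation peak {score:.3f} below {min_score} at offset "
            f"({dx}, {dy})")
    return (dx, dy), score


# --------------------------------------------------------------------------
# Band assembly
# --------------------------------------------------------------------------

@dataclass
class MontageLayout:
    """Placement of each volume in the band pixel frame.

    ``offsets_px`` are (col, row) origins per volume; columns run along the
    band axis (temporal or superior towards +cols).  ``fovea_px`` is the
    (col, row) of the foveal centre.
    """

    offsets_px: list
    axis: str                      # "horizontal" | "vertical"
    fovea_px: tuple[int, int]
    volume_shape: tuple[int, int]  # (rows, cols) of each en face
    pitch_mm: float
    onh_region: tuple | None = None    # (c0, c1, r0, r1) band-frame rectangle
    flip_sign: bool = False

    def __post_init__(self):
        if self.axis not in ("horizontal", "vertical"):
            raise ValidationError("axis must be 'horizontal' or 'vertical'")
        if self.pitch_mm <= 0:
            raise ValidationError("pitch must be positive")
        self.offsets_px = [(int(c), int(r)) for c, r in self.offsets_px]
        cols = [c for c, _ in self.offsets_px]
        if any(b < a for a, b in zip(cols, cols[1:])):
            raise ValidationError("volume offsets must be monotone along the band")
        n_cols = self.volume_shape[1]
        for a, b in zip(cols, cols[1:]):
            if b - a > int(0.8 * n_cols):
                raise ValidationError(
                    "consecutive volumes must overlap by >= 20% of extent")

    @property
    def band_shape(self) -> tuple[int, int]:
        rows = max(r for _, r in self.offsets_px) + self.volume_shape[0]
        cols = max(c for c, _ in self.offsets_px) + self.volume_shape[1]
        return (rows, cols)


@dataclass
class Band:
    """Stitched en face images per plexus, plus the layout that built them."""

    images: dict                    # plexus -> float32 (rows, cols)
    valid: np.ndarray               # bool (rows, cols)
    layout: MontageLayout
    pixel_counts: np.ndarray = field(repr=False, default=None)

    def eccentricity_mm(self) -> np.ndarray:
        """Signed eccentricity of every band column (mm)."""
        cols = np.arange(self.valid.shape[1])
        return eccentricity_of(cols, self.layout)


def build_band(enface_sets, layout: MontageLayout) -> Band:
    """Average overlapping volumes into one band per plexus.

    ``enface_sets`` is one ``{plexus: EnFaceImage | array}`` mapping per
    volume, in layout order.  Overlaps are blended by per-pixel mean; a gap
    between consecutive volumes raises :class:`CoverageError` with the gap
    interval (in band mm).
    """
    if len(enface_sets) != len(layout.offsets_px):
        raise ValidationError("one en face set per layout offset required")
    cols = [c for c, _ in layout.offsets_px]
    n_cols = layout.volume_shape[1]
    for i, (a, b) in enumerate(zip(cols, cols[1:])):
        if b > a + n_cols:
            lo = (a + n_cols) * layout.pitch_mm
            hi = b * layout.pitch_mm
            raise CoverageError((lo, hi),
                                f"gap between volumes {i} and {i + 1}: "
                                f"{lo:.2f}-{hi:.2f} mm")

    rows, cols_total = layout.band_shape
    plexuses = list(enface_sets[0].keys())
    acc = {p: np.zeros((rows, cols_total), dtype=np.float64) for p in plexuses}
    cnt = np.zeros((rows, cols_total), dtype=np.int32)
    for (c0, r0), faces in zip(layout.offsets_px, enface_sets):
        added = None
        for p in plexuses:
            img = faces[p]
            if isinstance(img, EnFaceImage):
                data, valid = img.data, img.valid
            else:
                data = np.asarray(img, dtype=np.float64)
                valid = np.ones(data.shape, dtype=bool)
            if data.shape != layout.volume_shape:
                raise ValidationError("en face shape differs from layout")
            sl = (slice(r0, r0 + data.shape[0]), slice(c0, c0 + data.shape[1]))
            acc[p][sl] += np.where(valid, data, 0.0)
            if added is None:
                cnt[sl] += valid.astype(np.int32)
                added = True
    valid = cnt > 0
    images = {}
    for p in plexuses:
        img = np.divide(acc[p], cnt, out=np.zeros_like(acc[p]), where=valid)
        images[p] = img.astype(np.float32)
    return Band(images=images, valid=valid, layout=layout, pixel_counts=cnt)


def eccentricity_of(band_col, layout: MontageLayout):
    """Signed eccentricity (mm) of a band column index.

    Positive towards temporal (horizontal band) or superior (vertical band);
    ``layout.flip_sign`` inverts the convention.
    """
    sign = -1.0 if layout.flip_sign else 1.0
    out = sign * (np.asarray(band_col) - layout.fovea_px[0]) * layout.pitch_mm
    return out if out.ndim else float(out)


def onh_exclusion(layout: MontageLayout, onh_centre_mm: float = -4.0,
                  radius_mm: float = 1.0) -> np.ndarray:
    """Mask of band pixels inside the optic-nerve-head exclusion disc.

    The ONH sits nasally (negative eccentricity) on the horizontal band; on
    a vertical band the mask is empty.  Windows that intersect the mask are
    excluded from density profiles.
    """
    rows, cols = layout.band_shape
    mask = np.zeros((rows, cols), dtype=bool)
    if layout.axis != "horizontal" or radius_mm <= 0:
        return mask
    sign = -1.0 if layout.flip_sign else 1.0
    cc = layout.fovea_px[0] + sign * onh_centre_mm / layout.pitch_mm
    rc = layout.fovea_px[1]
    r_px = radius_mm / layout.pitch_mm
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask[(xx - cc) ** 2 + (yy - rc) ** 2 <= r_px ** 2] = True
    return mask
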