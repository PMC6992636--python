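"""Analysis parameters for the C-scan and B-scan density procedures.

The defaults are the published protocol: a 15 x 15-pixel Gaussian window at
threshold 0.4 for the large-vessel mask on C-scans (20 x 20 on B-scans),
0.1 x 0.8-mm capillary-density sample windows stepped every 0.1 mm, window
exclusion when the vessel mask covers more than 40% of it, 6-µm depth bins
over 0.3 x 0.3-mm samples for the depth profiles, and plexus-peak detection
with a 9-µm minimum separation and a 0.05% minimum capillary density.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ValidationError


@dataclass(frozen=True)
class AnalysisParams:
    mask_window_px: int = 15
    mask_threshold: float = 0.4
    sample_window_mm: tuple[float, float] = (0.1, 0.8)  # (x, y) = (along, across)
    mask_exclusion_fraction: float = 0.40
    flow_binarization_threshold: float = 0.10
    profile_step_mm: float = 0.1
    bscan_mask_window_px: int = 20
    # The B-scan masking threshold is not pinned by the published protocol
    # (only the C-scan's 0.4 is); 0.3 keeps the whole vessel cross-section
    # inside the mask, including the top edge that survives projection
    # removal.
    bscan_mask_threshold: float = 0.3
    # guard margin (px) dilated around the B-scan mask: the smoothed mask's
    # threshold contour sits inside the vessel near its corners, and those
    # top-corner voxels survive projection removal
    bscan_mask_dilate_px: int = 3
    depth_bin_um: float = 6.0
    bscan_sample_mm: tuple[float, float] = (0.3, 0.3)
    peak_min_distance_um: float = 9.0
    peak_min_cd_pct: float = 0.05
    # Denominator convention for CD: masked large-vessel pixels are excluded
    # from both numerator and denominator by default; "total" restores the
    # raw-total-pixel denominator.
    cd_denominator: str = "unmasked"

    def __post_init__(self):
        positives = {
            "mask_window_px": self.mask_window_px,
            "mask_threshold": self.mask_threshold,
            "flow_binarization_threshold": self.flow_binarization_threshold,
            "profile_step_mm": self.profile_step_mm,
            "bscan_mask_window_px": self.bscan_mask_window_px,
            "bscan_mask_threshold": self.bscan_mask_threshold,
            "depth_bin_um": self.depth_bin_um,
            "peak_min_distance_um": self.peak_min_distance_um,
            "peak_min_cd_pct": self.peak_min_cd_pct,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("sample_window_mm", "bscan_sample_mm"):
            w = getattr(self, name)
            if len(w) != 2 or w[0] <= 0 or w[1] <= 0:
                raise ValidationError(f"{name} must be two positive lengths")
        if self.bscan_mask_dilate_px < 0:
            raise ValidationError("bscan_mask_dilate_px must be >= 0")
        if not (0.0 < self.mask_exclusion_fraction < 1.0):
            raise ValidationError("mask_exclusion_fraction must be in (0, 1)")
        if self.cd_denominator not in ("unmasked", "total"):
            raise ValidationError("cd_denominator must be 'unmasked' or 'total'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("sample_window_mm", "bscan_sample_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
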