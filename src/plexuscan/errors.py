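"""Exception hierarchy.

All package errors derive from :class:`PlexuscanError` so callers can catch
one base class; validation failures additionally derive from ``ValueError``.
"""


class PlexuscanError(Exception):
    """Base class for all plexuscan errors."""


class ValidationError(PlexuscanError, ValueError):
    """A domain invariant was violated (bad geometry, crossing surfaces...)."""


class FormatError(PlexuscanError):
    """On-disk volume does not match its sidecar metadata or value ranges."""


class RegistrationError(PlexuscanError):
    """Pairwise registration failed (no correlation peak above threshold)."""


class CoverageError(PlexuscanError):
    """Montage layout leaves a gap between consecutive volumes."""

    def __init__(self, gap_interval_mm, msg=None):
        self.gap_interval_mm = tuple(gap_interval_mm)
        super().__init__(msg or f"coverage gap at {self.gap_interval_mm} mm")


class SegmentationError(PlexuscanError):
    """Layer-surface segmentation failed (e.g. missing RPE signal)."""


class StageError(PlexuscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
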