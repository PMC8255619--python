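"""Exception hierarchy for the PERSI quantification pipeline.

Every failure mode that a caller may reasonably want to catch separately
gets its own class; all inherit from :class:`PersiError` so pipeline code
can distinguish "this subject failed" from programming errors.
"""


class PersiError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PersiError):
    """Input data violates a contract (NaNs, bad dimensionality, bad probabilities)."""


class DegenerateMaskError(PersiError):
    """A binarized segmentation contains no voxels."""


class AtlasError(PersiError):
    """Atlas construction or lookup failed (empty or missing regions)."""


class RegionLookupError(AtlasError, KeyError):
    """Requested region name is not defined in the atlas."""


class DegenerateHistogramError(PersiError):
    """Masked intensities have zero range; no histogram can be built."""


class FitFailureError(PersiError):
    """Bimodal fit did not converge after all restarts.

    Carries the optimizer diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SparseReferenceError(PersiError):
    """Too few voxels survive the reference-selection window."""


class NormalizationError(PersiError):
    """Reference mean is non-positive; SUVR undefined."""


class CohortError(PersiError):
    """Cohort-level failure (missing group, excessive subject failures)."""
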