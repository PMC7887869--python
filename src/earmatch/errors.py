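"""Exception hierarchy for the ear-identification pipeline."""


class EarMatchError(Exception):
    """Base class for all pipeline errors."""


class InvalidImageError(EarMatchError, ValueError):
    """Raised for empty images or unsupported channel layouts."""


class InvalidROIError(EarMatchError, ValueError):
    """Raised when a crop rectangle violates its bounds invariants."""


class ConfigError(EarMatchError, ValueError):
    """Raised for inconsistent pipeline configuration (e.g. crop without ROI)."""


class UnmatchableError(EarMatchError):
    """Raised when a descriptor set required for matching is empty."""


class InvalidCompositeError(EarMatchError, ValueError):
    """Raised when descriptor sets from different subjects are concatenated."""


class EnrollmentError(EarMatchError):
    """Raised when a subject cannot be enrolled (duplicate ID, no descriptors)."""


class GalleryStoreError(EarMatchError):
    """Raised for corrupt gallery stores or preprocessing-regime mismatches."""
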