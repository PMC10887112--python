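"""Exception types shared across the pipeline stages."""


class SpheroxiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpheroxiError):
    """Invalid scene, acquisition, or run configuration."""


class CalibrationError(SpheroxiError):
    """Stern-Volmer calibration cannot be established from the given lifetimes."""


class DetectionError(SpheroxiError):
    """Chamber detection failed (e.g. no template response above threshold)."""


class PlacementError(SpheroxiError):
    """Synthetic cell spots could not be placed disjointly."""


class StackFormatError(SpheroxiError):
    """A phase-stack file or sidecar violates the expected layout."""
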