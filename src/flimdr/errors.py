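"""Exception hierarchy for the FLIM drug-response pipeline."""


class FlimdrError(Exception):
    """Base class for all package errors."""


class ConfigError(FlimdrError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DomainError(FlimdrError, ValueError):
    """A physical quantity is outside its valid domain (e.g. fraction not in [0, 1])."""


class CalibrationError(FlimdrError, ValueError):
    """The calibration reference is unusable (e.g. zero-magnitude phasor)."""


class EmptyImageError(FlimdrError, ValueError):
    """No valid pixels survive intensity thresholding."""


class InsufficientReplicatesError(FlimdrError, ValueError):
    """Fewer replicate images than the statistics require (minimum 2 per arm)."""


class FormatError(FlimdrError, ValueError):
    """An on-disk container does not match the expected layout or metadata."""


class ManifestError(FlimdrError, ValueError):
    """A case manifest is malformed or references missing files."""
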