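"""Exception hierarchy for the mplung pipeline.

Every stage raises a subclass of :class:`MplungError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class MplungError(Exception):
    """Base class for all mplung errors."""


class ConfigurationError(MplungError, ValueError):
    """An invalid configuration value; the message names the field."""


class RegistrationError(MplungError):
    """Motion compensation failed (implausible shift estimate)."""


class SegmentationError(MplungError):
    """Fallback lung segmentation could not find two lungs."""


class BandEstimationError(MplungError):
    """No credible spectral peak inside a frequency band; names the band."""


class SchemaError(MplungError, ValueError):
    """A cohort table is missing required columns or has invalid values."""
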