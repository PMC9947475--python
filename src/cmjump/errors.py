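"""Exception hierarchy.

Every error raised by the package derives from :class:`CmjError` so callers
(and the CLI) can map failure categories to exit codes.
"""


class CmjError(Exception):
    """Base class for all package errors."""


class FormatError(CmjError):
    """A file does not match the declared dialect (e.g. missing column)."""


class DataError(CmjError):
    """The data content is invalid (non-monotone time, gaps, NaNs)."""


class CalibrationError(CmjError):
    """A calibration precondition failed (wrong orientation, norm far from g)."""


class QualityError(CmjError):
    """A signal-quality precondition failed (unstable static window)."""


class NoJumpError(CmjError):
    """No movement onset could be detected."""


class NoFlightError(CmjError):
    """No sample with a <= -g was found: the trace contains no flight phase."""


class MalformedJumpError(CmjError):
    """Detected events violate the countermovement-jump phase structure."""


class FeatureUndefinedError(CmjError):
    """A feature's defining window is empty; carries the feature name."""

    def __init__(self, feature: str, msg: str = ""):
        self.feature = feature
        super().__init__(f"feature {feature!r} undefined{': ' + msg if msg else ''}")


class DegenerateFeatureError(CmjError):
    """A feature column is constant and cannot be z-scored."""


class EmptySelectionError(CmjError):
    """Lasso shrank every coefficient to zero (alpha too large for the data)."""


class SchemaError(CmjError):
    """A required feature/column is missing from an input table."""


class ConstraintError(CmjError):
    """A synthetic jump specification is infeasible."""


class ConfigError(CmjError):
    """A run configuration failed validation."""
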