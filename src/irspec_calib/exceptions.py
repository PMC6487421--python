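"""Exception hierarchy for irspec_calib.

All library errors derive from :class:`IrspecError` so callers can catch one
base class at the CLI boundary.
"""


class IrspecError(Exception):
    """Base class for all irspec_calib errors."""


class FormatError(IrspecError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A cell or token could not be parsed as a number."""


class ConfigError(IrspecError):
    """Invalid configuration or parameter value."""


class ShapeError(IrspecError):
    """Array dimensions are inconsistent."""


class IntegrityError(IrspecError):
    """Cross-object consistency violated (ids, indices, pairing)."""


class DegenerateDataError(IrspecError):
    """Data degenerate for the requested operation (constant rows, etc.)."""


class RankError(IrspecError):
    """No covariance left to extract another latent variable."""

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable


class IllConditionedError(IrspecError):
    """A linear system is numerically singular."""


class TuningError(IrspecError):
    """Hyperparameter search failed on every grid point."""
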