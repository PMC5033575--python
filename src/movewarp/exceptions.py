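"""Exception hierarchy.

All errors raised by movewarp derive from :class:`MovewarpError` so callers
can catch the package's failures with a single ``except`` clause while still
distinguishing data-format problems from numerical ones.
"""


class MovewarpError(Exception):
    """Base class for all movewarp errors."""


class FormatError(MovewarpError, ValueError):
    """A file or table does not have the expected layout (e.g. missing column)."""


class ValidationError(MovewarpError, ValueError):
    """Input data violates a structural invariant (non-monotone times, duplicates)."""


class DomainError(MovewarpError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class LengthError(MovewarpError, ValueError):
    """A sequence is too short for the requested operation."""


class OnsetDetectionError(MovewarpError, RuntimeError):
    """No movement onset/offset could be detected under the given rule."""


class DegenerateDataError(MovewarpError, ValueError):
    """Data carry no usable variation (e.g. zero value span)."""


class RankError(MovewarpError, ValueError):
    """A design or normal-equation matrix is rank deficient."""


class NumericError(MovewarpError, RuntimeError):
    """A numerical operation failed (non-finite objective, indefinite matrix)."""


class FitError(MovewarpError, RuntimeError):
    """Model fitting failed; the message carries iteration context."""


class StateError(MovewarpError, RuntimeError):
    """An object is not in a state that allows the requested operation."""


class ConvergenceError(MovewarpError, RuntimeError):
    """Two fits that should be nested/ordered are inconsistent beyond tolerance."""


class ConfigError(MovewarpError, ValueError):
    """A configuration object is inconsistent."""
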