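"""Exception hierarchy used across the package.

Every user-facing failure maps to one of these classes so the command-line
layer can translate them into stable exit codes (usage=2, validation=3,
numeric=4).
"""


class ScfuseError(Exception):
    """Base class for all package errors."""


class FormatError(ScfuseError):
    """An on-disk file is internally inconsistent (e.g. matrix/name length mismatch)."""


class ValidationError(ScfuseError):
    """Input data violates a container invariant (negative counts, duplicate names...)."""


class ParameterError(ScfuseError):
    """A caller-supplied parameter is out of its admissible range."""


class EmptyResultError(ScfuseError):
    """A filtering step removed everything; carries the offending threshold in its message."""


class PairingError(ScfuseError):
    """Two views that must share cells disagree on cell identity or order."""


class DivergenceError(ScfuseError):
    """Optimization produced a non-finite loss; message names the epoch and learning rate."""


class ConditioningError(ScfuseError):
    """A covariance matrix stayed non-positive-definite after jitter escalation."""
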