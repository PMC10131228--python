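"""Exception hierarchy.

Validation problems (bad user input, malformed files, inconsistent model
definitions) raise :class:`ValidationError`; numerical problems discovered
while estimating (singular systems, disconnected statistics) raise
:class:`NumericalError`.  The CLI maps these to exit codes 2 and 3.
"""


class MilekinError(Exception):
    """Base class for all package errors."""


class ValidationError(MilekinError, ValueError):
    """Invalid input: model definition, trace, configuration, arguments."""


class ModelDefinitionError(ValidationError):
    """Milestone layout is ill-formed (non-monotone, non-positive, ...)."""


class OutOfDomainError(ValidationError):
    """A CV value falls outside the tessellated range."""


class TraceError(ValidationError):
    """An event trace is internally inconsistent or corrupt."""


class NumericalError(MilekinError, RuntimeError):
    """Estimation failed: disconnected statistics, singular matrices, ..."""


class DisconnectedError(NumericalError):
    """The sampled cell/milestone graph is not connected."""
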