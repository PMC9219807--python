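"""Exception hierarchy shared across the package.

Every error raised by allopred derives from :class:`AllopredError` so the
CLI can map any of them to a one-line diagnostic and a nonzero exit code.
"""


class AllopredError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AllopredError):
    """Missing or malformed metadata / configuration."""


class ValidationError(AllopredError):
    """Input data violates an invariant (ordering, positivity, arity)."""


class DomainError(AllopredError):
    """Numeric argument outside the mathematical domain of an operation."""


class EstimationError(AllopredError):
    """A fit could not be performed (e.g. no terminal decline)."""


class EvaluationError(AllopredError):
    """Predicted/observed comparison could not be carried out."""


class SimulationError(AllopredError):
    """Synthetic data generation failed (e.g. full LLOQ censoring)."""
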