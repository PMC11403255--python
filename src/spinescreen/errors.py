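"""Exception hierarchy shared across the package."""


class SpineScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(SpineScreenError, ValueError):
    """An input value violates a documented invariant."""


class NoSpinesError(ValidationError):
    """A per-neuron summary was requested for a neuron with no spines."""


class DamagedNeuronError(ValidationError):
    """A damaged neuron was passed to an operation that must exclude it."""


class InvalidWellError(SpineScreenError):
    """A well has too few evaluable neurons to yield a stable percentage."""


class ConfigurationError(SpineScreenError):
    """The dataset or run configuration is structurally wrong (e.g. a plate
    without exactly two vehicle wells)."""
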