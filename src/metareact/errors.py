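"""Exception hierarchy for model construction, unit checking, compilation and IO."""


class MetareactError(Exception):
    """Base class for all errors raised by this package."""


class ModelError(MetareactError):
    """Invalid meta-species / meta-reaction construction."""


class UnitError(MetareactError):
    """Dimensional inconsistency in a quantity, rate, or expression."""


class CompileError(MetareactError):
    """Failure while expanding meta-reactions into a concrete network."""


class SimulationError(MetareactError):
    """Failure while running a compiled model."""


class SchemaError(MetareactError):
    """Invalid declarative model file."""
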