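"""Exception hierarchy for myosyn."""


class MyosynError(Exception):
    """Base class for all myosyn errors."""


class RangeError(MyosynError, ValueError):
    """An angle lies outside the configured joint range."""


class DomainError(MyosynError, ValueError):
    """A quantity lies outside the mathematical domain of an operation."""


class ContractError(MyosynError, ValueError):
    """A caller violated an input contract (e.g. negative activation)."""


class NumericError(MyosynError, ArithmeticError):
    """Non-finite state encountered during integration."""


class InfeasibleTorqueError(MyosynError, ValueError):
    """No muscle can act in the direction of the demanded torque."""


class OracleError(MyosynError, RuntimeError):
    """The numerical reference solver failed to converge."""


class GenerationError(MyosynError, RuntimeError):
    """Random model generation failed to satisfy its constraints."""


class InvalidRepresentativeError(MyosynError, ValueError):
    """A candidate representative muscle changes torque direction in range."""


class DegenerateRepresentativeError(MyosynError, ValueError):
    """A representative's torque transform vanishes somewhere on the grid."""


class DegenerateInputError(MyosynError, ValueError):
    """An input matrix is unusable (e.g. all zeros) for factorization."""


class ScalingError(MyosynError, ValueError):
    """A synergy column cannot be scaled to its representative muscle."""


class ControllerError(MyosynError, RuntimeError):
    """The inner solver of a feedback controller failed."""
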