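"""Exception hierarchy shared across the package."""


class PorcycleError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PorcycleError, ValueError):
    """A model or operation parameter violates its contract."""


class FormatError(PorcycleError, ValueError):
    """A delimited input file could not be parsed into a valid dataset."""


class PreconditionError(PorcycleError, ValueError):
    """Input data do not satisfy an operation's precondition."""


class DegenerateModelError(PorcycleError, RuntimeError):
    """The kinetic model is not identifiable on the given data
    (e.g. two lifetimes collapsed onto each other)."""


class PhaseSeparationError(PorcycleError, RuntimeError):
    """Formation and decay phases of a transient cannot be separated
    by windowed single-exponential fitting."""


class IllConditionedScaleError(PorcycleError, RuntimeError):
    """The fast/slow matching region carries too little signal to
    estimate a scale factor."""


class ContractError(PorcycleError, ValueError):
    """Generator inputs violate a simulation contract."""
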