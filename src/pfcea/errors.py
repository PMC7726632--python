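"""Exception hierarchy for pfcea."""


class PfceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigSchemaError(PfceaError):
    """A configuration file violates the documented schema (missing or unknown key)."""


class InputValidationError(PfceaError, ValueError):
    """A domain object violates one of its invariants (e.g. negative cost)."""


class ParameterNotApplicableError(PfceaError):
    """The requested sensitivity parameter does not exist for this strategy."""


class ExtrapolationError(PfceaError):
    """A survival curve does not cover the requested horizon."""


class InfeasibleAdvantageError(PfceaError):
    """A requested progression-free survival advantage cannot be represented
    within the stated horizon (the restricted-mean gap is bounded by
    horizon minus the control restricted mean)."""


class UnknownParameterError(PfceaError):
    """A distribution specification names a parameter the model does not have."""
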