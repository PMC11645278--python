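"""Exception types shared across the pipeline."""


class BrainClockError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BrainClockError, ValueError):
    """Invalid configuration value or unknown enumeration member."""


class GenerationError(BrainClockError, ValueError):
    """Synthetic-data generation asked for an impossible output."""


class DegenerateInputError(BrainClockError, ValueError):
    """Input is degenerate for the requested computation (constant column, etc.)."""


class ContractError(BrainClockError, ValueError):
    """A documented precondition of an operation was violated."""
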