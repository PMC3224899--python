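"""Exception hierarchy for the virtual-trials toolkit."""


class VTrialError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VTrialError, ValueError):
    """Non-finite or out-of-domain numerical input."""


class ConfigurationError(VTrialError, ValueError):
    """Nonphysical parameters or a malformed configuration file."""


class CoverageError(VTrialError, ValueError):
    """A schedule or SI profile does not cover the requested interval."""


class NumericalError(VTrialError, RuntimeError):
    """Integrator failure; the message names the offending interval."""


class InsufficientDataError(VTrialError, ValueError):
    """Too few observations for the requested operation."""


class SchemaError(VTrialError, ValueError):
    """A record file violates the documented layout; names file and row."""


class SimulationFailure(VTrialError, RuntimeError):
    """A single virtual patient's simulation became nonphysical (e.g. BG <= 0)."""


class ProtocolDefinitionError(ConfigurationError):
    """Dosing bands have gaps, overlaps or ambiguous boundaries."""
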