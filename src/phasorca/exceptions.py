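"""Exception hierarchy for phasorca.

All data-dependent failures derive from :class:`PhasorcaError` so callers
(and the CLI) can distinguish them from programming errors.
"""


class PhasorcaError(Exception):
    """Base class for all phasorca data errors."""


class EmptyDecayError(PhasorcaError, ValueError):
    """A decay histogram with zero photons was passed where photons are required."""


class InsufficientDataError(PhasorcaError, ValueError):
    """Too few samples/points to perform the requested estimate."""


class DegenerateTitrationError(PhasorcaError, ValueError):
    """Titration lifetimes span too little of the sensor range to fit."""


class UnstableCalibrationError(PhasorcaError, ValueError):
    """Phasor anchor clouds overlap; endpoints cannot be resolved."""


class ConfigurationError(PhasorcaError, ValueError):
    """Inconsistent or missing configuration (modes, parameter mismatch)."""


class FormatError(PhasorcaError, ValueError):
    """A file does not match the declared on-disk format."""
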