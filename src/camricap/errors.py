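"""Exception types shared across the package."""


class CamRicapError(Exception):
    """Base class for all package errors."""


class ShapeError(CamRicapError, ValueError):
    """Array dimensions do not match what an operation requires."""


class ValidationError(CamRicapError, ValueError):
    """Input values violate an operation's preconditions."""


class ConfigError(CamRicapError, ValueError):
    """A configuration file or option is malformed."""


class TrainingDivergedError(CamRicapError, RuntimeError):
    """Loss became non-finite during optimisation."""
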