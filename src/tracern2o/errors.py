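"""Exception hierarchy shared across the pipeline.

Validation problems (bad inputs, malformed files, impossible configuration)
and estimation problems (not enough usable data to fit anything) are kept
distinct because the command line maps them to different exit codes.
"""


class TracerN2OError(Exception):
    """Base class for all package errors."""


class DomainError(TracerN2OError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(TracerN2OError, ValueError):
    """A configuration value or scenario definition is invalid."""


class SchemaError(TracerN2OError, ValueError):
    """An input table does not match the expected schema."""


class EstimationError(TracerN2OError, RuntimeError):
    """A quantity cannot be estimated from the data provided."""


#: CLI exit code for validation-type failures (DomainError/ConfigError/SchemaError)
EXIT_VALIDATION = 2
#: CLI exit code for estimation failures
EXIT_ESTIMATION = 3
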