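"""Exception hierarchy shared across the package."""


class MethylFPError(Exception):
    """Base class for all package errors."""


class ValidationError(MethylFPError, ValueError):
    """Invalid user input (bad concentrations, malformed tables, ...)."""


class NumericalError(MethylFPError, RuntimeError):
    """A numerical routine failed to converge or violated a balance check."""


class PlateSchemaError(ValidationError):
    """A plate CSV does not conform to the documented dialect."""
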