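"""Exception hierarchy for accuprof."""


class AccuprofError(Exception):
    """Base class for all accuprof errors."""


class SchemaError(AccuprofError):
    """An input table is missing a required column or has a malformed header."""


class DataValidationError(AccuprofError):
    """A row violates a domain invariant (e.g. non-positive nominal concentration)."""


class DesignError(AccuprofError):
    """The experimental design is degenerate or unbalanced where balance is required."""


class SingularFitError(AccuprofError):
    """A calibration fit is singular (zero slope with no response variance)."""
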