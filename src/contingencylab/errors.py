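"""Exception types shared across the package."""


class ContingencyLabError(Exception):
    """Base class for package errors."""


class ConfigurationError(ContingencyLabError):
    """Inconsistent or incomplete configuration (e.g. arm mismatch, missing cell)."""


class DataError(ContingencyLabError):
    """Input data violate a precondition (e.g. all-missing imputation row)."""


class DesignError(ContingencyLabError):
    """The factorial design is degenerate (e.g. an empty between-cell)."""


class NumericError(ContingencyLabError):
    """A numerical routine failed (zero variance, non-convergent root-finding)."""
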