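"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2,
data/validation problems exit 3.
"""


class PmbodError(Exception):
    """Base class for all package errors."""


class ValidationError(PmbodError, ValueError):
    """An input value violates a domain invariant."""


class FormatError(ValidationError):
    """A tabular input is structurally malformed (bad bins, bad columns)."""


class DataError(PmbodError):
    """Inconsistent or missing data across inputs (e.g. cause not in table)."""


class ConfigurationError(PmbodError):
    """A run or scenario configuration cannot be resolved."""


class GenerationError(PmbodError):
    """A synthetic-data spec cannot be satisfied."""
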