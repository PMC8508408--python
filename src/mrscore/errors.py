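"""Exception hierarchy for the mrscore pipeline.

Exit-code mapping used by the CLI: ValidationError/SchemaError/
ConfigurationError -> 2, NumericalError -> 3.
"""


class MrscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrscoreError):
    """Invalid configuration value (counts, rates, fractions, paths)."""


class SchemaError(MrscoreError):
    """An input table does not match the expected column schema."""


class ValidationError(MrscoreError):
    """A row or value fails a domain invariant (bounds, positivity, ids)."""


class UnclassifiableCategoryError(MrscoreError):
    """An institution category is not covered by the grading scheme."""

    def __init__(self, labels):
        self.labels = sorted(set(labels)) if not isinstance(labels, str) else [labels]
        super().__init__(f"unclassifiable institution categories: {self.labels}")


class CompositionError(MrscoreError):
    """A city is missing a level score required to compose the MRSc."""


class NumericalError(MrscoreError):
    """A numerical procedure failed (singular local fit, undefined score)."""
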