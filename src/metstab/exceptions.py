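"""Exception hierarchy.

Every input problem raises a named subclass of :class:`ValidationError` so
callers (and the CLI) can distinguish failure modes without parsing messages.
"""


class MetStabError(Exception):
    """Base class for all package errors."""


class ValidationError(MetStabError, ValueError):
    """Invalid input data."""


class MissingColumnError(ValidationError):
    """A mapped column is absent from the input file."""


class DuplicateKeyError(ValidationError):
    """The same (environment, genotype, replicate) key occurs twice."""


class UnbalancedDesignError(ValidationError):
    """Replicate counts differ between (environment, genotype) cells."""


class NonNumericValueError(ValidationError):
    """A trait value could not be parsed as a finite real number."""


class EmptyDataError(ValidationError):
    """The input contains no records."""


class DegenerateInputError(ValidationError):
    """The input is too small or too degenerate for the requested analysis."""


class MissingReplicatesError(MetStabError):
    """A replicate-level operation was requested on means-only input."""
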