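"""Exception hierarchy.

All package errors derive from :class:`OsteofrailiaError` so callers can
catch broadly; the subclasses distinguish bad user input, incomplete
configuration, out-of-domain results, empty selections, and parse failures.
"""


class OsteofrailiaError(Exception):
    """Base class for all errors raised by this package."""


class InputError(OsteofrailiaError, ValueError):
    """A caller-supplied value violates a precondition."""


class ConfigurationError(OsteofrailiaError):
    """A reference database, population model, or config file is incomplete
    or internally inconsistent."""


class DomainError(OsteofrailiaError):
    """A computation left its physical or probabilistic domain
    (e.g. a T-score implying non-positive BMD, a prevalence outside (0, 1))."""


class EmptySelectionError(OsteofrailiaError):
    """A filter or grouping selected no records."""


class ParseError(OsteofrailiaError):
    """A registry, study table, or cohort file failed to parse or validate."""


class ConflictError(OsteofrailiaError):
    """Duplicate identifiers within one registry or table."""


class DegenerateDataError(OsteofrailiaError):
    """Input data carry no usable variance for a fit."""
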