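"""Exception hierarchy.

All user-facing failures derive from :class:`ScreenError` so callers (and
the CLI) can catch one base class.  Messages always name the offending
column, group, or row: silent drops are never allowed.
"""


class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ScreenError):
    """An input table is missing a required column or has a bad dtype."""


class DuplicateWellError(ScreenError):
    """Two rows share the same (cell line, compound pair, concentrations, replicate) key."""


class ParseError(ScreenError):
    """A cell could not be parsed as a number; the row number is reported."""


class NormalizationError(ScreenError):
    """A normalization group lacks a usable vehicle (DMSO) control well."""


class IncompleteGridError(ScreenError):
    """A dose matrix is missing cells and cannot be assembled."""


class GroupingError(ScreenError):
    """Records that should share metadata do not, or a group is empty."""


class DegenerateFitError(ScreenError):
    """Dose-response data carry no signal (flat within tolerance)."""


class FitRangeError(ScreenError):
    """A requested effect level lies outside the fitted curve's range."""


class ConfigurationError(ScreenError):
    """An analysis parameter is missing or out of its valid range."""


class EndpointError(ScreenError):
    """A tumor trajectory cannot yield the requested endpoint (e.g. no day-0 volume)."""
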