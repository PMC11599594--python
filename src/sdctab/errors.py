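"""Exception hierarchy for sdctab.

Everything raised on bad user input derives from :class:`SdcError` so callers
(and the CLI) can catch one type; programming errors stay ordinary Python
exceptions.
"""

from __future__ import annotations


class SdcError(Exception):
    """Base class for all sdctab errors."""


class SchemaError(SdcError):
    """A role assignment or column reference is invalid for the table."""


class ParseError(SdcError):
    """A CSV file is malformed (ragged rows, duplicate headers, ...)."""


class RangeError(SdcError):
    """A numeric value falls outside the interval domain it must lie in."""


class HierarchyError(SdcError):
    """A hierarchy is ill-formed (non-functional level mapping, bad levels)."""


class HierarchyCoverageError(HierarchyError):
    """A cell value is not covered by any level of the relevant hierarchy."""


class HierarchyInconsistencyError(HierarchyError):
    """Observed values of one column span two different hierarchy levels."""


class ConfigError(SdcError):
    """A run configuration is structurally invalid."""


class EmptyTableError(SdcError):
    """An operation that needs at least one retained row got none."""


class UnachievableRequirementError(SdcError):
    """No transformation + suppression within budget satisfies the requirement.

    Attributes
    ----------
    best_transformation : list[int]
        The transformation vector with the smallest residual violation seen
        during the search.
    residual_rows : int
        Number of rows still violating at ``best_transformation`` (beyond what
        the suppression budget can absorb).
    """

    def __init__(self, message: str, best_transformation=None, residual_rows=None):
        super().__init__(message)
        self.best_transformation = best_transformation
        self.residual_rows = residual_rows
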