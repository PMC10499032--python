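"""Exception hierarchy for matrisomekit.

Everything raised on purpose derives from :class:`MatrisomeKitError`, so
callers embedding the library can catch one base class. Most errors also
subclass ``ValueError`` because they signal bad inputs rather than bugs.
"""

from __future__ import annotations


class MatrisomeKitError(Exception):
    """Base class for all errors raised by matrisomekit."""


class SchemaError(MatrisomeKitError, ValueError):
    """A reference CSV (or GO:CC map) does not follow the documented schema."""


class ReferenceValidationError(MatrisomeKitError, ValueError):
    """A matrisome reference failed validation; the report is attached."""

    def __init__(self, report):
        self.report = report
        lines = "; ".join(f"{sev}@{loc}: {msg}" for sev, loc, msg in report.issues if sev == "error")
        super().__init__(f"reference validation failed: {lines}")


class TableFormatError(MatrisomeKitError, ValueError):
    """An input table violates the format contract (headers, XML shape, ...)."""


class ParameterError(MatrisomeKitError, ValueError):
    """An operation was called with an invalid parameter combination."""


class EmptyChartError(MatrisomeKitError, ValueError):
    """A chart was requested for data with no non-zero groups."""


class ChartDomainError(MatrisomeKitError, ValueError):
    """Chart inputs are outside the supported domain (e.g. negative values)."""
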