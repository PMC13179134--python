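"""Exception hierarchy for marrowmap.

Validation errors name the offending field so CLI callers can surface
actionable messages; they map to exit code 2 at the command line.
"""


class MarrowmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MarrowmapError, ValueError):
    """A configuration or input value violates its contract."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ContractError(MarrowmapError, ValueError):
    """A required mark or attribute is missing from an input object."""


class EmptyStructureError(MarrowmapError, ValueError):
    """Distance to an empty structure set is undefined."""


class OutOfBoundsError(MarrowmapError, ValueError):
    """Cells fall outside the section; carries the offending row indices."""

    def __init__(self, rows, message: str = "cells outside section bounds"):
        self.rows = list(rows)
        super().__init__(f"{message}: rows {self.rows}")


class DegenerateWeightsError(MarrowmapError, ValueError):
    """Chemotaxis-weighted sampling requested but all weights are zero."""


class BoundaryEstimateError(MarrowmapError, ValueError):
    """Limiting-dilution likelihood is monotone; the MLE sits on a boundary.

    ``direction`` is ``"high"`` when every animal responded (frequency
    unbounded high) and ``"low"`` when none did.
    """

    def __init__(self, direction: str, message: str):
        self.direction = direction
        super().__init__(message)
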