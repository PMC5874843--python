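"""Exception hierarchy for the pipeline."""

from __future__ import annotations


class GelforgeError(Exception):
    """Base class for all package errors."""


class FormulaError(GelforgeError):
    """Malformed or unknown chemical formula token."""


class StructureParseError(GelforgeError):
    """Malformed structure file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class PackingError(GelforgeError):
    """Random packing exhausted its attempt budget.

    ``achieved`` reports how many chains were successfully placed.
    """

    def __init__(self, message: str, achieved: int):
        self.achieved = achieved
        super().__init__(f"{message} (placed {achieved})")


class CrosslinkShortfallError(GelforgeError):
    """Crosslinking stalled before the stoichiometric target.

    Carries the partially built model and the achieved crosslink count so
    callers can inspect or accept the partial network.
    """

    def __init__(self, message: str, achieved: int, model=None):
        self.achieved = achieved
        self.model = model
        super().__init__(f"{message} (achieved {achieved})")


class CapacityError(GelforgeError):
    """Not enough free anchor points for the requested grafts."""

    def __init__(self, message: str, available: int):
        self.available = available
        super().__init__(f"{message} (available {available})")


class PlacementError(GelforgeError):
    """Guest placement exhausted its attempt budget."""

    def __init__(self, message: str, achieved: int):
        self.achieved = achieved
        super().__init__(f"{message} (placed {achieved})")


class EstimabilityError(GelforgeError):
    """Design matrix rank-deficient; names the aliased terms."""

    def __init__(self, message: str, aliased=()):
        self.aliased = tuple(aliased)
        super().__init__(message)
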