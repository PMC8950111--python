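"""Small shared helpers: presentation rounding and domain errors."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round1(x: float) -> float:
    """Round half-up to one decimal place.

    Matches how the source tables present percentages and ratios
    (e.g. 8.888...% -> 8.9). Python's built-in ``round`` uses banker's
    rounding, which disagrees on exact .x5 values.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class DomainError(ValueError):
    """An input violates a documented precondition."""
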