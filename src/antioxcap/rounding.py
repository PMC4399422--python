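"""Display rounding conventions.

Published assay tables mix two conventions for 2-decimal display: ordinary
round-half-up (4.4499 -> 4.45) and plain truncation (0.2657 -> 0.26,
566.355 -> 566.35). Both are provided; raw values are always kept at full
precision and the convention used is recorded in report metadata.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

CONVENTIONS = ("half-up", "truncate")


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


def display_round(x: float, convention: str = "half-up", ndigits: int = 2) -> float:
    if convention == "half-up":
        return round_half_up(x, ndigits)
    if convention == "truncate":
        return truncate(x, ndigits)
    raise ValueError(f"unknown rounding convention {convention!r}")
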