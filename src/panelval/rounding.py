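"""Display rounding policies.

All statistics in this package are computed and compared at full floating
precision; rounding is strictly a rendering concern. Two conventions
coexist in study reports: "half-up" (11.757 -> 11.8) for descriptive
statistics, and "truncate" (round toward zero: 0.9294 -> 0.92) for V and
its confidence bounds, which is what the classic desk implementation
prints. ``"none"`` leaves full precision.

Both are implemented with decimal arithmetic on ``repr(float)`` so that a
value like 0.89 truncates to 0.89, not 0.88 via a binary representation
artifact.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["ROUNDING_POLICIES", "round_half_up", "truncate", "apply_policy", "fmt"]

ROUNDING_POLICIES = ("half-up", "truncate", "none")


def _quantize(x: float, ndigits: int, mode) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=mode))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at the given decimal place."""
    return _quantize(x, ndigits, ROUND_HALF_UP)


def truncate(x: float, ndigits: int = 2) -> float:
    """Drop digits beyond ``ndigits`` (round toward zero)."""
    return _quantize(x, ndigits, ROUND_DOWN)


def apply_policy(x: float, ndigits: int, policy: str) -> float:
    if policy == "half-up":
        return round_half_up(x, ndigits)
    if policy == "truncate":
        return truncate(x, ndigits)
    if policy == "none":
        return float(x)
    raise ValueError(f"unknown rounding policy {policy!r}")


def fmt(x: float, ndigits: int = 2, policy: str = "half-up") -> str:
    """Format with a fixed number of decimals under the given policy."""
    if policy == "none":
        return repr(float(x))
    return f"{apply_policy(x, ndigits, policy):.{ndigits}f}"
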