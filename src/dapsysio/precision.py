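"""Fixed-precision decimal formatting shared by the CSV dialect and verifier.

Values are rounded half-even at the requested number of decimals, applied to
the *shortest decimal representation* of the float (``repr``), which is what
a user reads off the number: ``0.33335`` rounds to ``0.3334`` at 4 decimals
even though its binary value is fractionally below the midpoint.  Formatter
and verifier share this helper so a stream always verifies exactly against
its own export.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

_QUANTA = {p: Decimal(1).scaleb(-p) for p in (4, 6)}


def format_fixed(value: float, decimals: int) -> str:
    """Render ``value`` with exactly ``decimals`` decimal places."""
    q = _QUANTA.get(decimals) or Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN):f}"


def round_fixed(value: float, decimals: int) -> float:
    """The f64 nearest to ``value`` rounded at ``decimals`` decimal places.

    Identical to parsing :func:`format_fixed` output, so comparing the two
    is exact by construction.
    """
    return float(format_fixed(value, decimals))
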