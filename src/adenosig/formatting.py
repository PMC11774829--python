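"""Report rounding and formatting conventions.

Group means and SDs print to one decimal, p-values to two significant
figures (scientific notation with unicode superscripts below 0.01), and
effect sizes to one decimal, mirroring the conventions of clinical
genomics comparison tables.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

_SUPERSCRIPTS = str.maketrans("0123456789-", "⁰¹²³⁴⁵⁶⁷⁸⁹⁻")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (5 rounds up), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


def format_p(p: float) -> str:
    """Render a p-value at two significant figures.

    Values below 0.01 use scientific notation with unicode superscripts
    (0.000341 -> "3.4 × 10⁻⁴"); larger values print as plain decimals.
    """
    if not math.isfinite(p):
        return "NA"
    if p >= 0.01:
        return f"{round_sig(p, 2):g}"
    if p == 0:
        return "0"
    exponent = math.floor(math.log10(p))
    mantissa = round_half_up(p / 10**exponent, 1)
    if mantissa >= 10:  # rounding pushed the mantissa over a decade
        mantissa /= 10
        exponent += 1
    return f"{mantissa:g} × 10{str(exponent).translate(_SUPERSCRIPTS)}"


def format_percent(x: float) -> str:
    """One-decimal percentage, half-up (65.55 -> '65.6 %')."""
    return f"{round_half_up(x, 1):g} %"
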