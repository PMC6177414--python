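"""Small shared helpers: sample-accounting arithmetic and rounding."""
from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with .5 always going away from zero (not banker's rounding)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent_increase(old: float, new: float) -> float:
    """100 * (new - old) / old."""
    if old == 0:
        raise ZeroDivisionError("percent_increase undefined for old == 0")
    return 100.0 * (new - old) / old


def percent_of(part: float, total: float) -> float:
    """100 * part / total."""
    if total == 0:
        raise ZeroDivisionError("percent_of undefined for total == 0")
    return 100.0 * part / total


def percent_outside(total: int, inside: int) -> float:
    """Share (in %) of items not in the flagged subset."""
    return percent_of(total - inside, total)
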