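"""Half-up rounding helpers.

Python's built-in ``round`` is banker's rounding; field reports round
half-up, so presentation layers go through these helpers.
"""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimals.

    A tiny epsilon guards against values like 44.99999999999999 that are
    exact halves (or integers) in the intended arithmetic.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    rounded = math.floor(abs(scaled) + 0.5 + 1e-9) * math.copysign(1.0, scaled)
    out = rounded / scale
    return out if ndigits > 0 else float(out)


def int_half_up(x: float) -> int:
    return int(round_half_up(x, 0))
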