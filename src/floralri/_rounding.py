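"""Half-up decimal rounding, as used when reporting index values.

Python's built-in ``round`` is banker's rounding; published isolation
indices are conventionally rounded half-up (0.4965 -> 0.497 at 3 dp).
"""

from __future__ import annotations

import decimal

import numpy as np


def round_half_up(x: float, digits: int = 3) -> float:
    """Round a scalar half-up to ``digits`` decimal places. NaN passes through."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def round_series_half_up(values, digits: int = 3):
    """Vectorised :func:`round_half_up` over an iterable; returns a list."""
    return [round_half_up(v, digits) for v in values]
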