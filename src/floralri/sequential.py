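"""Sequential combination of barrier strengths into contributions and totals.

Barriers act in the order they occur in the plant's life cycle, so an
early barrier pre-empts gene flow that later barriers never see.  Given
ordered strengths s_1..s_n (each in [-1, 1]) the absolute contribution of
each barrier is

    AC_1 = s_1
    AC_k = s_k * (1 - sum_{i<k} AC_i)

total isolation is TI = sum AC_k — for nonnegative strengths this equals
1 - prod(1 - s_i) — and the relative contribution is RC_k = AC_k / TI
(undefined when TI = 0).  A strength of 1 anywhere completes isolation:
all later AC are 0 and TI = 1.  Negative strengths (heterospecific excess)
propagate through the same recurrence and can reduce the total; they
trigger a warning since they make AC lose its share interpretation.

Barriers that were not measured for a pair (e.g. seed stages after a
fully incompatible cross) are skipped: the chain compresses over the
measured ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "BARRIER_ORDER",
    "BARRIER_CATEGORY",
    "absolute_contributions",
    "total_and_relative",
    "build_barrier_table",
    "category_means",
]

#: canonical life-cycle order of the barriers
BARRIER_ORDER = ("RI_F", "RI_MS", "RI_MP", "RI_I", "RI_S", "RI_V")

#: pre- vs postpollination classification
BARRIER_CATEGORY = {
    "RI_F": "pre", "RI_MS": "pre", "RI_MP": "pre",
    "RI_I": "post", "RI_S": "post", "RI_V": "post",
}


def absolute_contributions(strengths) -> np.ndarray:
    """Absolute contribution of each barrier in an ordered chain."""
    s = np.asarray(strengths, dtype=float)
    if s.size == 0:
        raise ValueError("empty barrier chain")
    if np.any(np.isnan(s)):
        raise ValueError("not-measured (NaN) strengths must be removed before the recurrence")
    if np.any((s < -1) | (s > 1)):
        raise ValueError(f"barrier strengths must lie in [-1, 1]; got {s}")
    if np.any(s < 0):
        warnings.warn(
            "negative barrier strength: heterospecific gene flow exceeds conspecific; "
            "the sequential total may decrease",
            stacklevel=2,
        )
    ac = np.empty_like(s)
    remaining = 1.0
    for i, si in enumerate(s):
        ac[i] = si * remaining
        remaining -= ac[i]
    return ac


def total_and_relative(ac) -> tuple[float, np.ndarray]:
    """Total isolation and relative contributions from absolute ones.

    RC is NaN-filled when the total is 0 (no isolation to apportion);
    this is flagged, not raised.
    """
    ac = np.asarray(ac, dtype=float)
    total = float(ac.sum())
    if total == 0:
        return 0.0, np.full_like(ac, np.nan)
    return total, ac / total


def build_barrier_table(barriers: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair sequential decomposition in long format.

    Parameters
    ----------
    barriers : DataFrame
        Columns ``recipient, donor, barrier, strength``; one row per
        directed pair and barrier, NaN strength meaning "not measured".
        Barriers are processed in :data:`BARRIER_ORDER` regardless of
        input row order.

    Returns
    -------
    table : DataFrame
        ``recipient, donor, barrier, strength, ac, rc`` — not-measured
        barriers keep their row with NaN in all value columns.
    totals : DataFrame
        ``recipient, donor, total`` per directed pair.
    """
    required = ["recipient", "donor", "barrier", "strength"]
    missing = [c for c in required if c not in barriers.columns]
    if missing:
        raise SchemaError(f"barrier table is missing columns {missing}", file="barriers")
    unknown = set(barriers["barrier"]) - set(BARRIER_ORDER)
    if unknown:
        raise SchemaError(f"unknown barrier labels {sorted(unknown)}", file="barriers",
                          column="barrier")
    if barriers.duplicated(["recipient", "donor", "barrier"]).any():
        raise SchemaError("duplicate (recipient, donor, barrier) rows", file="barriers")

    order = {b: i for i, b in enumerate(BARRIER_ORDER)}
    rows, tot_rows = [], []
    for (rec, don), g in barriers.groupby(["recipient", "donor"], sort=True):
        g = g.sort_values("barrier", key=lambda s: s.map(order))
        measured = g["strength"].notna().to_numpy()
        ac = np.full(len(g), np.nan)
        rc = np.full(len(g), np.nan)
        if measured.any():
            ac_m = absolute_contributions(g["strength"].to_numpy()[measured])
            total, rc_m = total_and_relative(ac_m)
            ac[measured] = ac_m
            rc[measured] = rc_m
        else:
            total = np.nan
        for (b, s), a, r in zip(zip(g["barrier"], g["strength"]), ac, rc):
            rows.append((rec, don, b, s, a, r))
        tot_rows.append((rec, don, total))
    table = pd.DataFrame(rows, columns=["recipient", "donor", "barrier", "strength", "ac", "rc"])
    totals = pd.DataFrame(tot_rows, columns=["recipient", "donor", "total"])
    return table, totals


def category_means(barriers: pd.DataFrame,
                   categories: dict[str, str] = BARRIER_CATEGORY) -> dict[str, float]:
    """Unweighted mean barrier strength per category (pre / post).

    Every measured directional cell counts once, including assigned zeros
    of the binary mechanical indices; not-measured (NaN) cells are
    excluded.  An empty category is an error.
    """
    out: dict[str, list[float]] = {}
    for _, row in barriers.iterrows():
        cat = categories.get(row["barrier"])
        if cat is None:
            raise SchemaError(f"barrier {row['barrier']!r} has no category", column="barrier")
        if pd.notna(row["strength"]):
            out.setdefault(cat, []).append(float(row["strength"]))
    for cat in set(categories.values()):
        if not out.get(cat):
            raise ValueError(f"no measured estimates in category {cat!r}")
    return {cat: float(np.mean(vals)) for cat, vals in sorted(out.items())}
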