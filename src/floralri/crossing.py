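"""Postpollination isolation from reciprocal hand-pollination experiments.

Three stages of a cross can fail after heterospecific pollen reaches the
stigma, each measured against the recipient species' conspecific
(intraspecific outcross) baseline and expressed with the same index

    RI = 1 - 2 * H / (H + C)

* RI_I — interspecific incompatibility (prezygotic): H and C are percent
  fruit set of pollinated flowers.
* RI_S — hybrid seed production (postzygotic): H and C are mean seeds per
  successful fruit.
* RI_V — hybrid seed viability (postzygotic): H and C are mean germination
  percentages over replicate trials.

RI = 1 means complete isolation (no heterospecific events), 0 random gene
flow (H = C), -1 purely heterospecific success.  H + C = 0 is "no data",
which is deliberately an error rather than an index of 1.  Stages
downstream of a fully incompatible cross (no fruit, hence no seeds) are
"not measured" and reported as NaN with ``measured = False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingBaselineError, SchemaError, UndefinedIndexError

__all__ = [
    "POSTMATING_BARRIERS",
    "PostRI",
    "summarize_crosses",
    "ri_postmating",
    "postmating_panel",
]

POSTMATING_BARRIERS = ("RI_I", "RI_S", "RI_V")

#: columns of the per-pair cross summary produced by :func:`summarize_crosses`
SUMMARY_COLUMNS = [
    "recipient", "donor",
    "fruit_rate", "n_flowers",
    "mean_seeds", "sd_seeds", "n_fruits",
    "germ_mean", "germ_sd", "n_replicates",
]


@dataclass(frozen=True)
class PostRI:
    """One postpollination barrier estimate for a directed cross."""

    recipient: str
    donor: str
    barrier: str
    H: float
    C: float
    ri: float
    n: int | None = None


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}", file=name)


def summarize_crosses(
    crosses: pd.DataFrame,
    seeds: pd.DataFrame | None = None,
    germination: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Collapse raw crossing tables to one summary row per (recipient, donor).

    Parameters
    ----------
    crosses : DataFrame
        Columns ``recipient, donor, flowers_pollinated, fruits_set``; may
        contain several rows (plants) per pair, which are pooled.
    seeds : DataFrame, optional
        Columns ``recipient, donor, fruit_id, n_seeds``, one row per fruit.
    germination : DataFrame, optional
        Columns ``recipient, donor, replicate, seeds_sown, seeds_germinated``.

    Returns
    -------
    DataFrame with one row per pair: percent fruit set (pooled), mean +/- sd
    seeds per fruit (sample sd, n-1 denominator), and mean +/- sd of replicate
    germination percentages.

    Notes
    -----
    Seed or germination rows for a pair that has no crossing record signal
    a bookkeeping error and raise :class:`SchemaError`.
    """
    _require_columns(crosses, ["recipient", "donor", "flowers_pollinated", "fruits_set"], "crosses")
    if (crosses["fruits_set"] > crosses["flowers_pollinated"]).any():
        bad = crosses.index[crosses["fruits_set"] > crosses["flowers_pollinated"]][0]
        raise SchemaError("fruits_set exceeds flowers_pollinated",
                          file="crosses", row=int(bad), column="fruits_set")
    if (crosses["flowers_pollinated"] <= 0).any():
        raise SchemaError("flowers_pollinated must be positive", file="crosses",
                          column="flowers_pollinated")

    grouped = crosses.groupby(["recipient", "donor"], sort=True).agg(
        flowers=("flowers_pollinated", "sum"), fruits=("fruits_set", "sum")
    )
    known_pairs = set(grouped.index)

    def _check_pairs(df: pd.DataFrame, name: str) -> None:
        extra = set(map(tuple, df[["recipient", "donor"]].itertuples(index=False))) - known_pairs
        if extra:
            raise SchemaError(
                f"{name} table references pairs with no cross records: {sorted(extra)}",
                file=name,
            )

    rows = []
    for (rec, don), g in grouped.iterrows():
        rows.append({
            "recipient": rec, "donor": don,
            "fruit_rate": 100.0 * g["fruits"] / g["flowers"],
            "n_flowers": int(g["flowers"]),
            "mean_seeds": np.nan, "sd_seeds": np.nan, "n_fruits": 0,
            "germ_mean": np.nan, "germ_sd": np.nan, "n_replicates": 0,
        })
    out = pd.DataFrame(rows).set_index(["recipient", "donor"])

    if seeds is not None and len(seeds):
        _require_columns(seeds, ["recipient", "donor", "fruit_id", "n_seeds"], "seeds")
        if (seeds["n_seeds"] < 0).any():
            raise SchemaError("n_seeds must be nonnegative", file="seeds", column="n_seeds")
        _check_pairs(seeds, "seeds")
        agg = seeds.groupby(["recipient", "donor"])["n_seeds"].agg(["mean", "std", "count"])
        out.loc[agg.index, "mean_seeds"] = agg["mean"]
        out.loc[agg.index, "sd_seeds"] = agg["std"]
        out.loc[agg.index, "n_fruits"] = agg["count"].astype(int)

    if germination is not None and len(germination):
        _require_columns(
            germination,
            ["recipient", "donor", "replicate", "seeds_sown", "seeds_germinated"],
            "germination",
        )
        if (germination["seeds_germinated"] > germination["seeds_sown"]).any():
            raise SchemaError("seeds_germinated exceeds seeds_sown",
                              file="germination", column="seeds_germinated")
        _check_pairs(germination, "germination")
        pct = 100.0 * germination["seeds_germinated"] / germination["seeds_sown"]
        tmp = germination.assign(pct=pct).groupby(["recipient", "donor"])["pct"]
        agg = tmp.agg(["mean", "std", "count"])
        out.loc[agg.index, "germ_mean"] = agg["mean"]
        out.loc[agg.index, "germ_sd"] = agg["std"]
        out.loc[agg.index, "n_replicates"] = agg["count"].astype(int)

    return out.reset_index()[SUMMARY_COLUMNS]


def ri_postmating(H: float, C: float, barrier: str,
                  recipient: str = "", donor: str = "",
                  n: int | None = None) -> PostRI:
    """RI = 1 - 2H/(H+C) for one barrier stage.

    H and C may be on any common scale (percent or fraction, counts or
    means); the index is scale-invariant.  ``H + C = 0`` raises
    :class:`UndefinedIndexError` — absence of data is not complete isolation.
    """
    if H < 0 or C < 0:
        raise ValueError(f"H and C must be nonnegative (got H={H}, C={C})")
    if H + C == 0:
        raise UndefinedIndexError(
            f"H + C = 0 for barrier {barrier} ({recipient!r} x {donor!r}): index undefined"
        )
    ri = 1.0 - 2.0 * H / (H + C)
    return PostRI(recipient, donor, barrier, float(H), float(C), float(ri), n)


# (summary column, sample-size column) per barrier stage
_STAGE_FIELDS = {
    "RI_I": ("fruit_rate", "n_flowers"),
    "RI_S": ("mean_seeds", "n_fruits"),
    "RI_V": ("germ_mean", "n_replicates"),
}


def postmating_panel(summaries: pd.DataFrame) -> pd.DataFrame:
    """All three postpollination indices for every heterospecific pair.

    ``summaries`` is the output of :func:`summarize_crosses` (or an
    equivalently shaped table of published summary statistics) and must
    contain, for every heterospecific recipient, the intraspecific
    baseline row with ``recipient == donor``.

    Returns a long DataFrame ``recipient, donor, barrier, H, C, ri, n,
    measured``.  A cross with zero fruit set yields RI_I = 1 and marks
    RI_S and RI_V as not measured (NaN, ``measured = False``); the same
    sentinel is used when a stage simply has no data for an otherwise
    successful cross.
    """
    _require_columns(summaries, SUMMARY_COLUMNS[:3], "summaries")
    idx = summaries.set_index(["recipient", "donor"])
    if idx.index.has_duplicates:
        raise SchemaError("duplicate (recipient, donor) rows in summaries", file="summaries")

    rows = []
    hetero = idx[[r != d for r, d in idx.index]]
    for (rec, don), row in hetero.iterrows():
        if (rec, rec) not in idx.index:
            raise MissingBaselineError(
                f"no conspecific baseline for recipient {rec!r} (stage RI_I)"
            )
        con = idx.loc[(rec, rec)]
        downstream_blocked = False
        for barrier in POSTMATING_BARRIERS:
            col, ncol = _STAGE_FIELDS[barrier]
            H = row.get(col, np.nan)
            C = con.get(col, np.nan)
            n = row.get(ncol, None)
            measured = not downstream_blocked and pd.notna(H)
            if measured and pd.isna(C):
                raise MissingBaselineError(
                    f"no conspecific baseline for recipient {rec!r} (stage {barrier})"
                )
            if measured:
                r = ri_postmating(float(H), float(C), barrier, rec, don,
                                  int(n) if pd.notna(n) else None)
                rows.append((rec, don, barrier, r.H, r.C, r.ri, r.n, True))
                if barrier == "RI_I" and H == 0:
                    downstream_blocked = True  # no fruit -> no seeds to measure
            else:
                rows.append((rec, don, barrier, np.nan, np.nan, np.nan, None, False))
    return pd.DataFrame(
        rows,
        columns=["recipient", "donor", "barrier", "H", "C", "ri", "n", "measured"],
    )
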