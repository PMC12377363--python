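"""Bundled reference data and simulation presets.

The reference tables summarise a published field study of four sympatric
bat-pollinated *Werauhia* bromeliads (Bromeliaceae, Tillandsioideae) from
a Costa Rican montane forest — *W. ampla* (Wa), *W. nephrolepis* (Wn),
*W. pedicellata* (Wp) and *W. subsecunda* (Ws).  They are provided at the
level of published summary statistics (rates, means, sample sizes), which
is exactly the granularity the index formulas consume, and double as the
package's worked example.

The ``werauhia_*_params`` presets parameterise the synthetic-data
generator to mimic the same study: four flowering seasons with
steady-state (Wa, Ws), bimodal (Wp) and cornucopia (Wn) schedules,
crossing outcomes matching the observed rates, and a large-flowered
(Wa, Wn) vs small-flowered (Ws, Wp) morphometric structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (
    CrossingParams,
    GaussianPeak,
    MorphologyParams,
    PairCross,
    PhenologyParams,
)

__all__ = [
    "WERAUHIA_SPECIES",
    "werauhia_cross_summaries",
    "werauhia_barrier_strengths",
    "werauhia_positions",
    "werauhia_phenology_params",
    "werauhia_crossing_params",
    "werauhia_morphology_params",
]

WERAUHIA_SPECIES = ("Wa", "Wn", "Wp", "Ws")

# Reciprocal hand-pollination summaries: percent fruit set (pooled over
# flowers), mean +/- sd seeds per successful fruit, and mean +/- sd
# germination percentage over 12 replicates of 40 seeds.  Diagonal rows
# are the recipients' intraspecific outcross baselines.  Crosses that set
# no fruit have no seed/germination data.  Wn overlapped no other species
# in flower, so it was never crossed.
_CROSS_SUMMARIES = [
    # recipient, donor, fruit%, n_fls, seeds_mean, seeds_sd, n_frt, germ%, germ_sd, n_rep
    ("Wa", "Wa", 82.4, 17, 2136.0, 497.0, 14, 80.6, 15.7, 12),
    ("Wa", "Wp", 0.0, None, None, None, 0, None, None, 0),
    ("Wa", "Ws", 0.0, None, None, None, 0, None, None, 0),
    ("Wp", "Wa", 0.0, None, None, None, 0, None, None, 0),
    ("Wp", "Wp", 58.1, 31, 367.0, 48.0, 8, 92.5, 6.7, 12),
    ("Wp", "Ws", 47.8, 23, 152.0, 76.0, 6, 31.9, 28.4, 12),
    ("Ws", "Wa", 54.5, 33, 214.0, 84.0, 11, 73.1, 12.7, 12),
    ("Ws", "Wp", 37.0, 27, 330.0, 182.0, 6, 92.3, 4.9, 12),
    ("Ws", "Ws", 76.5, 17, 636.0, 234.0, 8, 98.8, 2.0, 12),
]

# Published directional barrier strengths (recipient x donor), in
# life-cycle order; None marks barriers not measured for that pair.
_BARRIER_STRENGTHS = {
    #               RI_F   RI_MS RI_MP RI_I   RI_S   RI_V
    ("Wa", "Wn"): (0.984, 0, 0, None, None, None),
    ("Wn", "Wa"): (0.968, 0, 0, None, None, None),
    ("Wa", "Wp"): (0.497, 1, 0, 1.0, None, None),
    ("Wp", "Wa"): (0.467, 1, 0, 1.0, None, None),
    ("Wa", "Ws"): (0.128, 1, 1, 1.0, None, None),
    ("Ws", "Wa"): (0.258, 1, 1, 0.168, 0.497, 0.149),
    ("Wn", "Ws"): (0.967, 1, 1, None, None, None),
    ("Ws", "Wn"): (0.983, 1, 1, None, None, None),
    ("Wp", "Ws"): (0.345, 0, 1, 0.097, 0.414, 0.487),
    ("Ws", "Wp"): (0.554, 0, 1, 0.348, 0.316, 0.034),
    ("Wp", "Wn"): (0.978, 1, 0, None, None, None),
    ("Wn", "Wp"): (0.991, 1, 0, None, None, None),
}

_BARRIERS = ("RI_F", "RI_MS", "RI_MP", "RI_I", "RI_S", "RI_V")


def werauhia_cross_summaries() -> pd.DataFrame:
    """Crossing-experiment summary table, shaped like ``summarize_crosses`` output."""
    df = pd.DataFrame(
        _CROSS_SUMMARIES,
        columns=["recipient", "donor", "fruit_rate", "n_flowers",
                 "mean_seeds", "sd_seeds", "n_fruits",
                 "germ_mean", "germ_sd", "n_replicates"],
    )
    return df.astype({"fruit_rate": float, "mean_seeds": float, "sd_seeds": float,
                      "germ_mean": float, "germ_sd": float})


def werauhia_barrier_strengths() -> pd.DataFrame:
    """Directional barrier strengths in long format (NaN = not measured)."""
    rows = []
    for (rec, don), vals in _BARRIER_STRENGTHS.items():
        for barrier, v in zip(_BARRIERS, vals):
            rows.append((rec, don, barrier, np.nan if v is None else float(v)))
    return pd.DataFrame(rows, columns=["recipient", "donor", "barrier", "strength"])


def werauhia_positions() -> dict[str, str]:
    """Anther/stigma arrangement per species.

    Ws carries its stamens and stigma in two lateral triplets; the other
    three form the usual dorsal hood over the corolla aperture.
    """
    return {"Wa": "dorsal_hood", "Wn": "dorsal_hood", "Wp": "dorsal_hood",
            "Ws": "lateral_triplets"}


def werauhia_phenology_params() -> PhenologyParams:
    """Four-season flowering schedules emulating the study species.

    Seasons run October through July (spanning the calendar-year
    boundary).  Wa and Ws are long, low steady-state bloomers in the dry
    season; Wp is bimodal; Wn bursts briefly (cornucopia) in the rainy
    season, temporally isolated from the rest.  Monitored-plant counts
    sit in the study's 70-385 range.
    """
    return PhenologyParams(
        species={
            "Wa": (200, (GaussianPeak(day=120, width=45, amplitude=0.30),)),
            "Wn": (70, (GaussianPeak(day=265, width=12, amplitude=0.80),)),
            "Wp": (100, (GaussianPeak(day=90, width=18, amplitude=0.50),
                         GaussianPeak(day=180, width=18, amplitude=0.45),)),
            "Ws": (385, (GaussianPeak(day=150, width=40, amplitude=0.35),)),
        },
        season_starts={
            "2012-2013": "2012-10-01",
            "2014-2015": "2014-10-01",
            "2018-2019": "2018-10-01",
            "2020-2021": "2020-12-01",
        },
        season_length=280,
        census_interval=14,
    )


def werauhia_crossing_params() -> CrossingParams:
    """Crossing design matching the observed rates and sample sizes.

    Negative binomial dispersions are chosen so the simulated seed-count
    variances match the published sds (k = m^2 / (var - m)).
    """
    return CrossingParams(
        pairs={
            ("Wa", "Wa"): PairCross(0.824, 2136.0, 18.6, 0.806, 17),
            ("Wa", "Wp"): PairCross(0.0, 100.0, 5.0, 0.5, 17),
            ("Wa", "Ws"): PairCross(0.0, 100.0, 5.0, 0.5, 17),
            ("Wp", "Wa"): PairCross(0.0, 100.0, 5.0, 0.5, 17),
            ("Wp", "Wp"): PairCross(0.581, 367.0, 69.5, 0.925, 31),
            ("Wp", "Ws"): PairCross(0.478, 152.0, 4.1, 0.319, 23),
            ("Ws", "Wa"): PairCross(0.545, 214.0, 6.7, 0.731, 33),
            ("Ws", "Wp"): PairCross(0.370, 330.0, 3.3, 0.923, 27),
            ("Ws", "Ws"): PairCross(0.765, 636.0, 7.5, 0.988, 17),
        },
        n_replicates=12,
        seeds_per_replicate=40,
    )


def _cov(sds: list[float], rho: float = 0.5) -> np.ndarray:
    sds = np.asarray(sds, dtype=float)
    corr = np.full((4, 4), rho) + np.eye(4) * (1 - rho)
    return corr * np.outer(sds, sds)


def werauhia_morphology_params() -> MorphologyParams:
    """Floral morphometrics: large-flowered Wa/Wn vs small-flowered Wp/Ws.

    Corolla, stamen and pistil lengths of the large group are 2-3x those
    of the small group, with moderate within-species correlation among
    traits — enough separation for the size barrier between the groups
    but overlapping morphology within each group.
    """
    return MorphologyParams(
        species={
            "Wa": (np.array([50.0, 12.0, 55.0, 60.0]), _cov([3.0, 1.2, 3.0, 3.0]), 30),
            "Wn": (np.array([47.0, 11.0, 52.0, 57.0]), _cov([3.0, 1.2, 3.0, 3.0]), 31),
            "Wp": (np.array([24.0, 8.0, 22.0, 24.0]), _cov([2.0, 1.0, 2.0, 2.0]), 30),
            "Ws": (np.array([22.0, 7.0, 20.0, 22.0]), _cov([2.0, 1.0, 2.0, 2.0]), 33),
        },
        flowers_per_plant=2,
    )
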