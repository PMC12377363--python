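"""Temporal reproductive isolation from flowering phenology.

Two sympatric species can only exchange pollen while both are in flower.
This module quantifies that opportunity from census data — repeated counts
of how many monitored plants of each species have open flowers — and turns
it into a directional isolation index RI_F in [-1, 1]:

    RI_F = 1 - 2 * H / (H + C)

where, summing over census dates, H is the focal (pollen-recipient)
species' co-flowering exposure to the heterospecific donor and C its
exposure to conspecifics.  With flowering proportions p_f(t) and p_o(t)
(fraction of monitored plants in flower, which normalises unequal sample
sizes), each date with p_f + p_o > 0 contributes

    H += p_f * p_o / (p_f + p_o)      C += p_f**2 / (p_f + p_o)

so disjoint schedules give RI_F = 1 (complete temporal isolation),
identical schedules give RI_F = 0 (no barrier), and dates where only the
focal species flowers count entirely toward conspecific opportunity.

Multi-season studies average the per-season index; seasons in which the
focal species never flowered provide no mating opportunities and are
dropped from the average with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NoFloweringError, SeasonMismatchError, UndefinedIndexError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenologySeries",
    "TemporalRI",
    "align_censuses",
    "coflowering_exposure",
    "ri_phenology",
    "seasonal_mean_ri",
    "phenology_ri_table",
]


@dataclass(frozen=True)
class PhenologySeries:
    """One species' flowering census across the dates of one season.

    Parameters
    ----------
    species : str
        Species identifier.
    season : str
        Season identifier (e.g. ``"2018-2019"``); a season may span the
        calendar-year boundary, which is why dates, not day-of-year, are
        stored.
    dates : array-like of datetime64 (or ISO-8601 strings)
        Census dates, strictly increasing.
    n_flowering : array-like of int
        Number of monitored plants with open flowers at each date.
    n_sampled : array-like of int
        Number of plants monitored at each date (> 0).
    """

    species: str
    season: str
    dates: np.ndarray
    n_flowering: np.ndarray
    n_sampled: np.ndarray

    def __post_init__(self):
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        nf = np.asarray(self.n_flowering, dtype=np.int64)
        ns = np.asarray(self.n_sampled, dtype=np.int64)
        if dates.size == 0:
            raise ValueError("a phenology series needs at least one census date")
        if not (dates.shape == nf.shape == ns.shape):
            raise ValueError("dates, n_flowering and n_sampled must have equal length")
        if dates.size > 1 and not np.all(np.diff(dates).astype(int) > 0):
            raise ValueError("census dates must be strictly increasing")
        if np.any(nf < 0):
            raise ValueError("n_flowering must be nonnegative")
        if np.any(ns <= 0):
            raise ValueError("n_sampled must be positive")
        if np.any(nf > ns):
            raise ValueError("n_flowering cannot exceed n_sampled")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "n_flowering", nf)
        object.__setattr__(self, "n_sampled", ns)

    @property
    def proportions(self) -> np.ndarray:
        """Flowering proportion p(t) = n_flowering / n_sampled per census date."""
        return self.n_flowering / self.n_sampled

    def __len__(self) -> int:  # number of census dates
        return int(self.dates.size)


@dataclass(frozen=True)
class TemporalRI:
    """Directional temporal isolation of a focal (recipient) species.

    ``season == "mean"`` marks a multi-season average, in which case H and
    C are NaN (the index, not the exposures, is averaged).
    """

    focal: str
    other: str
    season: str
    H: float
    C: float
    ri: float


def align_censuses(a: PhenologySeries, b: PhenologySeries) -> pd.DataFrame:
    """Pair two same-season census series on the union of their dates.

    A species without a census on some date contributes flowering
    proportion 0 there (censuses are near-synchronous; absence from the
    grid is treated as not flowering, not interpolated).

    Returns a DataFrame with columns ``date``, ``p_a``, ``p_b``.
    """
    if a.season != b.season:
        raise SeasonMismatchError(
            f"cannot compare censuses across seasons: {a.season!r} vs {b.season!r}"
        )
    sa = pd.Series(a.proportions, index=pd.Index(a.dates, name="date"))
    sb = pd.Series(b.proportions, index=pd.Index(b.dates, name="date"))
    out = pd.concat({"p_a": sa, "p_b": sb}, axis=1).fillna(0.0).sort_index()
    return out.reset_index()


def coflowering_exposure(focal: PhenologySeries, other: PhenologySeries) -> tuple[float, float]:
    """Heterospecific (H) and conspecific (C) co-flowering exposure of the focal species.

    Raises
    ------
    NoFloweringError
        If the focal species never flowered in the season (no mating
        opportunities; the downstream index is undefined).
    """
    aligned = align_censuses(focal, other)
    p_f = aligned["p_a"].to_numpy()
    p_o = aligned["p_b"].to_numpy()
    if not np.any(p_f > 0):
        raise NoFloweringError(
            f"{focal.species!r} never flowered in season {focal.season!r}"
        )
    tot = p_f + p_o
    active = tot > 0
    H = float(np.sum(p_f[active] * p_o[active] / tot[active]))
    C = float(np.sum(p_f[active] ** 2 / tot[active]))
    return H, C


def ri_phenology(focal: PhenologySeries, other: PhenologySeries) -> TemporalRI:
    """Temporal isolation index of ``focal`` (pollen recipient) against ``other``."""
    H, C = coflowering_exposure(focal, other)
    if H + C == 0:
        raise UndefinedIndexError(
            f"H + C = 0 for {focal.species!r} x {other.species!r} in {focal.season!r}"
        )
    ri = 1.0 - 2.0 * H / (H + C)
    return TemporalRI(focal.species, other.species, focal.season, H, C, ri)


def seasonal_mean_ri(per_season: Sequence[TemporalRI]) -> TemporalRI:
    """Arithmetic mean of per-season temporal indices for one directed pair."""
    if len(per_season) == 0:
        raise ValueError("no per-season indices to average")
    pairs = {(r.focal, r.other) for r in per_season}
    if len(pairs) != 1:
        raise ValueError(f"cannot average across different species pairs: {sorted(pairs)}")
    focal, other = next(iter(pairs))
    mean = float(np.mean([r.ri for r in per_season]))
    return TemporalRI(focal, other, "mean", float("nan"), float("nan"), mean)


def phenology_ri_table(series: Iterable[PhenologySeries]) -> pd.DataFrame:
    """Per-season and multi-season-mean temporal RI for every directed pair.

    Seasons in which a focal species never flowered are excluded from
    that pair's mean and logged.  Returns a long DataFrame with columns
    ``focal, other, season, H, C, ri``.
    """
    by_season: dict[str, dict[str, PhenologySeries]] = {}
    for s in series:
        by_season.setdefault(s.season, {})[s.species] = s
    rows: list[TemporalRI] = []
    per_pair: dict[tuple[str, str], list[TemporalRI]] = {}
    for season in sorted(by_season):
        sp = by_season[season]
        for f, o in permutations(sorted(sp), 2):
            try:
                r = ri_phenology(sp[f], sp[o])
            except NoFloweringError:
                logger.warning(
                    "season %s dropped for pair (%s, %s): focal never flowered",
                    season, f, o,
                )
                continue
            rows.append(r)
            per_pair.setdefault((f, o), []).append(r)
    for pair in sorted(per_pair):
        rows.append(seasonal_mean_ri(per_pair[pair]))
    return pd.DataFrame(
        [(r.focal, r.other, r.season, r.H, r.C, r.ri) for r in rows],
        columns=["focal", "other", "season", "H", "C", "ri"],
    )
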