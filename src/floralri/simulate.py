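"""Synthetic phenology, crossing and morphometric data with known truth.

The generator mirrors the sampling designs the analysis modules expect,
with ground-truth isolation indices available in closed form
(:func:`true_ri`) so estimator behaviour can be checked by parameter
recovery:

* flowering schedules are Gaussian-bump mixtures — one wide low bump for
  a "steady-state" bloomer, one narrow tall bump for a "cornucopia"
  burst, two bumps for a bimodal species — censused every 14 days with
  binomially sampled flowering counts;
* hand-pollination outcomes are binomial fruit set per cross, negative
  binomial seeds per fruit (field seed counts are overdispersed relative
  to Poisson), and binomial germination per replicate dish (default
  12 replicates x 40 seeds);
* floral morphometrics are multivariate normal per species, truncated
  below at a small positive length.

A single global seed fans out deterministically to one independent
stream per simulated table via ``numpy`` ``SeedSequence`` spawning, so
each table is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenology import PhenologySeries

__all__ = [
    "GaussianPeak",
    "PhenologyParams",
    "PairCross",
    "CrossingParams",
    "MorphologyParams",
    "simulate_phenology",
    "simulate_crosses",
    "simulate_morphology",
    "true_ri",
]

_TRUNCATION_MM = 0.01  # floral traits are physical lengths; keep them positive


@dataclass(frozen=True)
class GaussianPeak:
    """One flowering bump: day of peak, width (sd, days), peak probability."""

    day: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if not 0 <= self.amplitude <= 1:
            raise ValueError("peak amplitude must lie in [0, 1]")


@dataclass(frozen=True)
class PhenologyParams:
    """Flowering-schedule parameters for a set of species in one or more seasons.

    ``species`` maps species id -> (n_sampled, peaks); the same schedule
    shape is reused each season (interannual noise comes from the
    binomial census sampling).  ``season_starts`` maps season id -> ISO
    start date, letting a season span the calendar-year boundary.
    """

    species: Mapping[str, tuple[int, tuple[GaussianPeak, ...]]]
    season_starts: Mapping[str, str]
    season_length: int = 280
    census_interval: int = 14

    def __post_init__(self):
        if self.census_interval >= self.season_length:
            raise ValueError("census_interval must be shorter than the season")
        for sp, (n, peaks) in self.species.items():
            if n <= 0:
                raise ValueError(f"n_sampled must be positive for {sp!r}")
            for p in peaks:
                if not isinstance(p, GaussianPeak):
                    raise TypeError("peaks must be GaussianPeak instances")


@dataclass(frozen=True)
class PairCross:
    """Generating parameters for one directed cross."""

    fruit_prob: float
    seed_mean: float
    seed_dispersion: float
    germ_prob: float
    n_flowers: int

    def __post_init__(self):
        if not 0 <= self.fruit_prob <= 1 or not 0 <= self.germ_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.seed_mean <= 0 or self.seed_dispersion <= 0:
            raise ValueError("seed mean and dispersion must be positive")
        if self.n_flowers <= 0:
            raise ValueError("n_flowers must be positive")


@dataclass(frozen=True)
class CrossingParams:
    """Crossing design: directed (recipient, donor) -> :class:`PairCross`.

    Diagonal entries (recipient == donor) are the conspecific baselines.
    """

    pairs: Mapping[tuple[str, str], PairCross]
    n_replicates: int = 12
    seeds_per_replicate: int = 40

    def __post_init__(self):
        if self.n_replicates <= 0 or self.seeds_per_replicate <= 0:
            raise ValueError("germination design sizes must be positive")


@dataclass(frozen=True)
class MorphologyParams:
    """Per-species 4-trait multivariate-normal floral morphology (mm)."""

    species: Mapping[str, tuple[np.ndarray, np.ndarray, int]]  # mean, cov, n_flowers
    flowers_per_plant: int = 2

    def __post_init__(self):
        for sp, (mean, cov, n) in self.species.items():
            mean = np.asarray(mean, dtype=float)
            cov = np.asarray(cov, dtype=float)
            if mean.shape != (4,) or cov.shape != (4, 4):
                raise ValueError(f"{sp!r}: mean must be length 4 and covariance 4x4")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"{sp!r}: covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"{sp!r}: covariance must be positive definite")
            if n <= 0:
                raise ValueError(f"{sp!r}: n_flowers must be positive")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def flowering_probability(days: np.ndarray, peaks: Sequence[GaussianPeak]) -> np.ndarray:
    """Mixture-of-bumps flowering probability, clipped at 1."""
    days = np.asarray(days, dtype=float)
    pi = np.zeros_like(days)
    for p in peaks:
        pi += p.amplitude * np.exp(-((days - p.day) ** 2) / (2 * p.width**2))
    return np.minimum(pi, 1.0)


def simulate_phenology(params: PhenologyParams, seed: int) -> list[PhenologySeries]:
    """Binomially sampled census series for every species x season."""
    n_series = len(params.species) * len(params.season_starts)
    rngs = iter(_spawn(seed, n_series))
    days = np.arange(0, params.season_length, params.census_interval)
    out = []
    for season, start in params.season_starts.items():
        start64 = np.datetime64(start, "D")
        dates = start64 + days.astype("timedelta64[D]")
        for sp, (n_sampled, peaks) in params.species.items():
            rng = next(rngs)
            pi = flowering_probability(days, peaks)
            counts = rng.binomial(n_sampled, pi)
            out.append(PhenologySeries(
                species=sp, season=season, dates=dates,
                n_flowering=counts,
                n_sampled=np.full(days.shape, n_sampled, dtype=np.int64),
            ))
    return out


def simulate_crosses(
    params: CrossingParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulated crossing, per-fruit seed-count and germination tables.

    Returns the three raw tables in the schemas ``summarize_crosses``
    reads.  Pairs that set no fruit yield no seed or germination rows
    (the downstream stages are unobservable, as in a real experiment).
    """
    keys = sorted(params.pairs)
    rngs = dict(zip(keys, _spawn(seed, len(keys))))
    cross_rows, seed_rows, germ_rows = [], [], []
    for (rec, don) in keys:
        p = params.pairs[(rec, don)]
        rng = rngs[(rec, don)]
        fruits = int(rng.binomial(p.n_flowers, p.fruit_prob))
        cross_rows.append((rec, don, p.n_flowers, fruits))
        if fruits == 0:
            continue
        # negative binomial with mean m and size k: var = m + m^2/k
        k, m = p.seed_dispersion, p.seed_mean
        counts = rng.negative_binomial(k, k / (k + m), size=fruits)
        for i, c in enumerate(counts, 1):
            seed_rows.append((rec, don, f"{rec}x{don}_f{i}", int(c)))
        germ = rng.binomial(params.seeds_per_replicate, p.germ_prob, size=params.n_replicates)
        for i, g in enumerate(germ, 1):
            germ_rows.append((rec, don, f"r{i}", params.seeds_per_replicate, int(g)))
    crosses = pd.DataFrame(cross_rows,
                           columns=["recipient", "donor", "flowers_pollinated", "fruits_set"])
    seeds = pd.DataFrame(seed_rows, columns=["recipient", "donor", "fruit_id", "n_seeds"])
    germination = pd.DataFrame(
        germ_rows, columns=["recipient", "donor", "replicate", "seeds_sown", "seeds_germinated"]
    )
    return crosses, seeds, germination


def simulate_morphology(params: MorphologyParams, seed: int) -> pd.DataFrame:
    """Multivariate-normal floral measurements, truncated at small positive values."""
    species = sorted(params.species)
    rngs = dict(zip(species, _spawn(seed, len(species))))
    rows = []
    for sp in species:
        mean, cov, n = params.species[sp]
        draws = rngs[sp].multivariate_normal(np.asarray(mean, float),
                                             np.asarray(cov, float), size=n)
        draws = np.maximum(draws, _TRUNCATION_MM)
        for i, row in enumerate(draws):
            rows.append((sp, f"{sp}_p{i // params.flowers_per_plant + 1}",
                         f"{sp}_fl{i + 1}", *row))
    return pd.DataFrame(
        rows,
        columns=["species", "plant_id", "flower_id",
                 "corolla_length_mm", "corolla_aperture_mm",
                 "stamen_length_mm", "pistil_length_mm"],
    )


def true_ri(params: CrossingParams) -> pd.DataFrame:
    """Closed-form ground-truth postpollination indices from generating parameters.

    For each heterospecific pair with a conspecific baseline for the same
    recipient: RI = 1 - 2H/(H+C) applied to the generating fruit
    probabilities (RI_I), seed means (RI_S) and germination probabilities
    (RI_V).  Pairs whose fruit probabilities are both zero get NaN (the
    index is undefined).
    """
    rows = []
    for (rec, don), p in sorted(params.pairs.items()):
        if rec == don:
            continue
        if (rec, rec) not in params.pairs:
            raise ValueError(f"no conspecific generating parameters for recipient {rec!r}")
        con = params.pairs[(rec, rec)]
        for barrier, h, c in (
            ("RI_I", p.fruit_prob, con.fruit_prob),
            ("RI_S", p.seed_mean, con.seed_mean),
            ("RI_V", p.germ_prob, con.germ_prob),
        ):
            ri = np.nan if h + c == 0 else 1.0 - 2.0 * h / (h + c)
            rows.append((rec, don, barrier, ri))
    return pd.DataFrame(rows, columns=["recipient", "donor", "barrier", "true_ri"])
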