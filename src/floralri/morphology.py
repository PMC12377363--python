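"""Mechanical isolation from floral morphometrics.

Flower architecture can act as a premating barrier in two ways: overall
size differences make the pollinator contact anthers and stigma with
different body parts, and different placement of the reproductive organs
around the corolla aperture targets pollen to different spots even on
similarly sized flowers.  Both are scored as binary indices per species
pair:

* ``RI_MS`` (size) = 1 when the species are demonstrably distinct in
  multivariate trait space: the pairwise permutation test is significant
  after Bonferroni correction AND their PC1 score intervals
  (mean +/- 2 sd) are disjoint.  Otherwise 0 — a deliberately
  conservative call, since overlapping morphologies permit gene flow.
* ``RI_MP`` (organ position) = 1 when the two species carry their anthers
  and stigma in different arrangements (e.g. a dorsal hood vs. lateral
  triplets), else 0.

The permutation test is the distance-based multivariate ANOVA of
Anderson (PERMANOVA): the total sum of squared Euclidean distances is
partitioned into among- and within-group components,

    F = (SS_A / (a - 1)) / (SS_W / (N - a)),    r^2 = SS_A / SS_T,

and significance is assessed by randomly permuting species labels with a
seeded generator, p = (1 + #{F* >= F_obs}) / (1 + n_perm).  The
permutation unit is the flower (row).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "TRAIT_COLUMNS",
    "POSITION_CATEGORIES",
    "PermTestResult",
    "permanova",
    "pairwise_permanova",
    "pca_floral",
    "assign_mechanical_ri",
]

#: the four floral traits, all in millimetres
TRAIT_COLUMNS = (
    "corolla_length_mm",
    "corolla_aperture_mm",
    "stamen_length_mm",
    "pistil_length_mm",
)

POSITION_CATEGORIES = ("dorsal_hood", "lateral_triplets")


@dataclass(frozen=True)
class PermTestResult:
    """Result of a (pairwise or global) permutation multivariate test."""

    scope: str                       # "global" or "speciesA|speciesB"
    pseudo_f: float
    r_squared: float
    p_value: float
    p_adjusted: float
    n_permutations: int
    seed: int
    df_among: int
    df_within: int


def _validate_table(table: pd.DataFrame, traits: Sequence[str]) -> None:
    missing = [c for c in ("species", *traits) if c not in table.columns]
    if missing:
        raise ValueError(f"morphometric table is missing columns {missing}")
    vals = table[list(traits)].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("all trait values must be finite and > 0 (mm)")


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_among, SS_within) from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    return ss_total - ss_within, ss_within


def permanova(
    table: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    traits: Sequence[str] = TRAIT_COLUMNS,
    scope: str = "global",
    n_comparisons: int = 1,
) -> PermTestResult:
    """Permutation multivariate test of trait differences among species.

    Works on the Euclidean distance matrix of the raw trait values; the
    pseudo-F statistic and r^2 are invariant to uniform rescaling of the
    distances.  ``p_adjusted`` is the Bonferroni-corrected p-value
    (``min(1, p * n_comparisons)``).
    """
    _validate_table(table, traits)
    labels, codes = np.unique(table["species"].to_numpy(), return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least two species to test")
    counts = np.bincount(codes)
    if counts.min() < 2:
        lonely = labels[counts.argmin()]
        raise ValueError(f"species {lonely!r} has a single observation; cannot partition variance")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")

    X = table[list(traits)].to_numpy(dtype=float)
    n = X.shape[0]
    d2 = squareform(pdist(X, metric="euclidean")) ** 2

    ss_a, ss_w = _ss_partition(d2, codes, a)
    df_among, df_within = a - 1, n - a
    f_obs = (ss_a / df_among) / (ss_w / df_within)
    r2 = ss_a / (ss_a + ss_w)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        ss_a_p, ss_w_p = _ss_partition(d2, perm, a)
        f_p = (ss_a_p / df_among) / (ss_w_p / df_within)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(
        scope=scope,
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        p_adjusted=float(min(1.0, p * n_comparisons)),
        n_permutations=int(n_perm),
        seed=int(seed),
        df_among=df_among,
        df_within=df_within,
    )


def pairwise_permanova(
    table: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    traits: Sequence[str] = TRAIT_COLUMNS,
) -> list[PermTestResult]:
    """One permutation test per species pair, Bonferroni-corrected.

    The correction multiplies each raw p by the number of pairwise
    comparisons actually performed.  Per-pair permutation streams are
    spawned deterministically from ``seed``.
    """
    _validate_table(table, traits)
    species = sorted(table["species"].unique())
    pairs = list(combinations(species, 2))
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(pairs), 1)) % (2**31)
    results = []
    for (sa, sb), s in zip(pairs, child_seeds):
        sub = table[table["species"].isin([sa, sb])]
        results.append(
            permanova(sub, n_perm=n_perm, seed=int(s), traits=traits,
                      scope=f"{sa}|{sb}", n_comparisons=len(pairs))
        )
    return results


def pca_floral(
    table: pd.DataFrame, traits: Sequence[str] = TRAIT_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the standardized (unit-variance) floral traits.

    Returns
    -------
    scores : DataFrame
        Per-flower component scores, with the ``species`` column retained.
    loadings : DataFrame
        Orthonormal component loadings (traits x components).
    explained : ndarray
        Explained-variance fractions, summing to 1.
    """
    _validate_table(table, traits)
    if len(table) < 3:
        raise ValueError("PCA needs at least three flowers")
    X = table[list(traits)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"zero-variance trait(s): {flat}; cannot standardize")
    Z = (X - X.mean(axis=0)) / sd
    k = min(len(traits), len(table))
    pca = PCA(n_components=k)
    comp = pca.fit_transform(Z)
    names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(comp, columns=names, index=table.index)
    scores.insert(0, "species", table["species"].to_numpy())
    loadings = pd.DataFrame(pca.components_.T, index=list(traits), columns=names)
    return scores, loadings, pca.explained_variance_ratio_.copy()


def _pc1_intervals(scores: pd.DataFrame) -> dict[str, tuple[float, float]]:
    out = {}
    for sp, g in scores.groupby("species"):
        m, s = g["PC1"].mean(), g["PC1"].std(ddof=1)
        out[sp] = (m - 2 * s, m + 2 * s)
    return out


def assign_mechanical_ri(
    table: pd.DataFrame,
    positions: Mapping[str, str] | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    traits: Sequence[str] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Binary size (RI_MS) and organ-position (RI_MP) indices per species pair.

    ``RI_MS = 1`` requires both a significant Bonferroni-corrected pairwise
    permutation test and disjoint PC1 mean +/- 2 sd intervals — the
    operational version of "clearly separated in multivariate space".
    ``RI_MP = 1`` whenever the two species' anther/stigma arrangements
    differ.  Both indices are symmetric; the returned long DataFrame has
    one row per unordered pair with columns
    ``species_a, species_b, ri_ms, ri_mp, p_adjusted, pc1_disjoint``.
    """
    if isinstance(positions, pd.DataFrame):
        positions = dict(zip(positions["species"], positions["position_category"]))
    species = sorted(table["species"].unique())
    for sp in species:
        if sp not in positions:
            raise ValueError(f"missing position category for species {sp!r}")
        if positions[sp] not in POSITION_CATEGORIES:
            raise ValueError(
                f"unknown position category {positions[sp]!r} for {sp!r}; "
                f"expected one of {POSITION_CATEGORIES}"
            )
    tests = {tuple(t.scope.split("|")): t
             for t in pairwise_permanova(table, n_perm=n_perm, seed=seed, traits=traits)}
    scores, _, _ = pca_floral(table, traits=traits)
    intervals = _pc1_intervals(scores)

    rows = []
    for sa, sb in combinations(species, 2):
        t = tests[(sa, sb)]
        lo_a, hi_a = intervals[sa]
        lo_b, hi_b = intervals[sb]
        disjoint = hi_a < lo_b or hi_b < lo_a
        ri_ms = int(t.p_adjusted <= alpha and disjoint)
        ri_mp = int(positions[sa] != positions[sb])
        rows.append((sa, sb, ri_ms, ri_mp, t.p_adjusted, disjoint))
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "ri_ms", "ri_mp", "p_adjusted", "pc1_disjoint"],
    )
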