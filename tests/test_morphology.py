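"""Mechanical isolation: permutation test, PCA, binary index assignment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

from floralri import assign_mechanical_ri, pairwise_permanova, pca_floral, permanova
from floralri.datasets import werauhia_positions
from floralri.morphology import TRAIT_COLUMNS, _ss_partition


def trait_table(groups, rng=None):
    """Build a measurement table from {species: (mean, sd, n)} specs."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for sp, (mean, sd, n) in groups.items():
        X = rng.normal(mean, sd, size=(n, 4)).clip(min=0.1)
        for i, r in enumerate(X):
            rows.append((sp, f"{sp}p{i}", f"{sp}f{i}", *r))
    return pd.DataFrame(rows, columns=["species", "plant_id", "flower_id", *TRAIT_COLUMNS])


class TestPermanova:
    def test_null_data_gives_small_r2_and_moderate_p(self):
        t = trait_table({"A": (20, 2, 40), "B": (20, 2, 40)})
        res = permanova(t, n_perm=199, seed=1)
        assert res.r_squared < 0.05
        assert res.p_value > 0.05

    def test_extreme_separation_hits_p_floor(self):
        t = trait_table({"A": (10, 0.5, 10), "B": (60, 0.5, 10)})
        res = permanova(t, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared > 0.95

    def test_sampled_p_matches_exhaustive_enumeration(self):
        """n = 6, two groups of 3: compare the sampled permutation p with
        the exact p over all C(6,3) = 20 label partitions."""
        t = trait_table({"A": (18, 3, 3), "B": (24, 3, 3)}, np.random.default_rng(5))
        res = permanova(t, n_perm=999, seed=2)

        X = t[list(TRAIT_COLUMNS)].to_numpy()
        d2 = squareform(pdist(X)) ** 2

        def f_stat(codes):
            ss_a, ss_w = _ss_partition(d2, codes, 2)
            return (ss_a / 1) / (ss_w / 4)

        obs = f_stat(np.array([0, 0, 0, 1, 1, 1]))
        fs = []
        for idx in combinations(range(6), 3):
            codes = np.ones(6, dtype=int)
            codes[list(idx)] = 0
            fs.append(f_stat(codes))
        exact_p = np.mean([f >= obs - 1e-12 for f in fs])
        # Monte-Carlo error of p over 999 draws
        mc_err = 3 * np.sqrt(exact_p * (1 - exact_p) / 999) + 1e-3
        assert res.p_value == pytest.approx(exact_p, abs=mc_err)

    def test_pseudo_f_matches_skbio_oracle(self):
        """Independent cross-check of the pseudo-F statistic against
        scikit-bio's distance-based implementation."""
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        t = trait_table({"A": (20, 3, 8), "B": (26, 3, 9), "C": (33, 3, 7)})
        res = permanova(t, n_perm=99, seed=0)
        dm = skbio_dist.DistanceMatrix(squareform(pdist(t[list(TRAIT_COLUMNS)].to_numpy())))
        ref = skbio_dist.permanova(dm, t["species"].to_numpy(), permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_statistics_invariant_to_uniform_scaling_and_relabeling(self):
        t = trait_table({"A": (20, 2, 6), "B": (28, 2, 6)})
        res = permanova(t, n_perm=99, seed=3)
        t2 = t.copy()
        t2[list(TRAIT_COLUMNS)] *= 5.0
        t2["species"] = t2["species"].map({"A": "X", "B": "Y"})
        res2 = permanova(t2, n_perm=99, seed=3)
        assert res2.pseudo_f == pytest.approx(res.pseudo_f)
        assert res2.r_squared == pytest.approx(res.r_squared)
        assert res2.p_value == res.p_value

    def test_single_observation_group_rejected(self):
        t = trait_table({"A": (20, 2, 5), "B": (25, 2, 1)})
        with pytest.raises(ValueError, match="single observation"):
            permanova(t, n_perm=99, seed=0)


class TestPairwise:
    def test_all_pairs_tested_with_bonferroni(self, werauhia_morphology):
        results = pairwise_permanova(werauhia_morphology, n_perm=999, seed=4)
        assert len(results) == comb(4, 2)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 6))
        # clearly distinct species: every raw p at the floor -> adjusted 0.006
        assert all(r.p_adjusted == pytest.approx(0.006) for r in results)

    def test_adjusted_p_capped_at_one(self):
        t = trait_table({"A": (20, 3, 10), "B": (20, 3, 10), "C": (20, 3, 10),
                         "D": (20, 3, 10)})
        results = pairwise_permanova(t, n_perm=199, seed=6)
        assert all(r.p_adjusted <= 1.0 for r in results)
        assert any(r.p_adjusted == 1.0 for r in results)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, werauhia_morphology):
        _, _, explained = pca_floral(werauhia_morphology)
        assert explained.sum() == pytest.approx(1.0)

    def test_collinear_data_loads_on_first_component(self):
        base = np.linspace(1, 3, 30)
        t = pd.DataFrame({
            "species": "A", "plant_id": "p", "flower_id": [f"f{i}" for i in range(30)],
            "corolla_length_mm": 10 * base, "corolla_aperture_mm": 2 * base,
            "stamen_length_mm": 11 * base, "pistil_length_mm": 12 * base,
        })
        _, _, explained = pca_floral(t)
        assert explained[0] == pytest.approx(1.0)

    def test_full_rank_scores_preserve_standardized_distances(self, werauhia_morphology):
        scores, loadings, _ = pca_floral(werauhia_morphology)
        X = werauhia_morphology[list(TRAIT_COLUMNS)].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(
            pdist(scores[["PC1", "PC2", "PC3", "PC4"]].to_numpy()), pdist(Z), atol=1e-8
        )
        # loadings are orthonormal
        np.testing.assert_allclose(loadings.to_numpy().T @ loadings.to_numpy(),
                                   np.eye(4), atol=1e-8)

    def test_zero_variance_trait_named_in_error(self):
        t = trait_table({"A": (20, 2, 10)})
        t["pistil_length_mm"] = 30.0
        with pytest.raises(ValueError, match="pistil_length_mm"):
            pca_floral(t)


class TestMechanicalAssignment:
    def test_study_like_groups_recover_published_pattern(self, werauhia_morphology):
        """RI_MS = 1 exactly for pairs crossing the large/small flower
        boundary; RI_MP = 1 exactly for pairs involving the lateral-
        triplet species."""
        mech = assign_mechanical_ri(werauhia_morphology, werauhia_positions(), seed=8)
        mech = mech.set_index(["species_a", "species_b"])
        large, small = {"Wa", "Wn"}, {"Wp", "Ws"}
        for (a, b), row in mech.iterrows():
            crosses_boundary = (a in large) != (b in large)
            assert row["ri_ms"] == int(crosses_boundary), (a, b)
            assert row["ri_mp"] == int("Ws" in (a, b)), (a, b)

    def test_duplicated_species_under_two_labels_is_no_barrier(self):
        rng = np.random.default_rng(9)
        t = trait_table({"A": (20, 2, 15)}, rng)
        t2 = t.copy()
        t2["species"] = "B"
        both = pd.concat([t, t2], ignore_index=True)
        mech = assign_mechanical_ri(both, {"A": "dorsal_hood", "B": "dorsal_hood"}, seed=9)
        assert mech["ri_ms"].item() == 0
        assert mech["ri_mp"].item() == 0

    def test_symmetric_and_idempotent(self, werauhia_morphology):
        kw = dict(positions=werauhia_positions(), seed=8)
        first = assign_mechanical_ri(werauhia_morphology, **kw)
        second = assign_mechanical_ri(werauhia_morphology, **kw)
        pd.testing.assert_frame_equal(first, second)
        # one row per unordered pair encodes symmetry by construction
        assert len(first) == comb(4, 2)

    def test_missing_position_category_rejected(self, werauhia_morphology):
        with pytest.raises(ValueError, match="position category"):
            assign_mechanical_ri(werauhia_morphology, {"Wa": "dorsal_hood"}, seed=8)
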