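"""Temporal isolation: alignment, H/C kernel, index and multi-season mean."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floralri import (
    PhenologySeries,
    TemporalRI,
    align_censuses,
    coflowering_exposure,
    phenology_ri_table,
    ri_phenology,
    seasonal_mean_ri,
)
from floralri.errors import NoFloweringError, SeasonMismatchError


class TestAlignment:
    def test_identical_grids_keep_row_count(self, make_series):
        a = make_series("A", [5, 0, 3])
        b = make_series("B", [1, 2, 3])
        assert len(align_censuses(a, b)) == 3

    def test_union_with_implicit_zeros(self, make_series):
        a = make_series("A", [5, 2])                      # d1, d2
        b = make_series("B", [2, 3], start="2020-01-15")  # d2, d3
        out = align_censuses(a, b)
        assert len(out) == 3
        assert out.loc[2, "p_a"] == 0.0   # A absent on d3
        assert out.loc[0, "p_b"] == 0.0   # B absent on d1

    def test_proportions_are_count_over_sampled(self, make_series):
        a = make_series("A", [5, 0], n_sampled=100)
        out = align_censuses(a, make_series("B", [0, 0]))
        assert out["p_a"].tolist() == [0.05, 0.0]

    def test_cross_season_comparison_rejected(self, make_series):
        a = make_series("A", [1], season="s1")
        b = make_series("B", [1], season="s2")
        with pytest.raises(SeasonMismatchError):
            align_censuses(a, b)

    def test_series_validation(self):
        dates = np.array(["2020-01-01", "2020-01-15"], dtype="datetime64[D]")
        with pytest.raises(ValueError, match="exceed"):
            PhenologySeries("A", "s1", dates, [5, 5], [4, 10])
        with pytest.raises(ValueError, match="increasing"):
            PhenologySeries("A", "s1", dates[[0, 0]], [1, 1], [10, 10])
        with pytest.raises(ValueError, match="at least one"):
            PhenologySeries("A", "s1", dates[:0], [], [])


class TestCofloweringKernel:
    def test_disjoint_schedules(self, make_series):
        f = make_series("F", [10, 0, 0])
        o = make_series("O", [0, 0, 10])
        H, C = coflowering_exposure(f, o)
        assert H == 0
        assert C == pytest.approx(0.1)

    def test_identical_schedules_give_equal_exposures(self, make_series):
        f = make_series("F", [40, 20])
        o = make_series("O", [40, 20])
        H, C = coflowering_exposure(f, o)
        assert H == pytest.approx(C)

    def test_hand_computed_example(self, make_series):
        # p_f = [0.4, 0.2], p_o = [0.4, 0.0]:
        # H = 0.4*0.4/0.8 = 0.2 ; C = 0.4*0.4/0.8 + 0.2 = 0.4
        f = make_series("F", [40, 20])
        o = make_series("O", [40, 0])
        H, C = coflowering_exposure(f, o)
        assert H == pytest.approx(0.2)
        assert C == pytest.approx(0.4)

    def test_focal_never_flowering_is_an_error(self, make_series):
        with pytest.raises(NoFloweringError):
            coflowering_exposure(make_series("F", [0, 0]), make_series("O", [5, 5]))

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=12))
    @settings(deadline=None)
    def test_matches_per_date_accumulation_oracle(self, counts):
        nf = np.array([c[0] for c in counts])
        no = np.array([c[1] for c in counts])
        if not nf.any():
            return
        dates = np.datetime64("2020-01-01") + np.arange(len(counts)) * np.timedelta64(7, "D")
        f = PhenologySeries("F", "s", dates, nf, np.full(len(counts), 50))
        o = PhenologySeries("O", "s", dates, no, np.full(len(counts), 50))
        H, C = coflowering_exposure(f, o)
        # brute-force date-by-date loop
        Hb = Cb = 0.0
        for a, b in zip(nf / 50, no / 50):
            if a + b > 0:
                Hb += a * b / (a + b)
                Cb += a * a / (a + b)
        assert H == pytest.approx(Hb)
        assert C == pytest.approx(Cb)


class TestTemporalIndex:
    def test_disjoint_gives_complete_isolation(self, make_series):
        r = ri_phenology(make_series("F", [10, 0]), make_series("O", [0, 10]))
        assert r.ri == pytest.approx(1.0)

    def test_identical_gives_no_barrier(self, make_series):
        r = ri_phenology(make_series("F", [30, 10]), make_series("O", [30, 10]))
        assert r.ri == pytest.approx(0.0)

    def test_closed_form_on_hand_example(self, make_series):
        # H = 0.2, C = 0.4 -> ri = 1 - 0.4/0.6 = 1/3
        r = ri_phenology(make_series("F", [40, 20]), make_series("O", [40, 0]))
        assert r.ri == pytest.approx(1 / 3)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)),
                    min_size=1, max_size=10),
           st.integers(2, 7))
    @settings(deadline=None)
    def test_bounded_and_sample_size_invariant(self, counts, factor):
        nf = np.array([c[0] for c in counts])
        no = np.array([c[1] for c in counts])
        if not nf.any():
            return
        dates = np.datetime64("2020-01-01") + np.arange(len(counts)) * np.timedelta64(14, "D")
        ns = np.full(len(counts), 30)
        f = PhenologySeries("F", "s", dates, nf, ns)
        o = PhenologySeries("O", "s", dates, no, ns)
        ri = ri_phenology(f, o).ri
        assert -1 <= ri <= 1
        # rescaling counts and sample sizes together preserves proportions
        f2 = PhenologySeries("F", "s", dates, nf * factor, ns * factor)
        assert ri_phenology(f2, o).ri == pytest.approx(ri)

    def test_more_heterospecific_flowering_never_raises_ri(self, make_series):
        f = make_series("F", [30, 10, 5])
        lo = ri_phenology(f, make_series("O", [5, 0, 0])).ri
        hi = ri_phenology(f, make_series("O", [25, 0, 0])).ri
        assert hi <= lo


class TestSeasonalMean:
    def test_single_season_passthrough(self):
        r = TemporalRI("F", "O", "s1", 0.1, 0.3, 0.5)
        assert seasonal_mean_ri([r]).ri == 0.5

    def test_arithmetic_mean(self):
        rs = [TemporalRI("F", "O", "s1", 0, 1, 1.0),
              TemporalRI("F", "O", "s2", 1, 1, 0.0)]
        m = seasonal_mean_ri(rs)
        assert m.ri == pytest.approx(0.5)
        assert m.season == "mean"

    def test_empty_and_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            seasonal_mean_ri([])
        with pytest.raises(ValueError):
            seasonal_mean_ri([TemporalRI("F", "O", "s1", 0, 1, 1.0),
                              TemporalRI("F", "X", "s1", 0, 1, 1.0)])

    def test_table_drops_undefined_seasons(self, make_series):
        # F never flowers in s2: that season is excluded from F's mean
        series = [
            make_series("F", [10, 0], season="s1"),
            make_series("O", [0, 10], season="s1"),
            make_series("F", [0, 0], season="s2"),
            make_series("O", [5, 5], season="s2"),
        ]
        tab = phenology_ri_table(series)
        f_mean = tab[(tab.focal == "F") & (tab.season == "mean")]
        assert f_mean["ri"].item() == pytest.approx(1.0)
        # O flowered in both seasons, so its mean covers two seasons
        o_rows = tab[(tab.focal == "O") & (tab.season != "mean")]
        assert len(o_rows) == 2

    def test_season_spanning_year_boundary(self):
        dates = np.array(["2018-12-20", "2019-01-03", "2019-01-17"], dtype="datetime64[D]")
        f = PhenologySeries("F", "2018-2019", dates, [5, 10, 5], [50, 50, 50])
        o = PhenologySeries("O", "2018-2019", dates, [5, 10, 5], [50, 50, 50])
        assert ri_phenology(f, o).ri == pytest.approx(0.0)
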