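"""Increment pair counting, %Dev, season typing and age estimation."""

import pytest
from hypothesis import given, strategies as st

from paleowear.cementochronology import (
    BandType,
    CementumIncrement,
    CementumSeries,
    Season,
    analyze_series,
    compute_pct_dev,
    count_increment_pairs,
    estimate_age,
    parse_n_cb,
    season_of_death,
)

TB, OB = BandType.TB, BandType.OB


def series(spec, *, last_incomplete_tb=None, sid="S1"):
    """Build a series from (band, thickness) pairs, optionally + partial TB."""
    incs = [
        CementumIncrement(i + 1, band, th) for i, (band, th) in enumerate(spec)
    ]
    if last_incomplete_tb is not None:
        incs.append(CementumIncrement(len(incs) + 1, TB, last_incomplete_tb, complete=False))
    return CementumSeries(specimen_id=sid, increments=incs)


def annual(n_pairs, tb=60.0, ob=8.0):
    return [(TB, tb), (OB, ob)] * n_pairs


class TestPairCounting:
    def test_three_pairs_plus_trailing_incomplete_tb(self):
        n, trailing = count_increment_pairs(series(annual(3), last_incomplete_tb=20.0))
        assert (n, trailing) == (3, True)

    def test_thirteen_complete_pairs_ending_in_ob(self):
        n, trailing = count_increment_pairs(series(annual(13)))
        assert (n, trailing) == (13, False)

    def test_leading_ob_before_first_pair_not_counted(self):
        n, trailing = count_increment_pairs(
            series([(OB, 8.0)] + annual(3), last_incomplete_tb=21.0)
        )
        assert (n, trailing) == (3, True)

    def test_empty_series_is_unreadable(self):
        res = analyze_series(CementumSeries(specimen_id="S1"))
        assert not res.readable and res.season is Season.unknown and res.n_pairs is None

    def test_non_alternating_sequence_rejected(self):
        with pytest.raises(ValueError, match="alternating"):
            count_increment_pairs(series([(TB, 60), (TB, 55)]))


class TestPctDev:
    def test_half_grown_band(self):
        s = series([(TB, 60), (OB, 8), (TB, 60), (OB, 8), (TB, 60), (OB, 8)], last_incomplete_tb=30)
        assert compute_pct_dev(s) == (50.0, False)

    def test_fully_grown_band_is_100(self):
        s = series(annual(2), last_incomplete_tb=60)
        assert compute_pct_dev(s) == (100.0, False)

    def test_overgrown_band_clamped_with_flag(self):
        s = series([(TB, 40), (OB, 8), (TB, 60), (OB, 8)], last_incomplete_tb=50)
        assert compute_pct_dev(s) == (100.0, False)  # 100 * 50/50 exactly
        s2 = series([(TB, 50), (OB, 8), (TB, 50), (OB, 8)], last_incomplete_tb=55)
        assert compute_pct_dev(s2) == (100.0, True)

    def test_requires_trailing_incomplete_tb(self):
        with pytest.raises(ValueError):
            compute_pct_dev(series(annual(2)))

    @given(st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, scale):
        base = series([(TB, 60), (OB, 8), (TB, 55), (OB, 7)], last_incomplete_tb=23)
        scaled = series(
            [(TB, 60 * scale), (OB, 8 * scale), (TB, 55 * scale), (OB, 7 * scale)],
            last_incomplete_tb=23 * scale,
        )
        assert compute_pct_dev(scaled)[0] == pytest.approx(compute_pct_dev(base)[0])


class TestSeasonOfDeath:
    @pytest.mark.parametrize(
        "band,pct,season",
        [
            (TB, 35.75, Season.good_middle),
            (TB, 10.39, Season.good_beginning),
            (TB, 92.84, Season.good_end),
            (OB, None, Season.bad),
            (TB, 33.3, Season.good_beginning),
            (TB, 33.35, Season.good_middle),  # rounds half-up to 33.4
            (TB, 66.6, Season.good_middle),
            (TB, 66.7, Season.good_end),
        ],
    )
    def test_category_bounds(self, band, pct, season):
        assert season_of_death(band, pct) is season

    def test_tb_without_pct_dev_is_unknown(self):
        assert season_of_death(TB, None) is Season.unknown

    def test_published_rows_all_reproduce(self, table2_rows):
        from paleowear.cementochronology import SEASON_LABELS

        determined = [r for r in table2_rows if r.determined]
        assert len(determined) == 17
        for row in determined:
            got = season_of_death(row.lcb, row.pct_dev)
            assert SEASON_LABELS[got] == row.season, row.specimen_id
        seasons = [season_of_death(r.lcb, r.pct_dev) for r in determined]
        assert seasons.count(Season.good_beginning) == 6
        assert seasons.count(Season.good_middle) == 4
        assert seasons.count(Season.good_end) == 2
        assert seasons.count(Season.bad) == 5


class TestAge:
    def test_trailing_tb_widens_to_half_open_interval(self):
        est = estimate_age(3, True, "m2 L", "cervus", {("cervus", "m2"): 1.25})
        assert (est.low, est.high) == (4.25, 5.25)
        assert est.is_interval

    def test_no_pairs_no_trailing_gives_eruption_age(self):
        est = estimate_age(0, False, "M1 R", "cervus", {("cervus", "M1"): 0.5})
        assert (est.low, est.high) == (0.5, 0.5)

    def test_unknown_tooth_errors_naming_it(self):
        with pytest.raises(ValueError, match="m4"):
            estimate_age(2, False, "m4", "cervus", {("cervus", "m2"): 1.25})
        with pytest.raises(ValueError, match="m3"):
            estimate_age(2, False, "m3 L", "cervus", {("cervus", "m2"): 1.25})


class TestBandCountText:
    @pytest.mark.parametrize(
        "text,pairs,lead,tb,at_least",
        [
            ("5 (+TB)", 5, False, True, False),
            ("OB + 3 (+TB)", 3, True, True, False),
            ("13", 13, False, False, False),
            ("9 (+TB) (at least)", 9, False, True, True),
        ],
    )
    def test_printed_notation_parses(self, text, pairs, lead, tb, at_least):
        parsed = parse_n_cb(text)
        assert (parsed.n_pairs, parsed.leading_ob, parsed.trailing_tb, parsed.at_least) == (
            pairs,
            lead,
            tb,
            at_least,
        )

    def test_empty_cell_is_none_and_garbage_rejected(self):
        assert parse_n_cb("") is None
        assert parse_n_cb("—") is None
        with pytest.raises(ValueError):
            parse_n_cb("TB + OB?")
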