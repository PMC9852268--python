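"""Event-based labelers: probability maps, AGIS/CIGTS scores, sustained-change
rules, and brute-force oracle equivalence for the GPA window logic."""

import datetime as dt

import numpy as np
import pytest

from conftest import make_exam, make_series
from vfprog.core import seeing_td
from vfprog.events import (NormativeCutoffs, ThresholdTable, agis_flag,
                           agis_score, cigts_flag, cigts_score, gpa_flag,
                           load_agis_tables, td_probability_level,
                           validate_agis_tables)
from vfprog.grid import grid_coordinates, seeing_indices

STD_CUTOFFS = NormativeCutoffs(np.tile([-2.0, -2.5, -2.8, -3.1], (52, 1)))


def td54(values_by_coord=None, fill=0.0):
    """54-vector with values set at given (x, y) coordinates."""
    td = np.full(54, float(fill))
    if values_by_coord:
        coords = {tuple(c): i for i, c in enumerate(grid_coordinates())}
        for xy, v in values_by_coord.items():
            td[coords[xy]] = v
    return td


class TestProbabilityLevels:
    def test_normal_field_level_zero(self):
        e = make_exam(dt.date(2020, 1, 1), td=0.0)
        assert np.all(td_probability_level(e, STD_CUTOFFS) == 0)

    def test_deep_field_level_four(self):
        e = make_exam(dt.date(2020, 1, 1), td=-30.0)
        assert np.all(td_probability_level(e, STD_CUTOFFS) == 4)

    def test_levels_monotone_in_depth(self):
        levels = []
        for v in (0.0, -2.2, -2.6, -3.0, -3.5):
            e = make_exam(dt.date(2020, 1, 1), td=v)
            levels.append(td_probability_level(e, STD_CUTOFFS)[0])
        assert levels == sorted(levels)
        assert levels == [0, 1, 2, 3, 4]

    def test_cutoff_shape_validated(self):
        with pytest.raises(ValueError):
            NormativeCutoffs(np.zeros((52, 3)))
        with pytest.raises(ValueError, match="non-increasing"):
            NormativeCutoffs(np.tile([-3.0, -2.0, -2.5, -3.5], (52, 1)))


class TestAgisScore:
    def test_normal_field_scores_zero(self):
        assert agis_score(make_exam(dt.date(2020, 1, 1), td=0.0)) == 0

    def test_maximal_defect_scores_twenty(self):
        assert agis_score(make_exam(dt.date(2020, 1, 1), td=-35.0)) == 20

    def test_nasal_only_defect_capped_at_two(self):
        nasal = {(x, y): -30.0 for x in (-27, -21, -15) for y in (3, -3)}
        e = make_exam(dt.date(2020, 1, 1), td=td54(nasal))
        assert 1 <= agis_score(e) <= 2

    def test_three_site_cluster_depth_grading(self):
        # a 3-site contiguous upper cluster: base 1 + depth increments
        sites = [(3, 9), (9, 9), (3, 15)]
        for depth, expected in ((-10.0, 1), (-17.0, 3), (-21.0, 4)):
            e = make_exam(dt.date(2020, 1, 1), td=td54({s: depth for s in sites}))
            assert agis_score(e) == expected

    def test_isolated_pair_scores_zero(self):
        e = make_exam(dt.date(2020, 1, 1), td=td54({(3, 9): -30.0, (9, 21): -30.0}))
        assert agis_score(e) == 0

    def test_scores_integer_in_range(self, rng):
        for _ in range(25):
            e = make_exam(dt.date(2020, 1, 1), td=rng.uniform(-35, 5, 54))
            s = agis_score(e)
            assert isinstance(s, int) and 0 <= s <= 20

    def test_deepening_never_decreases_score(self, rng):
        td = rng.uniform(-20, 2, 54)
        e = make_exam(dt.date(2020, 1, 1), td=td)
        deeper = td.copy()
        deeper[rng.integers(0, 54, 10)] -= rng.uniform(1, 10, 10)
        e2 = make_exam(dt.date(2020, 1, 1), td=deeper)
        assert agis_score(e2) >= agis_score(e)

    def test_structural_validation(self):
        doc = load_agis_tables()
        bad = {**doc, "sites": doc["sites"][:-1]}
        with pytest.raises(ValueError, match="52"):
            validate_agis_tables(bad)
        bad_caps = {**doc, "nasal_rules": {**doc["nasal_rules"], "cap": 3}}
        with pytest.raises(ValueError, match="caps"):
            validate_agis_tables(bad_caps)


# 2 x 4 block of mutually clustered points (each has >= 2 in-block neighbors)
BLOCK8 = [(-9, 3), (-3, 3), (3, 3), (9, 3), (-9, 9), (-3, 9), (3, 9), (9, 9)]


class TestCigtsScore:
    def test_normal_field_zero(self):
        assert cigts_score(make_exam(dt.date(2020, 1, 1), td=0.0), STD_CUTOFFS) == 0.0

    def test_maximal_defect_scores_twenty(self):
        e = make_exam(dt.date(2020, 1, 1), td=-30.0)
        assert cigts_score(e, STD_CUTOFFS) == pytest.approx(20.0)
        assert pytest.approx(52 * 4 / 10.4) == 20.0

    def test_isolated_deep_point_weighs_zero(self):
        e = make_exam(dt.date(2020, 1, 1), td=td54({(3, 9): -30.0}))
        assert cigts_score(e, STD_CUTOFFS) == 0.0

    def test_cluster_scores_by_size(self):
        e8 = make_exam(dt.date(2020, 1, 1), td=td54({s: -30.0 for s in BLOCK8}))
        assert cigts_score(e8, STD_CUTOFFS) == pytest.approx(8 * 4 / 10.4)
        e7 = make_exam(dt.date(2020, 1, 1),
                       td=td54({s: -30.0 for s in BLOCK8[:-1]}))
        assert cigts_score(e7, STD_CUTOFFS) == pytest.approx(7 * 4 / 10.4)

    def test_deepening_never_decreases_score(self, rng):
        td = rng.uniform(-15, 2, 54)
        e = make_exam(dt.date(2020, 1, 1), td=td)
        deeper = td - rng.uniform(0, 5, 54)
        e2 = make_exam(dt.date(2020, 1, 1), td=deeper)
        assert cigts_score(e2, STD_CUTOFFS) >= cigts_score(e, STD_CUTOFFS)


def _gpa_series(qualifying_per_exam, n_points):
    """Baseline-zero series; listed follow-ups drop n_points points by 5 dB."""
    n = 2 + len(qualifying_per_exam)
    td = np.zeros((n, 54))
    pts = seeing_indices()[:n_points]
    for k, hit in enumerate(qualifying_per_exam):
        if hit:
            td[2 + k, pts] = -5.0
    return make_series(td)


THRESH = ThresholdTable(np.full(52, -2.0))


def gpa_oracle(series, thresholds, min_points=3, run=3):
    """Brute-force enumeration of all length-3 follow-up windows."""
    from vfprog.core import baseline_exam
    base = seeing_td(baseline_exam(series))
    flags = [int(np.sum(seeing_td(e) - base <= thresholds.thresholds)) >= min_points
             for e in series.exams[2:]]
    return any(all(flags[k:k + run]) for k in range(len(flags) - run + 1))


class TestGpaFlag:
    @pytest.mark.parametrize("pattern,n_points,expected", [
        ([1, 1, 1], 3, True),
        ([1, 1, 0, 1], 3, False),       # only 2 consecutive
        ([1, 1, 1], 2, False),          # only 2 points
        ([0, 1, 1, 1, 0], 3, True),
        ([1, 0, 1, 0, 1], 3, False),
    ])
    def test_sustained_rule(self, pattern, n_points, expected):
        s = _gpa_series(pattern, n_points)
        assert gpa_flag(s, THRESH).worsening is expected
        assert gpa_oracle(s, THRESH) is expected

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 12))
            td = rng.normal(-1, 3, size=(n, 54))
            s = make_series(td)
            assert gpa_flag(s, THRESH).worsening == gpa_oracle(s, THRESH)

    def test_same_points_mode_stricter(self, rng):
        for _ in range(20):
            td = rng.normal(-1, 3, size=(8, 54))
            s = make_series(td)
            strict = gpa_flag(s, THRESH, same_points=True).worsening
            loose = gpa_flag(s, THRESH, same_points=False).worsening
            assert not (strict and not loose)

    def test_needs_five_exams(self):
        with pytest.raises(ValueError):
            gpa_flag(make_series(np.zeros((4, 54))), THRESH)


def _score_series(increase_pattern, site_block, depth=-30.0):
    """Baseline-zero series; follow-ups with a defect block when marked."""
    n = 2 + len(increase_pattern)
    td = np.zeros((n, 54))
    coords = {tuple(c): i for i, c in enumerate(grid_coordinates())}
    idx = [coords[s] for s in site_block]
    for k, hit in enumerate(increase_pattern):
        if hit:
            td[2 + k, idx] = depth
    return make_series(td)


class TestAgisFlag:
    # 3-site cluster at -21 dB scores 4 (base 1 + depth 12/16/20)
    SITES = [(3, 9), (9, 9), (3, 15)]

    def test_sustained_increase_of_four_flags(self):
        s = _score_series([1, 1, 1], self.SITES, depth=-21.0)
        assert agis_flag(s).worsening

    def test_interrupted_increase_not_flagged(self):
        s = _score_series([1, 1, 0, 1, 1], self.SITES, depth=-21.0)
        assert not agis_flag(s).worsening

    def test_increase_of_three_not_flagged(self):
        s = _score_series([1, 1, 1], self.SITES, depth=-17.0)  # score 3
        assert not agis_flag(s).worsening
        assert agis_flag(s).trace["increases"] == [3.0, 3.0, 3.0]


class TestCigtsFlag:
    def test_sustained_increase_of_three_flags(self):
        s = _score_series([1, 1, 1], BLOCK8)  # 8 * 4 / 10.4 = 3.08
        call = cigts_flag(s, STD_CUTOFFS)
        assert call.worsening
        assert call.trace["increases"][0] == pytest.approx(8 * 4 / 10.4)

    def test_unsustained_increase_not_flagged(self):
        s = _score_series([1, 1, 0, 1], BLOCK8)
        assert not cigts_flag(s, STD_CUTOFFS).worsening

    def test_increase_below_three_not_flagged(self):
        s = _score_series([1, 1, 1], BLOCK8[:-1])  # 7 * 4 / 10.4 = 2.69
        assert not cigts_flag(s, STD_CUTOFFS).worsening

    def test_flat_scores_not_flagged(self):
        s = make_series(np.zeros((8, 54)))
        assert not cigts_flag(s, STD_CUTOFFS).worsening
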