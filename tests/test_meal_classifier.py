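"""Eating-occasion classification rules, the worked fixture oracle and the
classifier's structural invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealscope.meal_classifier import (EXCLUDED, EatingOccasion, classify_day,
                                       classify_occasions, classify_records,
                                       drop_water_only, merge_overlaps,
                                       meal_descriptives,
                                       resolve_multiple_entries)
from mealscope.records_model import FoodRecordLine, records_frame
from mealscope.synthetic_data import generate_worked_fixtures


def day_frame(rows):
    """rows: (section, start, end, code, amount) for one participant-day."""
    lines = [FoodRecordLine("P", 1, s, a, b, code, amt)
             for s, a, b, code, amt in rows]
    return records_frame(lines)


def occ(label, start, end, order=0):
    return EatingOccasion("P", 1, label, start, end, line_idx=[order],
                          merged_from=[label], order=order)


class TestWaterOnly:
    def test_water_only_occasion_removed(self, table):
        day = day_frame([("snack", 600, 605, "wat01", 200.0)])
        assert classify_day(day, table) == []

    def test_water_plus_food_retained_whole(self, table):
        day = day_frame([("breakfast", 420, 440, "wat01", 200.0),
                         ("breakfast", 420, 440, "ric01", 150.0)])
        (res,) = classify_day(day, table)
        assert res.label == "breakfast" and len(res.line_idx) == 2

    def test_empty_input(self, table):
        assert drop_water_only([], day_frame([]).iloc[0:0], table) == []


class TestMultipleEntries:
    def test_second_breakfast_entry_becomes_snack(self):
        occasions = [occ("breakfast", 420, 440, 0), occ("breakfast", 600, 610, 1)]
        resolved = resolve_multiple_entries(occasions)
        assert [o.label for o in sorted(resolved, key=lambda o: o.start_time)] \
            == ["breakfast", "snack"]

    def test_single_entries_unchanged(self):
        occasions = [occ("breakfast", 420, 440), occ("lunch", 750, 770, 1)]
        assert [o.label for o in resolve_multiple_entries(occasions)] \
            == ["breakfast", "lunch"]

    def test_three_dinner_entries(self):
        occasions = [occ("dinner", 1080, 1110, 0), occ("dinner", 1260, 1280, 1),
                     occ("dinner", 1380, 1400, 2)]
        assert [o.label for o in resolve_multiple_entries(occasions)] \
            == ["dinner", "snack", "snack"]

    def test_tie_broken_by_input_order(self):
        occasions = [occ("lunch", 720, 740, 0), occ("lunch", 720, 745, 1)]
        resolved = sorted(resolve_multiple_entries(occasions), key=lambda o: o.order)
        assert [o.label for o in resolved] == ["lunch", "snack"]


class TestMergeOverlaps:
    def test_meal_snack_overlap_keeps_meal_label(self):
        merged = merge_overlaps([occ("lunch", 720, 750, 0), occ("snack", 730, 740, 1)])
        assert len(merged) == 1
        assert merged[0].label == "lunch"
        assert (merged[0].start_time, merged[0].end_time) == (720, 750)

    def test_overlap_after_earlier_same_meal_becomes_snack(self):
        # standalone merge rule: the second lunch-labelled occasion overlaps
        # a snack after lunch was already eaten
        merged = merge_overlaps([occ("lunch", 720, 740, 0),
                                 occ("lunch", 900, 920, 1),
                                 occ("snack", 905, 915, 2)])
        assert [o.label for o in merged] == ["lunch", "snack"]
        assert merged[1].end_time == 920

    def test_snack_snack_merge(self):
        merged = merge_overlaps([occ("snack", 600, 610, 0), occ("snack", 605, 615, 1)])
        assert len(merged) == 1
        assert (merged[0].label, merged[0].start_time, merged[0].end_time) \
            == ("snack", 600, 615)

    def test_boundary_touch_does_not_merge(self):
        merged = merge_overlaps([occ("lunch", 720, 740, 0), occ("snack", 740, 750, 1)])
        assert len(merged) == 2

    def test_two_distinct_mains_earlier_start_wins(self, caplog):
        with caplog.at_level("WARNING"):
            merged = merge_overlaps([occ("lunch", 720, 760, 0),
                                     occ("dinner", 740, 780, 1)])
        assert [o.label for o in merged] == ["lunch"]
        assert "overlapping" in caplog.text

    def test_transitive_merge(self):
        merged = merge_overlaps([occ("snack", 600, 612, 0),
                                 occ("snack", 610, 622, 1),
                                 occ("snack", 620, 630, 2)])
        assert len(merged) == 1
        assert (merged[0].start_time, merged[0].end_time) == (600, 630)


class TestClassifyDay:
    def test_standard_day_preserves_sections(self, table):
        day = day_frame([("breakfast", 440, 460, "ric01", 150.0),
                         ("lunch", 750, 770, "nod01", 250.0),
                         ("snack", 900, 910, "cnf01", 40.0),
                         ("dinner", 1160, 1190, "fsh01", 80.0)])
        labels = [o.label for o in classify_day(day, table)]
        assert labels == ["breakfast", "lunch", "snack", "dinner"]

    def test_all_water_day_is_empty(self, table):
        day = day_frame([("breakfast", 440, 450, "wat01", 200.0),
                         ("snack", 900, 905, "wat02", 150.0)])
        assert classify_day(day, table) == []

    def test_at_most_one_of_each_main_meal(self, table):
        day = day_frame([("breakfast", 420, 440, "ric01", 100.0),
                         ("breakfast", 600, 610, "fru01", 100.0),
                         ("lunch", 605, 620, "nod01", 200.0)])
        result = classify_day(day, table)
        mains = [o.label for o in result if o.is_main]
        assert len(mains) == len(set(mains))


class TestWorkedFixture:
    def test_fixture_matches_expectations_exactly(self, table):
        lines, expected = generate_worked_fixtures()
        occasions, line_labels = classify_records(records_frame(lines), table)
        got = (occasions[expected.columns]
               .sort_values(["participant_id", "start_time"])
               .reset_index(drop=True))
        exp = (expected.sort_values(["participant_id", "start_time"])
               .reset_index(drop=True))
        pd.testing.assert_frame_equal(got, exp)

    def test_fixture_aligned_with_occasions(self, table):
        lines, expected = generate_worked_fixtures()
        occasions, _ = classify_records(records_frame(lines), table)
        assert len(lines) > 0
        assert len(occasions) == len(expected)

    def test_water_only_lines_excluded(self, table):
        lines, _ = generate_worked_fixtures()
        frame = records_frame(lines)
        _, line_labels = classify_records(frame, table)
        water_only_idx = frame.index[(frame["participant_id"] == "WF02")
                                     & (frame["section"] == "snack")]
        assert (line_labels.loc[water_only_idx] == EXCLUDED).all()


# ---------------------------------------------------------------------------
# Structural invariants
# ---------------------------------------------------------------------------

sections = st.sampled_from(["breakfast", "lunch", "dinner", "snack"])
codes = st.sampled_from(["ric01", "fsh01", "cnf01", "neb01", "wat01"])


@st.composite
def random_day(draw):
    n = draw(st.integers(1, 10))
    # distinct start times: simultaneous starts in different sections have
    # an input-order tie-break, which order-invariance deliberately exempts
    starts = draw(st.lists(st.integers(0, 1400), min_size=n, max_size=n,
                           unique=True))
    rows = []
    for start in starts:
        dur = draw(st.integers(0, 60))
        rows.append((draw(sections), start, min(start + dur, 1439),
                     draw(codes), draw(st.integers(1, 300))))
    return day_frame(rows)


class TestInvariants:
    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(random_day())
    def test_conservation_and_uniqueness(self, table, day):
        """Every non-excluded line lands in exactly one final occasion and
        main-meal labels are unique within the day."""
        result = classify_day(day, table)
        assigned = [i for o in result for i in o.line_idx]
        assert len(assigned) == len(set(assigned))
        water = {c for c in table.codes if table.is_water_only(c)}
        # excluded lines are water lines only
        excluded = set(day.index) - set(assigned)
        assert all(day.at[i, "food_code"] in water for i in excluded)
        mains = [o.label for o in result if o.is_main]
        assert len(mains) == len(set(mains))

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(random_day())
    def test_idempotence(self, table, day):
        """Re-running the occasion pipeline on its own output changes nothing."""
        once = classify_day(day, table)
        again = classify_occasions(
            [EatingOccasion(o.participant_id, o.day_index, o.label,
                            o.start_time, o.end_time, list(o.line_idx),
                            list(o.merged_from), o.order) for o in once])
        key = lambda os: [(o.label, o.start_time, o.end_time, sorted(o.line_idx))
                          for o in os]
        assert key(again) == key(once)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(random_day(), st.randoms(use_true_random=False))
    def test_order_invariance(self, table, day, rnd):
        """Permuting input line order only permutes documented tie-breaks."""
        perm = list(day.index)
        rnd.shuffle(perm)
        shuffled = day.loc[perm].reset_index(drop=True)
        a = classify_day(day, table)
        b = classify_day(shuffled, table)
        key = lambda os: sorted((o.label, o.start_time, o.end_time, len(o.line_idx))
                                for o in os)
        assert key(a) == key(b)


class TestDescriptives:
    def test_constant_breakfast_time(self, table):
        lines = [FoodRecordLine("P", d, "breakfast", 420, 440, "ric01", 100.0)
                 for d in range(1, 5)]
        occasions, _ = classify_records(records_frame(lines), table)
        d = meal_descriptives(occasions, 4)
        assert d["start_times"]["breakfast"]["mean_start_min"] == 420
        assert d["start_times"]["breakfast"]["mean_start_clock"] == "07:00"
        assert d["meal_consumption"]["breakfast"]["pct_all_days"] == 100.0

    def test_no_snacks_gives_zero_snack_frequency(self, table):
        lines = [FoodRecordLine("P", 1, "lunch", 720, 740, "ric01", 100.0)]
        occasions, _ = classify_records(records_frame(lines), table)
        d = meal_descriptives(occasions, 4)
        assert d["snack_frequency"]["mean"] == 0.0
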