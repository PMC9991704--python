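"""Classification of diary lines into labelled eating occasions.

An *eating occasion* is any separate intake event with its own start clock
time and diary name. The classifier applies three rules, in order, within
each participant-day:

1. **Water-only exclusion** — occasions whose every food is plain water
   (tap or mineral) are dropped entirely.
2. **Multiple-entry rule** — when two or more occasions were recorded in
   the same main-meal diary section (breakfast, lunch or dinner), the
   earliest-starting one keeps the meal label and the later ones become
   snacks.
3. **Overlap merging** — occasions whose time intervals overlap are merged
   (transitively) into a single occasion spanning the union. A merge of a
   main meal with snacks keeps the meal label, unless that same meal
   already occurred earlier in the day, in which case the merged occasion
   is a snack.

Overlap is tested on half-open minute intervals: a shared boundary minute
(one occasion finishing exactly when the next starts) does not merge.

After classification each participant-day contains at most one occasion
each of breakfast, lunch and dinner, and every non-excluded diary line
belongs to exactly one occasion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records_model import (MAIN_MEALS, FoodCompositionTable, format_clock)

logger = logging.getLogger(__name__)

EXCLUDED = "excluded"


@dataclass
class EatingOccasion:
    """A labelled eating occasion (possibly merged from several entries)."""

    participant_id: str
    day_index: int
    label: str                       # breakfast | lunch | dinner | snack
    start_time: int                  # minutes since the day's midnight
    end_time: int                    # continuous axis (may exceed 1440)
    line_idx: list = field(default_factory=list)   # records-frame indices
    merged_from: list = field(default_factory=list)  # original section labels
    order: int = 0                   # input order of first member (tie-break)

    @property
    def is_main(self) -> bool:
        return self.label in MAIN_MEALS


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def group_occasions(day: pd.DataFrame) -> list[EatingOccasion]:
    """Group one participant-day's lines into candidate occasions.

    The occasion key is (diary section, start time): lines sharing both are
    one occasion even if entered apart, matching the diary convention that
    all items of an occasion carry the same clock time and name.
    """
    occasions: dict[tuple, EatingOccasion] = {}
    for order, (idx, row) in enumerate(day.iterrows()):
        key = (row["section"], int(row["start_time"]))
        end = int(row["end_time"]) + 1440 * int(bool(row.get("next_day", False)))
        occ = occasions.get(key)
        if occ is None:
            occasions[key] = EatingOccasion(
                participant_id=row["participant_id"],
                day_index=int(row["day_index"]),
                label=row["section"], start_time=int(row["start_time"]),
                end_time=end, line_idx=[idx],
                merged_from=[row["section"]], order=order)
        else:
            occ.line_idx.append(idx)
            occ.end_time = max(occ.end_time, end)
    return sorted(occasions.values(), key=lambda o: (o.start_time, o.order))


def drop_water_only(occasions: list[EatingOccasion], day: pd.DataFrame,
                    table: FoodCompositionTable) -> list[EatingOccasion]:
    """Remove occasions consisting solely of tap or mineral water."""
    water = {c for c in table.codes if table.is_water_only(c)}
    return [o for o in occasions
            if not all(day.at[i, "food_code"] in water for i in o.line_idx)]


def resolve_multiple_entries(occasions: list[EatingOccasion]) -> list[EatingOccasion]:
    """Relabel repeated main-meal entries: first keeps the meal, rest are snacks.

    Ties on start time are broken by input order (first-recorded wins).
    """
    seen: set[str] = set()
    for occ in sorted(occasions, key=lambda o: (o.start_time, o.order)):
        if occ.label in MAIN_MEALS:
            if occ.label in seen:
                occ.label = "snack"
            else:
                seen.add(occ.label)
    return occasions


def merge_overlaps(occasions: list[EatingOccasion]) -> list[EatingOccasion]:
    """Merge overlapping occasions transitively and resolve the labels.

    Label of a merged group: the single main-meal label present, unless
    that meal already occurred earlier in the day (then snack); if two
    different main meals collide, the earlier-starting one wins (logged).
    """
    occasions = sorted(occasions, key=lambda o: (o.start_time, o.order))
    groups: list[list[EatingOccasion]] = []
    for occ in occasions:
        if groups and occ.start_time < max(o.end_time for o in groups[-1]):
            groups[-1].append(occ)
        else:
            groups.append([occ])

    merged: list[EatingOccasion] = []
    earlier_mains: set[str] = set()
    for grp in groups:
        first = grp[0]
        if len(grp) == 1:
            occ = first
        else:
            occ = EatingOccasion(
                participant_id=first.participant_id,
                day_index=first.day_index,
                label="snack",
                start_time=min(o.start_time for o in grp),
                end_time=max(o.end_time for o in grp),
                line_idx=[i for o in grp for i in o.line_idx],
                merged_from=[s for o in grp for s in o.merged_from],
                order=first.order)
            mains = [o.label for o in grp if o.is_main]
            if mains:
                if len(set(mains)) > 1:
                    logger.warning(
                        "participant %s day %d: overlapping %s and %s at %s; "
                        "keeping the earlier (%s)",
                        first.participant_id, first.day_index, mains[0],
                        mains[1], format_clock(first.start_time), mains[0])
                occ.label = mains[0]  # grp is start-ordered
        if occ.is_main:
            if occ.label in earlier_mains:
                occ.label = "snack"  # same meal already recorded earlier
            else:
                earlier_mains.add(occ.label)
        merged.append(occ)
    return merged


def classify_occasions(occasions: list[EatingOccasion]) -> list[EatingOccasion]:
    """Occasion-level pipeline (multiple-entry rule, then overlap merging)."""
    return merge_overlaps(resolve_multiple_entries(occasions))


def classify_day(day: pd.DataFrame, table: FoodCompositionTable) -> list[EatingOccasion]:
    """Classify all diary lines of one participant-day.

    Returns the final occasions; lines of water-only occasions appear in no
    occasion (they are excluded from analysis).
    """
    occasions = group_occasions(day)
    occasions = drop_water_only(occasions, day, table)
    return classify_occasions(occasions)


# ---------------------------------------------------------------------------
# Population-level driver
# ---------------------------------------------------------------------------

def classify_records(records: pd.DataFrame, table: FoodCompositionTable
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Classify a whole records frame.

    Returns ``(occasion_frame, line_labels)`` where *occasion_frame* has one
    row per final occasion (participant_id, day_index, label, start, end,
    n_lines, source_sections) and *line_labels* maps every records-frame
    index to its final occasion label (or ``"excluded"`` for water-only
    lines).
    """
    line_labels = pd.Series(EXCLUDED, index=records.index, dtype=object)
    rows = []
    for (pid, day_idx), day in records.groupby(["participant_id", "day_index"], sort=True):
        for occ in classify_day(day, table):
            rows.append({"participant_id": pid, "day_index": day_idx,
                         "label": occ.label, "start_time": occ.start_time,
                         "end_time": occ.end_time, "n_lines": len(occ.line_idx),
                         "source_sections": "+".join(occ.merged_from)})
            line_labels.loc[occ.line_idx] = occ.label
    occ_frame = pd.DataFrame(
        rows, columns=["participant_id", "day_index", "label", "start_time",
                       "end_time", "n_lines", "source_sections"])
    return occ_frame, line_labels


def meal_descriptives(occasions: pd.DataFrame, n_days: int = 4) -> dict:
    """Population descriptives of meal timing and frequency.

    Start-time means/SDs are computed participant-wise first (participants
    who never consumed a meal are excluded from that meal's timing row,
    mirroring the consumer-only convention of timing statistics).
    """
    participants = occasions["participant_id"].unique()
    n = len(participants)
    out: dict = {"n_participants": n, "n_days": n_days}

    timing = {}
    for meal in MAIN_MEALS:
        sub = occasions[occasions["label"] == meal]
        per_part = sub.groupby("participant_id")["start_time"].mean()
        timing[meal] = {
            "n_consumers": int(per_part.size),
            "mean_start_min": float(per_part.mean()) if per_part.size else np.nan,
            "sd_start_min": float(per_part.std(ddof=1)) if per_part.size > 1 else np.nan,
            "mean_start_clock": (format_clock(round(per_part.mean()))
                                 if per_part.size else ""),
        }
    out["start_times"] = timing

    # days each meal was consumed, per participant
    consumption = {}
    for meal in MAIN_MEALS:
        days = (occasions[occasions["label"] == meal]
                .groupby("participant_id")["day_index"].nunique()
                .reindex(participants, fill_value=0))
        consumption[meal] = {
            "pct_all_days": float(100.0 * (days == n_days).mean()),
            "pct_never": float(100.0 * (days == 0).mean()),
            "days_distribution": days.value_counts().sort_index().to_dict(),
        }
    out["meal_consumption"] = consumption

    snacks = (occasions[occasions["label"] == "snack"]
              .groupby("participant_id").size()
              .reindex(participants, fill_value=0) / n_days)
    snack_days = (occasions[occasions["label"] == "snack"]
                  .groupby("participant_id")["day_index"].nunique()
                  .reindex(participants, fill_value=0))
    total = occasions.groupby("participant_id").size().reindex(participants, fill_value=0) / n_days
    out["snack_frequency"] = {
        "mean": float(snacks.mean()), "sd": float(snacks.std(ddof=1)),
        "min": float(snacks.min()), "max": float(snacks.max()),
        "pct_snack_all_days": float(100.0 * (snack_days == n_days).mean()),
        "pct_never": float(100.0 * (snack_days == 0).mean()),
    }
    out["eating_frequency"] = {
        "mean": float(total.mean()), "sd": float(total.std(ddof=1)),
        "min": float(total.min()), "max": float(total.max()),
    }
    return out
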