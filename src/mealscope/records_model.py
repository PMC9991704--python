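"""Core data model and I/O for weighed dietary records.

Three tables make up a study data set:

* **participants** — one row per person (sex, age, height, weight, survey
  year); these drive BMI, BMR, EER and reference-value lookups.
* **records** — one row per diary *line*: a single food amount inside an
  eating occasion, carrying the diary section (breakfast / lunch / dinner /
  snack) and the occasion's start and finish clock times.
* **composition** — per-100 g nutrient contents, a food-group label, and
  Healthy-Eating-Index component equivalents for every food code.

Clock times are stored as integer minutes since midnight. Occasions that
cross midnight carry an explicit ``next_day`` flag on the finish time and
are attributed to the day on which they start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECTIONS = ("breakfast", "lunch", "dinner", "snack")
MAIN_MEALS = ("breakfast", "lunch", "dinner")
#: Diet strata used throughout the analysis (plural "snacks" per convention).
STRATA = ("total", "breakfast", "lunch", "dinner", "snacks")
MEAL_STRATA = ("breakfast", "lunch", "dinner", "snacks")

FOOD_GROUPS = (
    "rice", "bread", "noodles", "potatoes", "pulses",
    "total_vegetables", "fruit", "fish", "meat", "eggs",
    "dairy", "confectioneries", "sugar_sweetened_beverages",
    "alcoholic_beverages", "non_energetic_beverages",
)

NUTRIENT_COLUMNS = (
    "energy_kcal", "protein_g", "fat_g", "sfa_g", "mufa_g", "pufa_g",
    "carb_g", "added_sugar_g", "alcohol_g", "fibre_g",
    "na_mg", "k_mg", "ca_mg", "mg_mg", "fe_mg",
    "vita_ugrae", "vitd_ug", "vitc_mg",
)

HEI_EQUIV_COLUMNS = (
    "heq_total_fruit", "heq_whole_fruit", "heq_total_veg", "heq_greens_beans",
    "heq_whole_grains", "heq_refined_grains", "heq_dairy",
    "heq_total_protein", "heq_seafood_plant",
)

#: All additive per-line quantity columns.
VALUE_COLUMNS = NUTRIENT_COLUMNS + HEI_EQUIV_COLUMNS


class RecordsError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def parse_clock(text: str) -> int:
    """Parse an ``HH:MM`` clock string into minutes since midnight."""
    try:
        hh, mm = text.strip().split(":")
        h, m = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise RecordsError(f"malformed time {text!r} (expected HH:MM)") from exc
    if not (0 <= h < 24 and 0 <= m < 60):
        raise RecordsError(f"time {text!r} out of range")
    return 60 * h + m


def format_clock(minutes: int) -> str:
    """Inverse of :func:`parse_clock` (modulo 24 h for next-day finishes)."""
    minutes = int(minutes) % 1440
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass
class Participant:
    """Demographics and anthropometry for one study participant."""

    id: str
    sex: str  # "male" | "female"
    age: int  # years
    height_cm: float
    weight_kg: float
    survey_year: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise RecordsError(f"participant {self.id}: unknown sex {self.sex!r}")
        if self.age < 18:
            raise RecordsError(f"participant {self.id}: age {self.age} < 18")
        if not 100 < self.height_cm < 220:
            raise RecordsError(f"participant {self.id}: implausible height {self.height_cm}")
        if not 25 < self.weight_kg < 200:
            raise RecordsError(f"participant {self.id}: implausible weight {self.weight_kg}")

    @property
    def bmi(self) -> float:
        h = self.height_cm / 100.0
        return self.weight_kg / (h * h)


@dataclass
class FoodRecordLine:
    """One diary line: an amount of one food inside an eating occasion."""

    participant_id: str
    day_index: int
    section: str
    start_time: int  # minutes since midnight
    end_time: int
    food_code: str
    amount_g: float
    next_day: bool = False  # finish time falls on the following calendar day

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise RecordsError(f"unknown diary section {self.section!r}")
        if self.amount_g < 0:
            raise RecordsError(f"negative amount {self.amount_g} for {self.food_code}")
        if not 0 <= self.start_time < 1440:
            raise RecordsError(f"start time {self.start_time} out of range")
        if not self.next_day and self.end_time < self.start_time:
            raise RecordsError(
                f"finish {self.end_time} precedes start {self.start_time} "
                "without a next-day flag"
            )

    @property
    def end_minutes(self) -> int:
        """Finish time on a continuous axis (start's midnight = 0)."""
        return self.end_time + 1440 * int(self.next_day)


RECORD_COLUMNS = [f.name for f in dc_fields(FoodRecordLine)]
PARTICIPANT_COLUMNS = [f.name for f in dc_fields(Participant)]


# ---------------------------------------------------------------------------
# Composition table
# ---------------------------------------------------------------------------

class FoodCompositionTable:
    """Per-100 g nutrient vectors, food-group labels and HEI equivalents.

    Wraps a DataFrame indexed by ``food_code``. The bundled miniature table
    (:meth:`default`) covers all fifteen food groups with at least three
    foods each; it is a swappable fixture, not a nutritional reference.
    """

    REQUIRED = ["food_group", "is_water_only", *VALUE_COLUMNS]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "food_code":
            if "food_code" not in frame.columns:
                raise RecordsError("composition table lacks a food_code column")
            frame = frame.set_index("food_code")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise RecordsError(f"composition table missing columns: {missing}")
        frame["is_water_only"] = frame["is_water_only"].astype(bool)
        self.frame = frame
        self.validate()

    @classmethod
    def read(cls, path: str | Path) -> "FoodCompositionTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "FoodCompositionTable":
        with resources.files("mealscope.data").joinpath("composition.csv").open() as fh:
            return cls(pd.read_csv(fh))

    def validate(self) -> None:
        f = self.frame
        if f.index.duplicated().any():
            dups = sorted(f.index[f.index.duplicated()].unique())
            raise RecordsError(f"duplicate food codes: {dups}")
        bad_groups = sorted(set(f["food_group"]) - set(FOOD_GROUPS))
        if bad_groups:
            raise RecordsError(f"unknown food groups: {bad_groups}")
        vals = f[list(VALUE_COLUMNS)]
        if (vals < 0).any().any():
            raise RecordsError("negative per-100 g values in composition table")
        # Atwater 4/9/4/7 consistency (5 kcal absolute floor for low-energy
        # beverages where relative tolerance is meaningless).
        atwater = (4 * f["protein_g"] + 9 * f["fat_g"]
                   + 4 * f["carb_g"] + 7 * f["alcohol_g"])
        tol = np.maximum(0.25 * f["energy_kcal"], 5.0)
        off = f.index[(f["energy_kcal"] - atwater).abs() > tol]
        if len(off):
            raise RecordsError(f"energy inconsistent with Atwater check: {list(off)}")

    # -- lookups ------------------------------------------------------------

    @property
    def codes(self) -> pd.Index:
        return self.frame.index

    def contains(self, code: str) -> bool:
        return code in self.frame.index

    def group(self, code: str) -> str:
        return self.frame.at[code, "food_group"]

    def is_water_only(self, code: str) -> bool:
        return bool(self.frame.at[code, "is_water_only"])

    def per100(self, code: str) -> pd.Series:
        if code not in self.frame.index:
            raise RecordsError(f"unknown food code {code!r}")
        return self.frame.loc[code, list(VALUE_COLUMNS)].astype(float)

    def codes_in_group(self, group: str, energy_bearing: bool = False) -> list[str]:
        sel = self.frame["food_group"] == group
        if energy_bearing:
            sel &= self.frame["energy_kcal"] > 0
        return list(self.frame.index[sel])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_participants(path: str | Path) -> list[Participant]:
    frame = pd.read_csv(path, dtype={"id": str, "survey_year": str})
    missing = set(PARTICIPANT_COLUMNS) - set(frame.columns)
    if missing:
        raise RecordsError(f"participants file missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(Participant(row.id, row.sex, int(row.age),
                                   float(row.height_cm), float(row.weight_kg),
                                   str(row.survey_year)))
        except (RecordsError, ValueError) as exc:
            raise RecordsError(f"{path}, line {i}: {exc}") from exc
    return out


def write_participants(participants: Sequence[Participant], path: str | Path) -> None:
    participants_frame(participants).to_csv(path, index=False)


def participants_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in participants], columns=PARTICIPANT_COLUMNS)


def read_records(path: str | Path,
                 table: FoodCompositionTable | None = None) -> list[FoodRecordLine]:
    """Read a records CSV into diary lines.

    Clock strings ``HH:MM`` are converted to minutes since midnight. Any
    malformed row raises :class:`RecordsError` with its line number; if a
    composition *table* is given, unknown food codes are collected and
    reported in one hard error.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str, "food_code": str,
                                     "section": str, "start_time": str,
                                     "end_time": str})
    if frame.empty:
        logger.warning("records file %s is empty", path)
        return []
    missing = {"participant_id", "day_index", "section", "start_time",
               "end_time", "food_code", "amount_g"} - set(frame.columns)
    if missing:
        raise RecordsError(f"records file missing columns: {sorted(missing)}")
    has_flag = "next_day" in frame.columns

    lines: list[FoodRecordLine] = []
    unknown: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            start = parse_clock(row.start_time)
            end = parse_clock(row.end_time)
            nd = bool(getattr(row, "next_day", False)) if has_flag else False
            line = FoodRecordLine(row.participant_id, int(row.day_index),
                                  row.section, start, end, row.food_code,
                                  float(row.amount_g), nd)
        except (RecordsError, ValueError) as exc:
            raise RecordsError(f"{path}, line {i}: {exc}") from exc
        if table is not None and not table.contains(line.food_code):
            unknown.add(line.food_code)
        lines.append(line)
    if unknown:
        raise RecordsError(f"unknown food codes in {path}: {sorted(unknown)}")
    return lines


def write_records(lines: Sequence[FoodRecordLine], path: str | Path) -> None:
    """Write diary lines in the canonical CSV format (times as ``HH:MM``)."""
    frame = records_frame(lines)
    frame = frame.assign(start_time=frame["start_time"].map(format_clock),
                         end_time=frame["end_time"].map(format_clock),
                         next_day=frame["next_day"].astype(int))
    frame.to_csv(path, index=False)


def records_frame(lines: Sequence[FoodRecordLine]) -> pd.DataFrame:
    """Diary lines as a DataFrame (times in minutes since midnight)."""
    return pd.DataFrame([vars(ln) for ln in lines], columns=RECORD_COLUMNS)


def lines_from_frame(frame: pd.DataFrame) -> list[FoodRecordLine]:
    return [FoodRecordLine(r.participant_id, int(r.day_index), r.section,
                           int(r.start_time), int(r.end_time), r.food_code,
                           float(r.amount_g), bool(r.next_day))
            for r in frame.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Nutrient arithmetic
# ---------------------------------------------------------------------------

def line_nutrients(line: FoodRecordLine, table: FoodCompositionTable) -> pd.Series:
    """Nutrient vector of one diary line: per-100 g values x amount / 100."""
    return table.per100(line.food_code) * (line.amount_g / 100.0)


def frame_nutrients(records: pd.DataFrame, table: FoodCompositionTable) -> pd.DataFrame:
    """Vectorised per-line nutrients for a records frame.

    Returns a DataFrame aligned with ``records`` (same index) holding one
    column per nutrient / HEI-equivalent plus the line's ``food_group``.
    """
    unknown = sorted(set(records["food_code"]) - set(table.codes))
    if unknown:
        raise RecordsError(f"unknown food codes: {unknown}")
    per100 = table.frame.loc[records["food_code"], list(VALUE_COLUMNS)].to_numpy(float)
    vals = per100 * (records["amount_g"].to_numpy(float)[:, None] / 100.0)
    out = pd.DataFrame(vals, columns=list(VALUE_COLUMNS), index=records.index)
    out["food_group"] = table.frame.loc[records["food_code"], "food_group"].to_numpy()
    return out


def sum_nutrients(vectors: Iterable[pd.Series]) -> pd.Series:
    """Sum of nutrient vectors (zero vector for an empty iterable)."""
    total = pd.Series(0.0, index=list(VALUE_COLUMNS))
    for v in vectors:
        total = total.add(v, fill_value=0.0)
    return total
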