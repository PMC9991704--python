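"""Shared fixtures: composition table, scoring references, and one
session-scoped default-configuration cohort reused by the calibration and
acceptance tests (generating it once keeps the suite fast)."""

import numpy as np
import pytest

from mealscope.diet_quality import NRFReferenceTable, load_hei_standards
from mealscope.intake_aggregation import aggregate, percent_contribution
from mealscope.meal_classifier import classify_records, meal_descriptives
from mealscope.records_model import FoodCompositionTable, records_frame
from mealscope.synthetic_data import default_config, generate_population


@pytest.fixture(scope="session")
def table():
    return FoodCompositionTable.default()


@pytest.fixture(scope="session")
def hei_standards():
    return load_hei_standards()


@pytest.fixture(scope="session")
def nrf_refs():
    return NRFReferenceTable.load()


@pytest.fixture(scope="session")
def pop600(table):
    """Default-configuration cohort (n=600, seed 1) through the full
    classify-and-aggregate pipeline."""
    cfg = default_config(n_participants=600, seed=1)
    participants, lines = generate_population(cfg, table)
    records = records_frame(lines)
    occasions, line_labels = classify_records(records, table)
    intakes = aggregate(records, line_labels, table,
                        [p.id for p in participants], cfg.n_days)
    return {
        "config": cfg,
        "participants": participants,
        "records": records,
        "occasions": occasions,
        "line_labels": line_labels,
        "intakes": intakes,
        "contrib": percent_contribution(intakes),
        "descriptives": meal_descriptives(occasions, cfg.n_days),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
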