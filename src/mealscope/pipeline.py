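"""End-to-end pipeline: generate/load -> classify -> aggregate -> score ->
screen -> describe/associate, with the report tables written as CSV.

The report bundle mirrors the layout of a meal-type characterisation
study: score descriptives (table 1), scores by participant characteristics
(table 2), nutrient and food-group contributions per meal type (tables 3
and 4), tertile-adjusted intakes of nutrients and foods from each main
meal (tables 5 and 6), and meal-consumption frequencies (supplementary
table 1). A machine-readable ``summary.json`` and a run log carrying the
seed and package version accompany the tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .records_model import (NUTRIENT_COLUMNS, FoodCompositionTable,
                            RecordsError, participants_frame,
                            read_participants, read_records, records_frame,
                            write_participants, write_records)
from .meal_classifier import classify_records, meal_descriptives
from .intake_aggregation import (GROUP_COLUMNS, aggregate,
                                 consumer_only_means, percent_contribution,
                                 percent_energy_profile, stratum_means)
from .diet_quality import (NRFReferenceTable, load_hei_standards,
                           score_population)
from .misreporting import screen_population
from .association_stats import (age_band, assign_tertiles, compare_groups,
                                correlate, describe_scores, tertile_table)
from .synthetic_data import GeneratorConfig, generate_population

logger = logging.getLogger(__name__)

TABLE_FILES = (
    "table1_score_descriptives.csv",
    "table2_scores_by_characteristics.csv",
    "table3_nutrient_contributions.csv",
    "table4_food_contributions.csv",
    "table5_tertile_nutrients.csv",
    "table6_tertile_foods.csv",
    "supp_table1_meal_frequencies.csv",
)


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results"
    seed: int = 0
    # either generate ...
    generator: GeneratorConfig | None = None
    # ... or read from CSV
    records_path: str | Path | None = None
    participants_path: str | Path | None = None
    composition_path: str | Path | None = None
    hei_standards_path: str | Path | None = None
    dri_reference_path: str | Path | None = None
    n_days: int = 4
    write_inputs: bool = True       # persist generated participant/record CSVs
    run_associations: bool = True   # tertile GLM tables (needs enough n)
    tertile_outcomes: tuple = ("energy_kcal", "protein_g", "fibre_g",
                               "grams_total_vegetables", "grams_fish",
                               "grams_rice", "grams_confectioneries")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict.

    Any stage failure raises :class:`PipelineError` naming the stage, and
    partially written tables are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mealscope")
    root.addHandler(handler)
    prev_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    written: list[Path] = []
    stage = "setup"
    try:
        logger.info("mealscope %s, seed %d", __version__, config.seed)

        stage = "load"
        table = (FoodCompositionTable.read(config.composition_path)
                 if config.composition_path else FoodCompositionTable.default())
        if config.generator is not None:
            stage = "generate"
            gen = replace(config.generator, seed=config.seed)
            participants, lines = generate_population(gen, table)
            n_days = gen.n_days
            if config.write_inputs:
                write_participants(participants, out / "participants.csv")
                write_records(lines, out / "records.csv")
                written += [out / "participants.csv", out / "records.csv"]
        elif config.records_path and config.participants_path:
            participants = read_participants(config.participants_path)
            lines = read_records(config.records_path, table)
            n_days = config.n_days
        else:
            raise RecordsError("config needs either a generator or input paths")
        records = records_frame(lines)

        stage = "classify"
        occasions, line_labels = classify_records(records, table)
        occasions.to_csv(out / "occasions.csv", index=False)
        written.append(out / "occasions.csv")
        descriptives = meal_descriptives(occasions, n_days)

        stage = "aggregate"
        ids = [p.id for p in participants]
        intakes = aggregate(records, line_labels, table, ids, n_days)
        intakes.reset_index().to_csv(out / "intakes.csv", index=False)
        written.append(out / "intakes.csv")
        contrib = percent_contribution(intakes)
        energy_profile = percent_energy_profile(intakes)
        means = stratum_means(intakes)

        stage = "score"
        standards = load_hei_standards(config.hei_standards_path)
        refs = NRFReferenceTable.load(config.dri_reference_path)
        scores = score_population(intakes, participants, standards, refs)
        scores.reset_index().to_csv(out / "scores.csv", index=False)
        written.append(out / "scores.csv")

        stage = "screen"
        screening = screen_population(participants, intakes)
        screening.to_csv(out / "screening.csv")
        written.append(out / "screening.csv")

        stage = "report"
        written += _write_tables(out, config, participants, descriptives,
                                 intakes, contrib, energy_profile, means,
                                 scores, screening)

        stage = "summary"
        summary = _summarise(config, participants, descriptives, contrib,
                             scores, screening)
        with (out / "summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %d participants", len(participants))
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.setLevel(prev_level)
        root.removeHandler(handler)
        handler.close()


def _characteristics(participants, screening) -> pd.DataFrame:
    chars = participants_frame(participants).set_index("id")
    chars["age_band"] = chars["age"].map(age_band)
    chars["weight_status"] = screening["weight_status"]
    chars["reporting_status"] = screening["reporting_status"]
    return chars


def _write_tables(out, config, participants, descriptives, intakes, contrib,
                  energy_profile, means, scores, screening) -> list[Path]:
    written = []
    chars = _characteristics(participants, screening)

    # table 1: score descriptives per stratum + inter-stratum correlations
    desc = describe_scores(scores[["hei_total", "nrf_total"]])
    corr_blocks = []
    for col in ("hei_total", "nrf_total"):
        wide = scores[col].unstack("stratum")
        corr = correlate(wide).round(3)
        corr.insert(0, "score", col)
        corr_blocks.append(corr)
    desc.to_csv(out / TABLE_FILES[0])
    pd.concat(corr_blocks).to_csv(out / "table1b_score_correlations.csv")
    written += [out / TABLE_FILES[0], out / "table1b_score_correlations.csv"]

    # table 2: total scores by characteristics
    rows = []
    total_scores = scores.xs("total", level="stratum")
    for col in ("hei_total", "nrf_total"):
        for grouping in ("sex", "survey_year", "age_band", "weight_status",
                         "reporting_status"):
            cmp = compare_groups(total_scores[col], chars[grouping])
            for lv in cmp["levels"]:
                rows.append({
                    "score": col, "grouping": grouping, "level": lv,
                    "n": cmp["n"][lv], "mean": cmp["means"][lv],
                    "sd": cmp["sds"][lv], "test": cmp["test"],
                    "p_value": cmp["p_value"],
                    "posthoc": (cmp["letters"] or {}).get(lv, "")})
        pd.DataFrame(rows).to_csv(out / TABLE_FILES[1], index=False)
    written.append(out / TABLE_FILES[1])

    # tables 3/4: per-capita means and contributions
    nut = means[list(NUTRIENT_COLUMNS)].T.join(
        contrib.loc[list(NUTRIENT_COLUMNS)].add_prefix("pct_"))
    nut.to_csv(out / TABLE_FILES[2])
    energy_profile.to_csv(out / "table3b_percent_energy.csv")
    foods = means[list(GROUP_COLUMNS)].T.join(
        contrib.loc[list(GROUP_COLUMNS)].add_prefix("pct_"))
    consumers = consumer_only_means(intakes).unstack("stratum")
    consumers.columns = [f"{a}_{b}" for a, b in consumers.columns]
    consumers.index = [f"grams_{g}" for g in consumers.index]
    foods = foods.join(consumers)
    foods.to_csv(out / TABLE_FILES[3])
    written += [out / TABLE_FILES[2], out / "table3b_percent_energy.csv",
                out / TABLE_FILES[3]]

    # tables 5/6: tertile GLM of intakes from each main meal
    t5_blocks, t6_blocks = [], []
    if config.run_associations and len(participants) >= 60:
        hei_tert = assign_tertiles(scores.xs("total", level="stratum")["hei_total"])
        base = chars.join(hei_tert["tertile"])
        nutrient_outcomes = [c for c in config.tertile_outcomes
                             if not c.startswith("grams_")]
        food_outcomes = [c for c in config.tertile_outcomes
                         if c.startswith("grams_")]
        for stratum in ("breakfast", "lunch", "dinner"):
            intake_s = intakes.xs(stratum, level="stratum")
            data = base.join(intake_s[list(config.tertile_outcomes)])
            for blocks, outcomes in ((t5_blocks, nutrient_outcomes),
                                     (t6_blocks, food_outcomes)):
                if not outcomes:
                    continue
                tab = tertile_table(data, outcomes)
                tab.insert(0, "meal", stratum)
                blocks.append(tab)
    for blocks, fname in ((t5_blocks, TABLE_FILES[4]), (t6_blocks, TABLE_FILES[5])):
        frame = (pd.concat(blocks) if blocks
                 else pd.DataFrame(columns=["meal", "T1", "T2", "T3", "trend_p", "n"]))
        frame.to_csv(out / fname)
        written.append(out / fname)

    # supplementary table 1: meal consumption frequencies
    rows = []
    for meal, d in descriptives["meal_consumption"].items():
        rows.append({"meal": meal, "pct_all_days": d["pct_all_days"],
                     "pct_never": d["pct_never"]})
    sf = descriptives["snack_frequency"]
    rows.append({"meal": "snacks", "pct_all_days": sf["pct_snack_all_days"],
                 "pct_never": sf["pct_never"]})
    pd.DataFrame(rows).to_csv(out / TABLE_FILES[6], index=False)
    written.append(out / TABLE_FILES[6])
    return written


def _summarise(config, participants, descriptives, contrib, scores,
               screening) -> dict:
    energy_contrib = contrib.loc["energy_kcal"]
    conf_contrib = contrib.loc["grams_confectioneries"]
    hei = scores["hei_total"].groupby(level="stratum", observed=True).mean()
    nrf = scores["nrf_total"].groupby(level="stratum", observed=True).mean()
    reporting = screening["reporting_status"].value_counts(normalize=True)
    summary = {
        "package_version": __version__,
        "seed": int(config.seed),
        "n_participants": len(participants),
        "energy_contribution_pct": {k: round(float(v), 6)
                                    for k, v in energy_contrib.items()},
        "confectionery_contribution_pct": {k: round(float(v), 6)
                                           for k, v in conf_contrib.items()},
        "mean_start_times": {m: d["mean_start_clock"]
                             for m, d in descriptives["start_times"].items()},
        "snack_frequency_mean": round(descriptives["snack_frequency"]["mean"], 6),
        "eating_frequency_mean": round(descriptives["eating_frequency"]["mean"], 6),
        "hei_total_means": {k: round(float(v), 6) for k, v in hei.items()},
        "nrf_total_means": {k: round(float(v), 6) for k, v in nrf.items()},
        "reporting_status_pct": {k: round(float(v * 100), 6)
                                 for k, v in reporting.items()},
    }
    return summary
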