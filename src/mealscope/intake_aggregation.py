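"""Aggregation of classified occasions into per-stratum mean daily intakes.

All dietary variables are averaged over the recording days (default 4),
with zero assigned for non-consumers, so every participant has a value in
every stratum (total, breakfast, lunch, dinner, snacks). Percentage
contributions are per-capita: the ratio of population means, not the mean
of individual ratios, matching the convention of contribution tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records_model import (FOOD_GROUPS, MEAL_STRATA, STRATA,
                            VALUE_COLUMNS, FoodCompositionTable,
                            frame_nutrients)
from .meal_classifier import EXCLUDED

GROUP_COLUMNS = tuple(f"grams_{g}" for g in FOOD_GROUPS)
#: All aggregated intake variables.
INTAKE_COLUMNS = VALUE_COLUMNS + GROUP_COLUMNS

#: Atwater energy factors (kcal per gram).
ATWATER = {"protein_g": 4.0, "fat_g": 9.0, "carb_g": 4.0, "alcohol_g": 7.0}


def aggregate(records: pd.DataFrame, line_labels: pd.Series,
              table: FoodCompositionTable, participant_ids, n_days: int = 4
              ) -> pd.DataFrame:
    """Mean daily intake per participant and stratum.

    Returns a frame indexed by (participant_id, stratum) with one column
    per nutrient, HEI equivalent and food-group gram amount, plus
    ``consumed_any`` (did the stratum ever occur) and ``n_days_consumed``.
    The snack label is reported under the plural stratum name ``snacks``.
    """
    participant_ids = list(participant_ids)
    nut = frame_nutrients(records, table)
    nut["participant_id"] = records["participant_id"].values
    nut["day_index"] = records["day_index"].values
    nut["amount_g"] = records["amount_g"].values
    nut["stratum"] = line_labels.replace({"snack": "snacks"}).values
    nut = nut[nut["stratum"] != EXCLUDED]

    # nutrient + equivalent sums
    sums = (nut.groupby(["participant_id", "stratum"])[list(VALUE_COLUMNS)]
            .sum() / n_days)
    # food-group grams
    grams = (nut.pivot_table(index=["participant_id", "stratum"],
                             columns="food_group", values="amount_g",
                             aggfunc="sum", fill_value=0.0) / n_days)
    grams = grams.reindex(columns=list(FOOD_GROUPS), fill_value=0.0)
    grams.columns = [f"grams_{g}" for g in grams.columns]
    days = (nut.groupby(["participant_id", "stratum"])["day_index"]
            .nunique().rename("n_days_consumed"))

    full = pd.MultiIndex.from_product([participant_ids, list(MEAL_STRATA)],
                                      names=["participant_id", "stratum"])
    strat = (pd.concat([sums, grams, days], axis=1)
             .reindex(full, fill_value=0.0))
    strat["consumed_any"] = strat["n_days_consumed"] > 0

    total = strat.groupby(level="participant_id", sort=False)[list(INTAKE_COLUMNS)].sum()
    total["n_days_consumed"] = (
        nut.groupby("participant_id")["day_index"].nunique()
        .reindex(participant_ids, fill_value=0))
    total["consumed_any"] = total["n_days_consumed"] > 0
    total["stratum"] = "total"
    total = total.set_index("stratum", append=True)

    out = pd.concat([strat, total]).reset_index()
    out["stratum"] = pd.Categorical(out["stratum"], categories=list(STRATA),
                                    ordered=True)
    out = (out.sort_values(["participant_id", "stratum"])
           .set_index(["participant_id", "stratum"]))
    out["n_days_consumed"] = out["n_days_consumed"].astype(int)
    return out


def stratum_means(intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-capita population means of every variable by stratum."""
    return (intakes.groupby(level="stratum", observed=True)[list(INTAKE_COLUMNS)]
            .mean())


def percent_contribution(intakes: pd.DataFrame,
                         variables: list[str] | None = None) -> pd.DataFrame:
    """Per-capita percentage contribution of each meal type to total intake.

    contribution(variable, meal) = 100 x mean intake from meal / mean total
    intake, zeros included. Variables whose population mean total intake is
    zero get missing (NaN) contributions rather than propagating a division
    by zero.
    """
    variables = list(variables) if variables is not None else list(INTAKE_COLUMNS)
    means = stratum_means(intakes)[variables]
    total = means.loc["total"]
    contrib = means.loc[list(MEAL_STRATA)].div(total, axis=1) * 100.0
    contrib[total.index[total == 0]] = np.nan
    return contrib.T  # variables x meal strata


def percent_energy_profile(intakes: pd.DataFrame) -> pd.DataFrame:
    """Macronutrient percentage-of-energy profile per stratum.

    Computed over stratum consumers only (participants who never consumed
    a stratum are excluded from its denominator, as are the rare zero-
    energy strata). Energy from protein / fat / carbohydrate / alcohol uses
    Atwater factors 4/9/4/7; saturated fats and added sugars are also
    expressed in %E for diet-quality reporting.
    """
    rows = []
    for stratum, sub in intakes.groupby(level="stratum", observed=True):
        sub = sub[(sub["consumed_any"]) & (sub["energy_kcal"] > 0)]
        row = {"stratum": stratum, "n_consumers": len(sub)}
        for macro, factor in ATWATER.items():
            pe = 100.0 * factor * sub[macro] / sub["energy_kcal"]
            row[f"{macro[:-2]}_pctE_mean"] = pe.mean()
            row[f"{macro[:-2]}_pctE_sd"] = pe.std(ddof=1)
        for extra, factor in (("sfa_g", 9.0), ("added_sugar_g", 4.0)):
            pe = 100.0 * factor * sub[extra] / sub["energy_kcal"]
            row[f"{extra[:-2]}_pctE_mean"] = pe.mean()
            row[f"{extra[:-2]}_pctE_sd"] = pe.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def consumer_only_means(intakes: pd.DataFrame) -> pd.DataFrame:
    """Food-group means over consumers of each group within each stratum.

    Mirrors contribution tables that report, next to per-capita values, the
    number of consumers and means calculated on consumers only.
    """
    rows = []
    for stratum, sub in intakes.groupby(level="stratum", observed=True):
        for col in GROUP_COLUMNS:
            consumers = sub[sub[col] > 0][col]
            rows.append({"stratum": stratum, "food_group": col[len("grams_"):],
                         "n_consumers": int(consumers.size),
                         "consumer_mean_g": (float(consumers.mean())
                                             if consumers.size else np.nan)})
    return pd.DataFrame(rows).set_index(["food_group", "stratum"])
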