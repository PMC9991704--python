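#!/usr/bin/env python
"""Decompose intakes into per-meal percentage contributions.

Aggregates 4-day mean intakes per stratum (zeros for non-consumers),
writes the nutrient and food-group contribution tables, and prints the
headline pattern: how much of daily energy — and of each food group —
comes from breakfast, lunch, dinner and snacks.
"""

from pathlib import Path

from mealscope.intake_aggregation import (aggregate, consumer_only_means,
                                          percent_contribution,
                                          percent_energy_profile)
from mealscope.records_model import (FoodCompositionTable, read_participants,
                                     read_records, records_frame)
from mealscope.meal_classifier import classify_records

OUT = Path("results/analysis")


def main() -> None:
    table = FoodCompositionTable.default()
    participants = read_participants(OUT / "participants.csv")
    records = records_frame(read_records(OUT / "records.csv", table))
    occasions, line_labels = classify_records(records, table)
    intakes = aggregate(records, line_labels, table,
                        [p.id for p in participants], n_days=4)
    intakes.reset_index().to_csv(OUT / "intakes.csv", index=False)

    contrib = percent_contribution(intakes)
    contrib.to_csv(OUT / "contributions.csv")
    percent_energy_profile(intakes).to_csv(OUT / "percent_energy.csv")
    consumer_only_means(intakes).to_csv(OUT / "consumer_only_means.csv")

    e = contrib.loc["energy_kcal"]
    print("energy from breakfast/lunch/dinner/snacks: "
          + "/".join(f"{e[s]:.0f}" for s in
                     ("breakfast", "lunch", "dinner", "snacks")) + " %")
    print("\nfood groups dominated by one meal type:")
    foods = contrib.loc[[c for c in contrib.index if c.startswith("grams_")]]
    top = foods.idxmax(axis=1)
    for var, meal in top.items():
        share = foods.loc[var, meal]
        if share > 50:
            print(f"  {var[len('grams_'):]:26s} {share:5.1f} % at {meal}")
    print("\nevenly spread (no meal above 50 %): "
          + ", ".join(v[len("grams_"):] for v, m in top.items()
                      if foods.loc[v, m] <= 50))


if __name__ == "__main__":
    main()
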