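#!/usr/bin/env python
"""Score diet quality (HEI-2015 and NRF9.3) for the total diet and each
meal type.

Writes per-participant scores, the descriptive table and the stratum
correlation matrices, and prints the quality ordering across meal types.
"""

from pathlib import Path

from mealscope.association_stats import correlate, describe_scores
from mealscope.diet_quality import score_population
from mealscope.intake_aggregation import aggregate
from mealscope.meal_classifier import classify_records
from mealscope.records_model import (FoodCompositionTable, read_participants,
                                     read_records, records_frame)

OUT = Path("results/analysis")


def main() -> None:
    table = FoodCompositionTable.default()
    participants = read_participants(OUT / "participants.csv")
    records = records_frame(read_records(OUT / "records.csv", table))
    occasions, line_labels = classify_records(records, table)
    intakes = aggregate(records, line_labels, table,
                        [p.id for p in participants], n_days=4)
    scores = score_population(intakes, participants)
    scores.reset_index().to_csv(OUT / "scores.csv", index=False)

    desc = describe_scores(scores[["hei_total", "nrf_total"]])
    desc.to_csv(OUT / "score_descriptives.csv")
    for col in ("hei_total", "nrf_total"):
        wide = scores[col].unstack("stratum")
        correlate(wide).to_csv(OUT / f"correlations_{col}.csv")

    print("mean (sd) scores by stratum:")
    for col, cap in (("hei_total", 100), ("nrf_total", 900)):
        print(f"  {col} (max {cap}):")
        for stratum in ("total", "breakfast", "lunch", "dinner", "snacks"):
            row = desc.loc[(col, stratum)]
            print(f"    {stratum:9s} {row['mean']:7.1f} (sd {row['sd']:5.1f}),"
                  f" n={row['n']:.0f}")
    hei = desc.loc["hei_total"].loc[["breakfast", "lunch", "dinner", "snacks"],
                                    "mean"]
    order = " > ".join(hei.sort_values(ascending=False).index)
    print(f"quality ordering (HEI-2015): {order}")
    corr = correlate(scores["hei_total"].unstack("stratum"))
    meals = ["breakfast", "lunch", "dinner", "snacks"]
    print("HEI total-diet vs meal correlations: "
          + ", ".join(f"{m} {corr.loc['total', m]:.2f}" for m in meals))


if __name__ == "__main__":
    main()
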