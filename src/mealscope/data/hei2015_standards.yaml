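# HEI-2015 component scoring standards.
#
# direction: adequacy (more is better) or moderation (less is better).
# basis:
#   per_1000   — amount per 1000 kcal of energy
#   pct_energy — percentage of energy
#   ratio      — unadjusted ratio (fatty acids: (MUFA + PUFA) / SFA)
# max_threshold:  intake at (or beyond) which the component earns max_points
# zero_threshold: intake at (or beyond, in the moderation direction) which the
#                 component earns 0 points; adequacy components score
#                 proportionally from 0 between zero_threshold and
#                 max_threshold (all adequacy zero_thresholds are 0 here).
components:
  total_fruits:
    direction: adequacy
    basis: per_1000
    source: heq_total_fruit      # cup-eq
    max_points: 5
    max_threshold: 0.8
    zero_threshold: 0.0
  whole_fruits:
    direction: adequacy
    basis: per_1000
    source: heq_whole_fruit      # cup-eq
    max_points: 5
    max_threshold: 0.4
    zero_threshold: 0.0
  total_vegetables:
    direction: adequacy
    basis: per_1000
    source: heq_total_veg        # cup-eq
    max_points: 5
    max_threshold: 1.1
    zero_threshold: 0.0
  greens_and_beans:
    direction: adequacy
    basis: per_1000
    source: heq_greens_beans     # cup-eq
    max_points: 5
    max_threshold: 0.2
    zero_threshold: 0.0
  whole_grains:
    direction: adequacy
    basis: per_1000
    source: heq_whole_grains     # oz-eq
    max_points: 10
    max_threshold: 1.5
    zero_threshold: 0.0
  dairy:
    direction: adequacy
    basis: per_1000
    source: heq_dairy            # cup-eq
    max_points: 10
    max_threshold: 1.3
    zero_threshold: 0.0
  total_protein_foods:
    direction: adequacy
    basis: per_1000
    source: heq_total_protein    # oz-eq
    max_points: 5
    max_threshold: 2.5
    zero_threshold: 0.0
  seafood_plant_proteins:
    direction: adequacy
    basis: per_1000
    source: heq_seafood_plant    # oz-eq
    max_points: 5
    max_threshold: 0.8
    zero_threshold: 0.0
  fatty_acids:
    direction: adequacy
    basis: ratio                 # (MUFA + PUFA) / SFA, unadjusted
    source: fatty_acid_ratio
    max_points: 10
    max_threshold: 2.5
    zero_threshold: 1.2
  refined_grains:
    direction: moderation
    basis: per_1000
    source: heq_refined_grains   # oz-eq
    max_points: 10
    max_threshold: 1.8
    zero_threshold: 4.3
  sodium:
    direction: moderation
    basis: per_1000
    source: na_g                 # grams of sodium
    max_points: 10
    max_threshold: 1.1
    zero_threshold: 2.0
  added_sugars:
    direction: moderation
    basis: pct_energy
    source: added_sugar_g        # converted to % of energy at 4 kcal/g
    max_points: 10
    max_threshold: 6.5
    zero_threshold: 26.0
  saturated_fats:
    direction: moderation
    basis: pct_energy
    source: sfa_g                # converted to % of energy at 9 kcal/g
    max_points: 10
    max_threshold: 8.0
    zero_threshold: 16.0
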