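# Reference daily values for the NRF9.3 score, by sex and age band, drawn
# from the Dietary Reference Intakes for Japanese (2015) conventions for
# adults, plus the WHO conditional limit for added sugars (5 % of energy).
#
# EER: Estimated Energy Requirement (kcal/d) for a moderate physical
# activity level; used to re-scale energy densities to absolute amounts
# before expressing them as % of the daily value.
#
# Disqualifying daily values are derived from energy:
#   added sugars: 5 %E of the EER at 4 kcal/g
#   saturated fats: 7 %E of the EER at 9 kcal/g
#   sodium: salt-equivalent target (g) converted at Na = salt / 2.54 * 1000
age_bands:
  - {name: "18-29", min_age: 18, max_age: 29}
  - {name: "30-49", min_age: 30, max_age: 49}
  - {name: "50-69", min_age: 50, max_age: 69}
  - {name: "70+",   min_age: 70, max_age: 130}

eer_kcal:
  male:   {"18-29": 2650, "30-49": 2650, "50-69": 2450, "70+": 2200}
  female: {"18-29": 1950, "30-49": 2000, "50-69": 1900, "70+": 1750}

# Qualifying nutrients (units match the intake columns).
qualifying:
  protein_g:
    male:   {"18-29": 60, "30-49": 60, "50-69": 60, "70+": 60}
    female: {"18-29": 50, "30-49": 50, "50-69": 50, "70+": 50}
  fibre_g:
    male:   {"18-29": 20, "30-49": 20, "50-69": 20, "70+": 19}
    female: {"18-29": 18, "30-49": 18, "50-69": 18, "70+": 17}
  vita_ugrae:
    male:   {"18-29": 850, "30-49": 900, "50-69": 850, "70+": 800}
    female: {"18-29": 650, "30-49": 700, "50-69": 700, "70+": 650}
  vitc_mg:
    male:   {"18-29": 100, "30-49": 100, "50-69": 100, "70+": 100}
    female: {"18-29": 100, "30-49": 100, "50-69": 100, "70+": 100}
  vitd_ug:
    male:   {"18-29": 5.5, "30-49": 5.5, "50-69": 5.5, "70+": 5.5}
    female: {"18-29": 5.5, "30-49": 5.5, "50-69": 5.5, "70+": 5.5}
  ca_mg:
    male:   {"18-29": 800, "30-49": 650, "50-69": 700, "70+": 700}
    female: {"18-29": 650, "30-49": 650, "50-69": 650, "70+": 650}
  fe_mg:
    male:   {"18-29": 7.0, "30-49": 7.5, "50-69": 7.5, "70+": 7.0}
    female: {"18-29": 10.5, "30-49": 10.5, "50-69": 6.5, "70+": 6.0}
  k_mg:
    male:   {"18-29": 3000, "30-49": 3000, "50-69": 3000, "70+": 3000}
    female: {"18-29": 2600, "30-49": 2600, "50-69": 2600, "70+": 2600}
  mg_mg:
    male:   {"18-29": 340, "30-49": 370, "50-69": 350, "70+": 320}
    female: {"18-29": 270, "30-49": 290, "50-69": 290, "70+": 270}

# Disqualifying nutrient parameters.
disqualifying:
  added_sugar_pct_energy_limit: 5.0
  sfa_pct_energy_limit: 7.0
  salt_equivalent_g:
    male: 8.0
    female: 7.0

# Context recorded with the Goldberg screening configuration: the cut-offs
# 1.02 / 2.35 assume a sedentary physical activity level of 1.55.
goldberg:
  pal: 1.55
  under_cutoff: 1.02
  over_cutoff: 2.35
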