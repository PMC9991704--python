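# Methods

This note documents the models, conventions and numerical choices behind
`mealscope`: what each stage computes, which knobs matter, what the
synthetic-record generator does and does not emulate, and the known
limitations.

## Eating-occasion classification

An *eating occasion* is a separate intake event with its own start clock
time and diary name. Diary lines are grouped into candidate occasions by
(participant, day, diary section, start time): lines sharing a section and
start time are one occasion, matching the diary convention that all items
of an occasion carry the same clock time and name. Times are integer
minutes since midnight; an occasion finishing after midnight carries a
next-day flag and is attributed to the day on which it starts.

Three rules are applied per participant-day, in this order:

1. **Water-only exclusion.** Occasions whose every member food is plain
   tap or mineral water are removed whole. An occasion containing water
   plus anything else is retained whole.
2. **Multiple-entry rule.** If a main-meal diary section (breakfast,
   lunch, dinner) holds more than one occasion, the earliest-starting
   occasion keeps the meal label and the later ones become snacks. Ties on
   start time fall to the first-recorded entry.
3. **Overlap merging.** Occasions whose half-open minute intervals
   intersect are merged transitively into one occasion spanning the union
   (touching boundaries do not merge — the least surprising reading of an
   "overlapping time period"). A merged set containing one main-meal label
   plus snacks keeps the meal label, unless that meal already occurred
   earlier in the day, in which case the merged occasion is a snack.
   All-snack merges stay snacks. Two *different* main meals overlapping is
   not covered by the diary conventions; the earlier-starting label wins
   and the event is logged, which preserves the at-most-one-of-each-meal
   invariant deterministically.

The order (multiple-entry resolution before merging) is a fixed design
choice. For diary-style inputs the two orders agree: a second lunch-section
entry overlapping a snack is relabelled snack by rule 2 and then merged
snack-with-snack by rule 3, the same outcome as merging first and applying
the earlier-same-meal precedence. The precedence branch is nevertheless
kept in `merge_overlaps` (and unit-tested standalone) so the function is
correct when used on its own.

The pipeline is idempotent, conserves every non-excluded line into exactly
one occasion, and is invariant to input line order up to the documented
tie-breaks.

## Aggregation and contribution decomposition

All dietary variables are averaged over the recording days (default 4)
with zero assigned for non-consumers, yielding one value per participant
for each of five strata: total, breakfast, lunch, dinner, snacks. The
stratum totals satisfy `total = breakfast + lunch + dinner + snacks`
exactly.

Percentage contributions are **per-capita** — the ratio of population
means (zeros included), not the mean of individual ratios — so the four
meal contributions of every variable sum to exactly 100 % before
rounding. Percentage-of-energy profiles use Atwater factors 4/9/4/7
(protein / fat / available carbohydrate / alcohol) and are computed over
stratum consumers only; carbohydrate in the bundled composition table
excludes fibre, so the macronutrient %E closes to 100 up to rounding.
Food-group tables also report consumer counts and consumer-only means.

## Diet-quality scores

**HEI-2015** scores 13 components against the 2015–2020 Dietary
Guidelines for Americans: nine adequacy components scored upward and four
moderation components (refined grains, sodium, added sugars, saturated
fats) scored downward, 100 points total. Intakes are energy-adjusted by
the density method — amount per 1000 kcal, or % of energy for added
sugars and saturated fats — except the fatty-acid component, the
unadjusted ratio (MUFA + PUFA)/SFA. Each component is linear between its
zero and maximum thresholds and clamped outside them. The thresholds ship
as packaged YAML (`data/hei2015_standards.yaml`) transcribed from the
published HEI-2015 scoring standards; they are configuration, not code,
so the mapping is auditable and swappable. Degenerate case: with SFA = 0
the ratio is taken as +infinity (full points) when any unsaturated fat is
present, and as the floor (0 points) when there is no fat at all —
continuity in the adequacy direction.

Because the source food tables do not come with cup/oz-equivalents for
Japanese foods, the composition table carries explicit HEI-equivalent
columns per 100 g of every food; this makes the otherwise-undocumented
food-to-component mapping visible data.

**NRF9.3** sums the %DV of nine qualifying nutrients (protein, fibre,
vitamins A, C, D, Ca, Fe, K, Mg), each capped at 100, minus the uncapped
%DV of three disqualifying nutrients (added sugars, saturated fats,
sodium); the maximum is 900 and the minimum unbounded below. Nutrient
densities are re-scaled to the participant's sex- and age-specific
Estimated Energy Requirement (moderate physical activity) before
comparison with the daily values. Reference values
(`data/dri_reference.yaml`) follow the Dietary Reference Intakes for
Japanese (2015) conventions for adults in four age bands, with the WHO
conditional limit (5 % of energy) for added sugars, a 7 %E limit for
saturated fats and salt-equivalent targets for sodium (disqualifying
daily values derive from the EER).

Meal-stratum scores apply the same density method to the stratum's own
energy and, for NRF, the full-day EER: a meal is scored as a diet of its
own composition. A stratum that was never consumed (zero energy) has no
defined density and scores missing, and such strata are excluded from
descriptive and correlation denominators. Both scores are exactly
invariant to rescaling all food amounts by a common factor.

## Misreporting screening

BMI bands: <18.5 underweight, 18.5 to <25 normal, >=25 overweight. BMR
uses the Japanese-adult equation on weight, height, age and sex,

    BMR [MJ/d] = 0.1238 + 0.0481 W + 0.0234 H − 0.0138 A − 0.5473 S,

S = 1 for men, 2 for women, converted at 239.006 kcal/MJ; the equation is
pluggable and pinned by hand-computed regression fixtures. Goldberg
screening compares the 4-day mean energy intake to BMR: ratios <1.02,
1.02 to <2.35 and >=2.35 flag under-, plausible and overreporting. The
cut-offs are constants derived under a sedentary physical activity level
of 1.55, which is recorded as configuration metadata, not recomputed.

## Association analysis

Group comparisons of total-diet scores use the independent t test for
two-level groupings and one-way ANOVA otherwise, with all-pairs
Bonferroni-corrected post hoc tests (compact letter display) only when the
overall ANOVA p < 0.05.

Participants are split into tertiles of the total-diet score; ties take
average ranks broken by stable input order, so assignment is deterministic
and group sizes differ by at most one. The tertile GLM regresses each
intake outcome on the tertile category plus categorical covariates (sex,
age band <40/40–59/>=60, weight status, reporting status, survey year),
fitted by OLS with treatment coding. Adjusted means are
population-marginal: each tertile's prediction averaged over the observed
covariate distribution, which reduces exactly to raw tertile means when
covariates are omitted or orthogonal. The trend p-value refits the model
with the tertile as an ordinal 1/2/3 score. Unobserved covariate levels
are dropped with a warning. No correction is applied across outcome rows;
the analysis is explicitly exploratory.

## Synthetic-record generator

No individual-level dietary records are distributable with this package,
so the generator emulates the population structure the pipeline is meant
to measure, and every default is fixed to study-scale conditions:

* 600 participants (45 % male), ages ~N(47, 13) truncated to 20–81,
  heights/weights by sex giving BMI ≈ 23, survey-year labels 2003/2013 in
  the study's proportions, four diary days each;
* meal energy shares averaging 20/31/39/10 % for
  breakfast/lunch/dinner/snacks — the closest exact decomposition of the
  ~21/32/40/11 % pattern, since per-capita contributions must sum to
  100 %;
* breakfast/lunch/dinner starting around 07:28/12:32/19:25 with
  participant-level SDs near 46/32/56 minutes (person mean plus day
  noise, clipped to non-overlapping windows);
* snack counts per day from a beta-binomial on 0–8 moment-matched to
  mean 1.8, SD 1.3;
* per-day meal-skipping probabilities set so ~88/92/97 % of participants
  eat breakfast/lunch/dinner on all four days;
* a 15-food-group × 4-meal-type allocation matrix whose rows are the
  target per-capita contribution patterns (e.g. confectioneries
  3/10/8/79 %), with daily energy anchored to each person's BMR so the
  EI:BMR distribution is centred near 1.7 with realistic Goldberg tails.

**Calibration is analytic and happens before any sampling.** Three facts
make naive sampling miss its targets: skipped meals and zero-snack days
renormalise the day's energy shares; the classifier's overlap rule folds
a fraction λ of snack content into main meals; and within-meal group
sampling must be simultaneously consistent with the allocation rows and
the meal shares. The generator therefore (1) solves the day-level
Dirichlet base weights by a fixed point over the 16 meal/snack presence
patterns so the *unconditional* mean shares hit their targets — exact
because a Dirichlet renormalised to a subset is again Dirichlet with the
subset's expectations; (2) computes λ in closed form from the overlap
rate, the snack-count distribution and main-meal presence, and
pre-corrects the allocation matrix so the *pipeline-measured*
contribution matrix matches the configured targets; and (3) solves the
daily group energy shares p by constrained least squares so that
`Σ_g p_g · A[g, m]` equals each meal's share target. Within a meal, line
energy shares are a symmetric Dirichlet independent of the sampled
groups, which makes expected group energy shares exactly the sampling
probabilities for any line count; amounts are back-solved from line
energies, so each day's line energies sum exactly to the drawn daily
energy.

Non-energetic beverages carry almost no energy and would otherwise appear
as absurd multi-kilogram lines; they are instead generated as bounded
side-lines (a cup of tea, coffee or plain water accompanying an
occasion), whose host occasion is solved with the same presence fixed
point so the group's contribution pattern is preserved, and whose small
energy is deducted from the host's budget to keep the day total exact.

Person-level heterogeneity uses mean-preserving Dirichlet tilts of the
share weights and of each meal's group distribution (concentrations 36
and 60), plus person-level meal-time and energy preferences; day-to-day
variation is independent around the person means. Anomaly days exercise
the classifier: ~9.5 % of days place one snack inside a main meal's time
interval (the merge rule), and ~0.4 % record a snack into a main-meal
diary section (the multiple-entry rule) — rates that reproduce the
rarity of both events at study scale (roughly 240 and 10 cases per 2 556
participant-days).

**What the generator does not emulate**, and hence what passing tests do
not show about real data: day-to-day intake is conditionally independent
given the person (real records autocorrelate, and habitual never-snackers
are underrepresented — the never-snacked-on-any-day rate is near zero
here versus ~7 % in field data); group preferences are drawn per meal
type independently, so between-meal quality correlations are near zero
rather than weakly positive; composite dishes are not disaggregated (each
food code belongs to exactly one group); the bundled ~50-food composition
table is a fixture with plausible—not reference—values, energies set
Atwater-consistent by construction; and no seasonality, weekday or
secular (2003 vs 2013) intake differences exist beyond the survey-year
label.

## Numerical conventions and problem sizes

Clock strings are parsed as `HH:MM`; amounts are stored as floats and
written with full precision, so record round-trips are exact. The
composition-table validator enforces non-negative values, one group per
code and Atwater consistency within 25 % (5 kcal absolute floor for
near-zero-energy beverages). Zero-energy strata propagate as missing, and
zero-total variables report missing contributions rather than NaN
arithmetic. Analyses and calibration checks run at n = 600 (the study
scale); the allocation-fidelity property is checked at n = 2000 where
sampling noise per contribution cell is below one percentage point; the
trend-test type-I error uses 2000 null simulations of n = 60. All
randomness flows from a single seed; rerunning any script with the same
seed reproduces its outputs byte-for-byte.
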