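"""BMI classification and Goldberg energy-reporting screening.

Misreporting of energy intake is screened with the Goldberg approach: the
ratio of reported mean daily energy intake (EI) to estimated basal
metabolic rate (BMR) is compared against cut-offs derived under an assumed
sedentary physical activity level of 1.55 — EI:BMR < 1.02 flags
underreporting, 1.02 <= ratio < 2.35 plausible reporting and
ratio >= 2.35 overreporting.

The default BMR estimate is the Japanese-adult equation on weight, height,
age and sex:

    BMR [MJ/d] = 0.1238 + 0.0481 W[kg] + 0.0234 H[cm] - 0.0138 A[y] - 0.5473 S

with S = 1 for men and 2 for women, converted at 239.006 kcal/MJ. Any
equation with the same signature can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .records_model import Participant, RecordsError

KCAL_PER_MJ = 239.006

GOLDBERG_UNDER = 1.02
GOLDBERG_OVER = 2.35
#: Physical activity level under which the cut-offs above were derived.
GOLDBERG_PAL = 1.55

BMI_UNDERWEIGHT = 18.5
BMI_OVERWEIGHT = 25.0


@dataclass
class ScreeningResult:
    participant_id: str
    bmi: float
    weight_status: str       # underweight | normal | overweight
    bmr_kcal: float
    ei_kcal: float
    ei_bmr_ratio: float
    reporting_status: str    # under | plausible | over


def classify_weight(bmi: float) -> str:
    """BMI bands: <18.5 underweight, 18.5 to <25 normal, >=25 overweight."""
    if bmi <= 0:
        raise RecordsError(f"non-positive BMI {bmi}")
    if bmi < BMI_UNDERWEIGHT:
        return "underweight"
    if bmi < BMI_OVERWEIGHT:
        return "normal"
    return "overweight"


def bmr_japanese_adult(participant: Participant) -> float:
    """Default Japanese-adult BMR equation (kcal/d); see module docstring."""
    s = 1.0 if participant.sex == "male" else 2.0
    mj = (0.1238 + 0.0481 * participant.weight_kg
          + 0.0234 * participant.height_cm - 0.0138 * participant.age
          - 0.5473 * s)
    return mj * KCAL_PER_MJ


def estimate_bmr(participant: Participant,
                 equation: Callable[[Participant], float] = bmr_japanese_adult
                 ) -> float:
    """Estimate BMR with a pluggable equation; rejects non-positive output."""
    bmr = equation(participant)
    if not bmr > 0:
        raise RecordsError(
            f"BMR equation returned non-positive value {bmr} for "
            f"participant {participant.id}")
    return bmr


def classify_reporting(ei_kcal: float, bmr_kcal: float) -> str:
    """Goldberg status from the EI:BMR ratio (boundaries as documented)."""
    if bmr_kcal <= 0:
        raise RecordsError(f"non-positive BMR {bmr_kcal}")
    ratio = ei_kcal / bmr_kcal
    if ratio < GOLDBERG_UNDER:
        return "under"
    if ratio < GOLDBERG_OVER:
        return "plausible"
    return "over"


def screen_population(participants: Sequence[Participant],
                      intakes: pd.DataFrame,
                      equation: Callable[[Participant], float] = bmr_japanese_adult
                      ) -> pd.DataFrame:
    """Screen every participant; EI is the mean daily total-stratum energy.

    Returns a frame indexed by participant id with bmi, weight_status,
    bmr_kcal, ei_kcal, ei_bmr_ratio and reporting_status columns.
    """
    energy = intakes.xs("total", level="stratum")["energy_kcal"]
    rows = []
    for p in participants:
        bmr = estimate_bmr(p, equation)
        ei = float(energy.loc[p.id])
        rows.append(ScreeningResult(
            participant_id=p.id, bmi=p.bmi,
            weight_status=classify_weight(p.bmi),
            bmr_kcal=bmr, ei_kcal=ei, ei_bmr_ratio=ei / bmr,
            reporting_status=classify_reporting(ei, bmr)))
    return pd.DataFrame([vars(r) for r in rows]).set_index("participant_id")
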