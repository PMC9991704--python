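"""HEI-2015 and NRF9.3 diet-quality scoring.

**HEI-2015** (Healthy Eating Index 2015) is a 13-component, 100-point
compliance score against the 2015-2020 Dietary Guidelines for Americans:
nine adequacy components (total fruits, whole fruits, total vegetables,
greens and beans, whole grains, dairy, total protein foods, seafood and
plant proteins, fatty-acid ratio) and four moderation components (refined
grains, sodium, added sugars, saturated fats). Intakes are energy-adjusted
by the density method — amount per 1000 kcal or percentage of energy —
except for the fatty-acid ratio (MUFA + PUFA) / SFA, which is unadjusted.
Each component scores linearly between its zero and maximum thresholds,
clamped at both ends; the thresholds ship as a packaged YAML table so the
food-to-component mapping stays explicit and swappable.

**NRF9.3** (Nutrient-Rich Food Index 9.3) sums the percentage of reference
daily values of nine qualifying nutrients (protein, fibre, vitamins A, C
and D, Ca, Fe, K, Mg; each capped at 100 %) and subtracts the (uncapped)
%DV of three disqualifying nutrients (added sugars, saturated fats,
sodium), for a maximum of 900. Intakes are energy-adjusted by the density
method and re-scaled to the sex- and age-specific Estimated Energy
Requirement (EER, moderate physical activity) before comparison with the
daily values; meal strata use the same full-day EER on the stratum's own
energy.

Both scores are invariant to rescaling every food amount by a common
factor, and a zero-energy stratum has no defined score (returned as NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .records_model import Participant, RecordsError

HEI_COMPONENTS = (
    "total_fruits", "whole_fruits", "total_vegetables", "greens_and_beans",
    "whole_grains", "dairy", "total_protein_foods", "seafood_plant_proteins",
    "fatty_acids", "refined_grains", "sodium", "added_sugars",
    "saturated_fats",
)

NRF_QUALIFYING = ("protein_g", "fibre_g", "vita_ugrae", "vitc_mg", "vitd_ug",
                  "ca_mg", "fe_mg", "k_mg", "mg_mg")
NRF_DISQUALIFYING = ("added_sugar_g", "sfa_g", "na_mg")


# ---------------------------------------------------------------------------
# Standards and reference tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HEIStandard:
    name: str
    direction: str        # adequacy | moderation
    basis: str            # per_1000 | pct_energy | ratio
    source: str
    max_points: float
    max_threshold: float
    zero_threshold: float

    def __post_init__(self) -> None:
        if self.direction == "adequacy":
            if not self.zero_threshold < self.max_threshold:
                raise RecordsError(f"{self.name}: adequacy thresholds inverted")
        elif self.direction == "moderation":
            if not self.max_threshold < self.zero_threshold:
                raise RecordsError(f"{self.name}: moderation thresholds inverted")
        else:
            raise RecordsError(f"{self.name}: unknown direction {self.direction!r}")


def load_hei_standards(path: str | Path | None = None) -> dict[str, HEIStandard]:
    """Load HEI component standards (packaged defaults if *path* is None)."""
    if path is None:
        text = resources.files("mealscope.data").joinpath(
            "hei2015_standards.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)["components"]
    standards = {name: HEIStandard(name=name, **cfg) for name, cfg in raw.items()}
    total = sum(s.max_points for s in standards.values())
    if abs(total - 100.0) > 1e-9:
        raise RecordsError(f"HEI component max points sum to {total}, not 100")
    return standards


class NRFReferenceTable:
    """Sex x age-band daily values and EERs for the NRF9.3 score."""

    def __init__(self, raw: Mapping):
        self.bands = raw["age_bands"]
        self.eer = raw["eer_kcal"]
        self.qualifying = raw["qualifying"]
        self.disq = raw["disqualifying"]
        self.goldberg = raw.get("goldberg", {})
        for sex in ("male", "female"):
            for band in (b["name"] for b in self.bands):
                if self.eer[sex][band] <= 0:
                    raise RecordsError(f"non-positive EER for {sex} {band}")
                for nut, tab in self.qualifying.items():
                    if tab[sex][band] <= 0:
                        raise RecordsError(f"non-positive DV for {nut} {sex} {band}")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "NRFReferenceTable":
        if path is None:
            text = resources.files("mealscope.data").joinpath(
                "dri_reference.yaml").read_text()
        else:
            text = Path(path).read_text()
        return cls(yaml.safe_load(text))

    def band(self, age: int) -> str:
        for b in self.bands:
            if b["min_age"] <= age <= b["max_age"]:
                return b["name"]
        raise RecordsError(f"no reference age band covers age {age}")

    def eer_kcal(self, sex: str, age: int) -> float:
        return float(self.eer[sex][self.band(age)])

    def daily_values(self, sex: str, age: int) -> dict[str, float]:
        """Daily values for all 12 nutrients (disqualifying derived from EER)."""
        band = self.band(age)
        eer = self.eer_kcal(sex, age)
        dv = {nut: float(tab[sex][band]) for nut, tab in self.qualifying.items()}
        dv["added_sugar_g"] = self.disq["added_sugar_pct_energy_limit"] / 100.0 * eer / 4.0
        dv["sfa_g"] = self.disq["sfa_pct_energy_limit"] / 100.0 * eer / 9.0
        dv["na_mg"] = self.disq["salt_equivalent_g"][sex] / 2.54 * 1000.0
        return dv


# ---------------------------------------------------------------------------
# HEI-2015
# ---------------------------------------------------------------------------

def hei_component_score(value: float, standard: HEIStandard) -> float:
    """Score one component: linear between thresholds, clamped at both ends."""
    if value < 0:
        raise RecordsError(f"{standard.name}: negative intake value {value}")
    if standard.direction == "adequacy":
        frac = ((value - standard.zero_threshold)
                / (standard.max_threshold - standard.zero_threshold))
    else:
        frac = ((standard.zero_threshold - value)
                / (standard.zero_threshold - standard.max_threshold))
    return standard.max_points * min(max(frac, 0.0), 1.0)


def hei_density_value(intake: Mapping[str, float], standard: HEIStandard) -> float:
    """Energy-adjusted value of one component for an intake vector."""
    energy = float(intake["energy_kcal"])
    if standard.basis == "ratio":
        sfa = float(intake["sfa_g"])
        unsat = float(intake["mufa_g"]) + float(intake["pufa_g"])
        if sfa <= 0:
            # limit convention: no saturated fat with any unsaturated fat is
            # ideal; neither fat at all leaves the ratio at its floor
            return math.inf if unsat > 0 else 0.0
        return unsat / sfa
    if standard.source == "na_g":
        amount = float(intake["na_mg"]) / 1000.0
    else:
        amount = float(intake[standard.source])
    if standard.basis == "per_1000":
        return amount * 1000.0 / energy
    if standard.basis == "pct_energy":
        factor = 9.0 if standard.source == "sfa_g" else 4.0
        return 100.0 * factor * amount / energy
    raise RecordsError(f"unknown basis {standard.basis!r}")


def hei_score(intake: Mapping[str, float],
              standards: dict[str, HEIStandard]) -> dict[str, float]:
    """All 13 HEI-2015 component scores and the total for one diet stratum.

    Returns NaN scores for a zero-energy stratum (no defined density).
    """
    energy = float(intake["energy_kcal"])
    if not energy > 0:
        return {**{name: np.nan for name in standards}, "hei_total": np.nan}
    scores = {}
    for name, std in standards.items():
        value = hei_density_value(intake, std)
        if math.isinf(value):
            scores[name] = std.max_points
        else:
            scores[name] = hei_component_score(value, std)
    scores["hei_total"] = sum(scores.values())
    return scores


# ---------------------------------------------------------------------------
# NRF9.3
# ---------------------------------------------------------------------------

def nrf_score(intake: Mapping[str, float], participant: Participant,
              refs: NRFReferenceTable) -> dict[str, float]:
    """NRF9.3 component percentages and total for one diet stratum.

    Each nutrient density (per kcal) is re-scaled to the participant's EER
    and expressed as % of the reference daily value; qualifying components
    are capped at 100, disqualifying ones are not.
    """
    energy = float(intake["energy_kcal"])
    names = [*NRF_QUALIFYING, *NRF_DISQUALIFYING]
    if not energy > 0:
        return {**{f"nrf_{n}": np.nan for n in names}, "nrf_total": np.nan}
    eer = refs.eer_kcal(participant.sex, participant.age)
    dv = refs.daily_values(participant.sex, participant.age)
    out = {}
    qual_sum = disq_sum = 0.0
    for nut in NRF_QUALIFYING:
        pct = min(100.0 * (float(intake[nut]) / energy) * eer / dv[nut], 100.0)
        out[f"nrf_{nut}"] = pct
        qual_sum += pct
    for nut in NRF_DISQUALIFYING:
        pct = 100.0 * (float(intake[nut]) / energy) * eer / dv[nut]
        out[f"nrf_{nut}"] = pct
        disq_sum += pct
    out["nrf_total"] = qual_sum - disq_sum
    return out


# ---------------------------------------------------------------------------
# Population scoring and reference diets
# ---------------------------------------------------------------------------

def score_population(intakes: pd.DataFrame, participants: list[Participant],
                     standards: dict[str, HEIStandard] | None = None,
                     refs: NRFReferenceTable | None = None) -> pd.DataFrame:
    """Score every participant x stratum row of an intake frame.

    Returns a frame indexed like *intakes* with HEI component columns,
    ``hei_total``, NRF component columns and ``nrf_total``. Strata never
    consumed score NaN throughout.
    """
    standards = standards or load_hei_standards()
    refs = refs or NRFReferenceTable.load()
    by_id = {p.id: p for p in participants}
    rows = []
    for (pid, stratum), row in intakes.iterrows():
        intake = row.to_dict()
        scores = hei_score(intake, standards)
        scores.update(nrf_score(intake, by_id[pid], refs))
        rows.append(scores)
    return pd.DataFrame(rows, index=intakes.index)


def perfect_hei_intake(standards: dict[str, HEIStandard] | None = None,
                       energy_kcal: float = 2000.0) -> dict[str, float]:
    """A synthetic intake that saturates every HEI-2015 component.

    Adequacy components sit exactly at their maximum-score thresholds;
    moderation components sit at or below theirs (zero added sugars and
    refined grains, low sodium, saturated fat low in %E yet dominated by
    unsaturated fat for the ratio component).
    """
    standards = standards or load_hei_standards()
    scale = energy_kcal / 1000.0
    intake = {c: 0.0 for c in ("energy_kcal", "protein_g", "fat_g", "sfa_g",
                               "mufa_g", "pufa_g", "carb_g", "added_sugar_g",
                               "alcohol_g", "na_mg")}
    intake["energy_kcal"] = energy_kcal
    for name, std in standards.items():
        if std.basis == "per_1000" and std.direction == "adequacy":
            intake[std.source] = std.max_threshold * scale
    intake["heq_refined_grains"] = 0.0
    intake["sfa_g"] = 1.0                     # 9 kcal -> well under 8 %E
    intake["mufa_g"] = intake["pufa_g"] = 2.0  # ratio 4.0 >= 2.5
    intake["fat_g"] = 5.0
    intake["na_mg"] = 400.0                   # 0.2 g/1000 kcal
    intake["added_sugar_g"] = 0.0
    return intake


def worst_hei_intake(standards: dict[str, HEIStandard] | None = None,
                     energy_kcal: float = 2000.0) -> dict[str, float]:
    """A synthetic intake that fails every HEI-2015 component (score 0)."""
    standards = standards or load_hei_standards()
    scale = energy_kcal / 1000.0
    intake = {c: 0.0 for c in ("energy_kcal", "protein_g", "fat_g", "carb_g",
                               "alcohol_g")}
    intake["energy_kcal"] = energy_kcal
    for name, std in standards.items():
        if std.direction == "adequacy" and std.basis == "per_1000":
            intake[std.source] = 0.0
    intake["heq_refined_grains"] = standards["refined_grains"].zero_threshold * scale
    intake["na_mg"] = standards["sodium"].zero_threshold * 1000.0 * scale
    intake["added_sugar_g"] = (standards["added_sugars"].zero_threshold / 100.0
                               * energy_kcal / 4.0)
    intake["sfa_g"] = (standards["saturated_fats"].zero_threshold / 100.0
                       * energy_kcal / 9.0)
    intake["mufa_g"] = intake["pufa_g"] = 0.0  # ratio floor -> 0 points
    intake["fat_g"] = intake["sfa_g"]
    return intake


def perfect_nrf_intake(participant: Participant,
                       refs: NRFReferenceTable | None = None,
                       energy_kcal: float = 2000.0) -> dict[str, float]:
    """A synthetic intake reaching 100 %DV for all nine qualifying nutrients
    with zero disqualifying nutrients (NRF9.3 total 900)."""
    refs = refs or NRFReferenceTable.load()
    eer = refs.eer_kcal(participant.sex, participant.age)
    dv = refs.daily_values(participant.sex, participant.age)
    intake = {n: 0.0 for n in (*NRF_QUALIFYING, *NRF_DISQUALIFYING)}
    intake["energy_kcal"] = energy_kcal
    for nut in NRF_QUALIFYING:
        # slightly above the cap so float rounding cannot land below 100 %DV
        intake[nut] = dv[nut] * energy_kcal / eer * 1.01
    return intake
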