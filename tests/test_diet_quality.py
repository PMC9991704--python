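"""HEI-2015 and NRF9.3 scoring: component arithmetic, ceilings, limit
conventions and the density-method invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealscope.diet_quality import (HEI_COMPONENTS, NRF_DISQUALIFYING,
                                    NRF_QUALIFYING, hei_component_score,
                                    hei_score, nrf_score, perfect_hei_intake,
                                    perfect_nrf_intake, worst_hei_intake)
from mealscope.records_model import Participant, RecordsError

PARTICIPANT = Participant("Q1", "female", 45, 160.0, 55.0, "2013")


def random_intake(rng):
    """A random plausible daily intake vector."""
    intake = {
        "energy_kcal": rng.uniform(900, 3200),
        "protein_g": rng.uniform(20, 120), "fat_g": rng.uniform(20, 120),
        "sfa_g": rng.uniform(0, 40), "mufa_g": rng.uniform(0, 40),
        "pufa_g": rng.uniform(0, 30), "carb_g": rng.uniform(80, 450),
        "added_sugar_g": rng.uniform(0, 80), "alcohol_g": rng.uniform(0, 40),
        "fibre_g": rng.uniform(0, 30), "na_mg": rng.uniform(500, 7000),
        "k_mg": rng.uniform(800, 4000), "ca_mg": rng.uniform(100, 1200),
        "mg_mg": rng.uniform(80, 500), "fe_mg": rng.uniform(2, 20),
        "vita_ugrae": rng.uniform(50, 1500), "vitd_ug": rng.uniform(0, 20),
        "vitc_mg": rng.uniform(10, 250),
    }
    for c in ("heq_total_fruit", "heq_whole_fruit", "heq_total_veg",
              "heq_greens_beans", "heq_dairy"):
        intake[c] = rng.uniform(0, 4)
    for c in ("heq_whole_grains", "heq_refined_grains", "heq_total_protein",
              "heq_seafood_plant"):
        intake[c] = rng.uniform(0, 10)
    return intake


class TestComponentScore:
    def test_adequacy_at_threshold_scores_max(self, hei_standards):
        std = hei_standards["total_fruits"]
        assert hei_component_score(0.8, std) == 5.0
        assert hei_component_score(2.0, std) == 5.0

    def test_adequacy_at_zero_scores_zero(self, hei_standards):
        for name in ("total_fruits", "whole_grains", "dairy"):
            assert hei_component_score(0.0, hei_standards[name]) == 0.0

    def test_moderation_halfway_scores_half(self, hei_standards):
        std = hei_standards["added_sugars"]  # max at 6.5 %E, zero at 26 %E
        halfway = (std.max_threshold + std.zero_threshold) / 2
        assert hei_component_score(halfway, std) == pytest.approx(std.max_points / 2)

    def test_linearity_between_thresholds(self, hei_standards):
        std = hei_standards["sodium"]
        for frac in (0.25, 0.5, 0.75):
            v = std.zero_threshold - frac * (std.zero_threshold - std.max_threshold)
            assert hei_component_score(v, std) == pytest.approx(frac * std.max_points)

    def test_negative_value_rejected(self, hei_standards):
        with pytest.raises(RecordsError):
            hei_component_score(-0.1, hei_standards["total_fruits"])


class TestHEITotal:
    def test_ideal_diet_scores_exactly_100(self, hei_standards):
        scores = hei_score(perfect_hei_intake(hei_standards), hei_standards)
        assert scores["hei_total"] == 100.0

    def test_failing_diet_scores_exactly_0(self, hei_standards):
        scores = hei_score(worst_hei_intake(hei_standards), hei_standards)
        assert scores["hei_total"] == 0.0

    def test_zero_energy_stratum_is_missing(self, hei_standards):
        intake = {k: 0.0 for k in perfect_hei_intake(hei_standards)}
        assert math.isnan(hei_score(intake, hei_standards)["hei_total"])

    def test_zero_sfa_with_unsaturated_fat_gets_full_ratio_points(self, hei_standards):
        intake = perfect_hei_intake(hei_standards)
        intake["sfa_g"] = 0.0
        scores = hei_score(intake, hei_standards)
        assert scores["fatty_acids"] == hei_standards["fatty_acids"].max_points

    def test_zero_fat_entirely_gets_zero_ratio_points(self, hei_standards):
        intake = perfect_hei_intake(hei_standards)
        intake["sfa_g"] = intake["mufa_g"] = intake["pufa_g"] = 0.0
        assert hei_score(intake, hei_standards)["fatty_acids"] == 0.0


class TestNRF:
    def test_saturated_reference_diet_scores_900(self, nrf_refs):
        intake = perfect_nrf_intake(PARTICIPANT, nrf_refs)
        assert nrf_score(intake, PARTICIPANT, nrf_refs)["nrf_total"] == 900.0

    def test_all_zero_nutrients_score_zero(self, nrf_refs):
        intake = {n: 0.0 for n in (*NRF_QUALIFYING, *NRF_DISQUALIFYING)}
        intake["energy_kcal"] = 2000.0
        assert nrf_score(intake, PARTICIPANT, nrf_refs)["nrf_total"] == 0.0

    def test_hand_worked_minus_100(self, nrf_refs):
        """Protein at 50 %DV and sodium at 150 %DV: 50 - 150 = -100."""
        eer = nrf_refs.eer_kcal("female", 45)
        dv = nrf_refs.daily_values("female", 45)
        intake = {n: 0.0 for n in (*NRF_QUALIFYING, *NRF_DISQUALIFYING)}
        intake["energy_kcal"] = 2000.0
        intake["protein_g"] = 0.5 * dv["protein_g"] * 2000.0 / eer
        intake["na_mg"] = 1.5 * dv["na_mg"] * 2000.0 / eer
        assert nrf_score(intake, PARTICIPANT, nrf_refs)["nrf_total"] \
            == pytest.approx(-100.0)

    def test_disqualifying_not_capped(self, nrf_refs):
        dv = nrf_refs.daily_values("female", 45)
        eer = nrf_refs.eer_kcal("female", 45)
        intake = {n: 0.0 for n in (*NRF_QUALIFYING, *NRF_DISQUALIFYING)}
        intake["energy_kcal"] = 2000.0
        intake["na_mg"] = 3.0 * dv["na_mg"] * 2000.0 / eer
        scores = nrf_score(intake, PARTICIPANT, nrf_refs)
        assert scores["nrf_na_mg"] == pytest.approx(300.0)


class TestInvariances:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.2, 5.0))
    def test_amount_scaling_invariance(self, hei_standards, nrf_refs, seed, k):
        """Multiplying every amount by k leaves both scores unchanged."""
        intake = random_intake(np.random.default_rng(seed))
        scaled = {key: k * v for key, v in intake.items()}
        h1 = hei_score(intake, hei_standards)["hei_total"]
        h2 = hei_score(scaled, hei_standards)["hei_total"]
        assert h2 == pytest.approx(h1, abs=1e-9)
        n1 = nrf_score(intake, PARTICIPANT, nrf_refs)["nrf_total"]
        n2 = nrf_score(scaled, PARTICIPANT, nrf_refs)["nrf_total"]
        assert n2 == pytest.approx(n1, rel=1e-12, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotonicity(self, hei_standards, nrf_refs, seed):
        """More of a qualifying nutrient never lowers NRF; more of a
        moderation-component intake never raises HEI."""
        rng = np.random.default_rng(seed)
        intake = random_intake(rng)
        bumped = dict(intake)
        bumped["fibre_g"] *= 1.5
        assert (nrf_score(bumped, PARTICIPANT, nrf_refs)["nrf_total"]
                >= nrf_score(intake, PARTICIPANT, nrf_refs)["nrf_total"] - 1e-9)
        worse = dict(intake)
        worse["na_mg"] *= 1.5
        assert (hei_score(worse, hei_standards)["hei_total"]
                <= hei_score(intake, hei_standards)["hei_total"] + 1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_component_caps(self, hei_standards, nrf_refs, seed):
        intake = random_intake(np.random.default_rng(seed))
        h = hei_score(intake, hei_standards)
        for name in HEI_COMPONENTS:
            assert 0.0 <= h[name] <= hei_standards[name].max_points
        n = nrf_score(intake, PARTICIPANT, nrf_refs)
        for nut in NRF_QUALIFYING:
            assert 0.0 <= n[f"nrf_{nut}"] <= 100.0
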