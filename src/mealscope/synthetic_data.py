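"""Synthetic 4-day weighed dietary records with realistic meal structure.

The generator emulates the population structure that the downstream
pipeline is designed to measure: meal energy shares averaging 21/32/40/11 %
for breakfast/lunch/dinner/snacks, breakfast/lunch/dinner starting around
07:28/12:32/19:25 with realistic spread, a bounded snack frequency (0-8
per day, mean 1.8, SD 1.3), rare meal skipping (about 88/92/97 % of
participants consume breakfast/lunch/dinner on every recording day), and a
strong food-group-to-meal-type dependence (e.g. confectioneries eaten
predominantly as snacks, noodles at lunch, bread and dairy at breakfast).

Everything is calibrated **analytically before any sampling**:

* the stratum share weights of the day-level Dirichlet are solved (over
  the 16 meal/snack presence patterns) so that the *unconditional* mean
  energy shares hit their targets despite skipped meals and zero-snack
  days, exploiting the aggregation property of the Dirichlet under
  renormalisation to a subset;
* the food-to-meal allocation matrix is pre-corrected for the
  classifier's overlap-merging rule, which folds the occasional snack
  recorded during a main meal into that meal, so that the
  pipeline-measured per-capita contribution matrix matches the configured
  targets;
* group sampling weights are solved so the per-meal group mixes are
  simultaneously consistent with the allocation matrix and the meal
  energy shares.

Within a meal, energy is split across lines by a symmetric Dirichlet that
is independent of the sampled food groups; this makes expected group
energy shares exactly equal to the sampling probabilities for any line
count. Amounts are back-solved from line energies, so per-day line
energies sum exactly to the drawn daily energy.

Anomaly days exercise the classifier's special rules: a snack written
into a main-meal diary section (multiple-entry rule) and a snack
overlapping a main meal's time interval (merge rule), at rates echoing
their rarity in real diaries (~0.4 % and ~9.5 % of participant-days).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .records_model import (FOOD_GROUPS, MAIN_MEALS, FoodCompositionTable,
                            FoodRecordLine, Participant, RecordsError)

STRATA4 = ("breakfast", "lunch", "dinner", "snack")


def default_allocation_matrix() -> pd.DataFrame:
    """Target per-capita contribution of each meal type to each food group
    (rows: 15 food groups; columns: breakfast/lunch/dinner/snack; rows sum
    to 1). Anchored on the contribution pattern of Japanese adult diets:
    dinner-dominated potatoes/pulses/vegetables/fish/meat/alcohol, noodles
    at lunch, bread and dairy at breakfast, confectioneries and sweetened
    beverages at snacks, rice and eggs spread over the main meals."""
    rows = {
        "rice":                      (0.19, 0.41, 0.40, 0.00),
        "bread":                     (0.71, 0.15, 0.06, 0.08),
        "noodles":                   (0.10, 0.58, 0.28, 0.04),
        "potatoes":                  (0.10, 0.25, 0.60, 0.05),
        "pulses":                    (0.20, 0.20, 0.55, 0.05),
        "total_vegetables":          (0.14, 0.31, 0.53, 0.02),
        "fruit":                     (0.28, 0.29, 0.26, 0.17),
        "fish":                      (0.12, 0.23, 0.62, 0.03),
        "meat":                      (0.08, 0.27, 0.62, 0.03),
        "eggs":                      (0.33, 0.30, 0.34, 0.03),
        "dairy":                     (0.50, 0.15, 0.12, 0.23),
        "confectioneries":           (0.03, 0.10, 0.08, 0.79),
        "sugar_sweetened_beverages": (0.10, 0.20, 0.18, 0.52),
        "alcoholic_beverages":       (0.04, 0.20, 0.70, 0.06),
        "non_energetic_beverages":   (0.22, 0.27, 0.24, 0.27),
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(STRATA4)).loc[list(FOOD_GROUPS)]


def default_group_energy_shares() -> pd.Series:
    """Baseline fraction of daily energy from each food group (sums to 1);
    the calibration nudges these to be consistent with the meal shares."""
    base = {
        "rice": 0.32, "bread": 0.06, "noodles": 0.07, "potatoes": 0.02,
        "pulses": 0.05, "total_vegetables": 0.06, "fruit": 0.04,
        "fish": 0.08, "meat": 0.09, "eggs": 0.03, "dairy": 0.04,
        "confectioneries": 0.08, "sugar_sweetened_beverages": 0.02,
        "alcoholic_beverages": 0.04,
        # effectively zero: these beverages carry almost no energy and are
        # generated as side-lines outside the energy partition
        "non_energetic_beverages": 0.0,
    }
    return pd.Series(base).loc[list(FOOD_GROUPS)]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-record generator (defaults are the study
    conditions the pipeline is validated against)."""

    n_participants: int = 600
    n_days: int = 4
    seed: int = 0

    # cohort
    sex_ratio_male: float = 0.45
    age_mean: float = 47.0
    age_sd: float = 13.0
    age_range: tuple[int, int] = (20, 81)
    pct_survey_2003: float = 250 / 639
    daily_energy_mean_kcal: dict = field(
        default_factory=lambda: {"male": 2400.0, "female": 1900.0})
    daily_energy_sd_kcal: dict = field(
        default_factory=lambda: {"male": 450.0, "female": 350.0})
    energy_day_cv: float = 0.12

    # meal structure
    # closest exact decomposition of the ~21/32/40/11 % pattern (per-capita
    # contributions must sum to exactly 100 %)
    meal_energy_share_means: tuple = (0.20, 0.31, 0.39, 0.10)
    meal_share_person_concentration: float = 36.0
    meal_share_day_concentration: float = 150.0
    meal_start_means: tuple = (448, 752, 1165)       # minutes since midnight
    meal_start_person_sds: tuple = (45.0, 31.0, 54.0)
    meal_start_day_sds: tuple = (18.0, 15.0, 27.0)
    meal_duration_range: tuple = (10, 40)
    snack_duration_range: tuple = (5, 25)
    all_days_consumption: tuple = (0.88, 0.923, 0.969)
    snack_mean: float = 1.8
    snack_sd: float = 1.3
    snack_max: int = 8

    # food allocation
    food_allocation_matrix: pd.DataFrame = field(
        default_factory=default_allocation_matrix)
    group_energy_shares: pd.Series = field(
        default_factory=default_group_energy_shares)
    group_pref_concentration: float = 60.0
    person_level_variation: bool = True
    lines_per_meal_poisson: float = 2.5     # lines = 3 + Poisson(.)
    second_snack_line_prob: float = 0.4

    # anomalies
    double_entry_rate: float = 0.004
    overlap_rate: float = 0.095
    water_only_rate: float = 0.05
    #: non-energetic beverages ride along as bounded side-lines (a cup of
    #: tea, coffee or water with a meal) rather than through the energy
    #: partition; the host occasion follows the beverage allocation row via
    #: a presence-corrected weight solve
    beverage_lines_per_day: float = 1.0
    water_line_fraction: float = 0.3
    beverage_amount_range: tuple = (120, 350)

    def validate(self) -> None:
        if abs(sum(self.meal_energy_share_means) - 1.0) > 1e-9:
            raise RecordsError("meal energy shares must sum to 1")
        A = self.food_allocation_matrix
        if list(A.index) != list(FOOD_GROUPS) or list(A.columns) != list(STRATA4):
            raise RecordsError("allocation matrix must be 15 food groups x 4 meal types")
        if (A.to_numpy() < 0).any():
            raise RecordsError("allocation matrix entries must be non-negative")
        bad = A.index[(A.sum(axis=1) - 1.0).abs() > 1e-9]
        if len(bad):
            raise RecordsError(f"allocation rows must sum to 1: {list(bad)}")
        if abs(self.group_energy_shares.sum() - 1.0) > 1e-9:
            raise RecordsError("group energy shares must sum to 1")
        for sds in (self.meal_start_person_sds, self.meal_start_day_sds):
            if any(s <= 0 for s in sds):
                raise RecordsError("start-time SDs must be positive")
        if not all(0 <= p <= 1 for p in self.all_days_consumption):
            raise RecordsError("all-days consumption rates must be in [0, 1]")


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Analytic calibration
# ---------------------------------------------------------------------------

def snack_count_pmf(mean: float, sd: float, nmax: int) -> np.ndarray:
    """Moment-matched beta-binomial pmf on 0..nmax (binomial fallback when
    the requested variance is at or below binomial; degenerate at 0 for a
    zero mean)."""
    if mean <= 0:
        pmf = np.zeros(nmax + 1)
        pmf[0] = 1.0
        return pmf
    p = mean / nmax
    if not 0 < p < 1:
        raise RecordsError(f"snack mean {mean} incompatible with support 0..{nmax}")
    binom_var = nmax * p * (1 - p)
    if sd ** 2 <= binom_var + 1e-12:
        pmf = stats.binom.pmf(np.arange(nmax + 1), nmax, p)
    else:
        over = sd ** 2 / binom_var  # (s + n) / (s + 1), s = alpha + beta
        s = (nmax - over) / (over - 1)
        if s <= 0:
            raise RecordsError("snack count SD too large for a beta-binomial")
        pmf = stats.betabinom.pmf(np.arange(nmax + 1), nmax, s * p, s * (1 - p))
    return pmf / pmf.sum()


@dataclass
class Calibration:
    """Derived, deterministic quantities the sampler runs on."""

    presence: np.ndarray           # per-day presence prob of b/l/d/snack
    snack_pmf: np.ndarray
    redirect_fraction: float       # lambda: share of snack content merged into mains
    redirect_to_main: np.ndarray   # rho_m over the three main meals
    share_targets: np.ndarray      # generator-level stratum share targets t
    share_weights: np.ndarray      # Dirichlet base weights w
    allocation_nominal: pd.DataFrame  # lambda-corrected allocation matrix
    group_shares: pd.Series        # solved daily group energy shares p_g
    group_probs: pd.DataFrame      # q[g, m]: within-meal group sampling probs
    beverage_host_weights: np.ndarray  # host-occasion weights for side-lines


def _presence_patterns(presence: np.ndarray):
    """All 16 stratum presence patterns with probabilities; a fully empty
    day is folded into the dinner-only pattern (dinner is forced)."""
    pats = []
    for mask in itertools.product((1, 0), repeat=4):
        prob = float(np.prod([presence[i] if m else 1 - presence[i]
                              for i, m in enumerate(mask)]))
        if prob <= 0:
            continue
        if not any(mask):
            mask = (0, 0, 1, 0)
        pats.append((np.array(mask, bool), prob))
    return pats


def _solve_share_weights(targets: np.ndarray, patterns) -> np.ndarray:
    """Fixed point for Dirichlet base weights w such that
    sum_S P(S) w_m / w(S) = targets_m."""
    active = targets > 0
    w = targets.copy()
    for _ in range(500):
        f = np.zeros(4)
        for mask, prob in patterns:
            mask = mask & active
            tot = w[mask].sum()
            if tot > 0:
                f[mask] += prob * w[mask] / tot
        ratio = np.where((f > 0) & active, targets / np.maximum(f, 1e-300), 1.0)
        w = w * ratio
        w = np.where(active, np.maximum(w, 1e-12), 0.0)
        w /= w.sum()
        if np.max(np.abs(f - targets)[active]) < 1e-12:
            break
    return w


def calibrate(config: GeneratorConfig) -> Calibration:
    config.validate()
    pres_mains = np.array([c ** (1.0 / config.n_days)
                           for c in config.all_days_consumption])
    pmf = snack_count_pmf(config.snack_mean, config.snack_sd, config.snack_max)
    p_snack = 1.0 - pmf[0]
    presence = np.append(pres_mains, p_snack)

    # overlap redirect: expected fraction of snack-stratum content that the
    # classifier merges into a main meal
    main_pats = []
    for mask in itertools.product((1, 0), repeat=3):
        prob = float(np.prod([pres_mains[i] if m else 1 - pres_mains[i]
                              for i, m in enumerate(mask)]))
        if any(mask) and prob > 0:
            main_pats.append((np.array(mask, bool), prob))
    p_any_main = sum(prob for _, prob in main_pats)
    rho = np.zeros(3)
    for mask, prob in main_pats:
        rho[mask] += prob / mask.sum()
    rho = rho / p_any_main if p_any_main > 0 else rho
    inv_k = float(sum(pmf[k] / k for k in range(1, config.snack_max + 1)))
    lam = (config.overlap_rate * p_any_main * inv_k / p_snack
           if p_snack > 0 else 0.0)

    # stratum share targets adjusted for the redirect
    s = np.array(config.meal_energy_share_means, float)
    t = s.copy()
    if p_snack > 0:
        t[3] = s[3] / (1.0 - lam)
        t[:3] = s[:3] - lam * t[3] * rho
    else:
        t[3] = 0.0
    # strata that can never occur get zero target; renormalise the rest
    t = np.where(presence > 0, t, 0.0)
    t /= t.sum()

    patterns = _presence_patterns(presence)
    weights = _solve_share_weights(t, patterns)

    # allocation matrix corrected for the redirect (measured == configured)
    A = config.food_allocation_matrix.to_numpy(float).copy()
    if p_snack > 0 and lam > 0:
        nominal_snack = A[:, 3] / (1.0 - lam)
        A[:, :3] = A[:, :3] - lam * np.outer(nominal_snack, rho)
        A[:, 3] = nominal_snack
        A = np.clip(A, 0.0, None)
        A /= A.sum(axis=1, keepdims=True)
    # strata that never occur: redistribute each food's allocation over the
    # strata that do, so the consistency constraints below stay feasible
    inactive = t <= 0
    if inactive.any():
        A[:, inactive] = 0.0
        rowsum = A.sum(axis=1, keepdims=True)
        fallback = np.tile((~inactive) / (~inactive).sum(), (A.shape[0], 1))
        A = np.where(rowsum > 0, A / np.where(rowsum > 0, rowsum, 1.0),
                     fallback)
    A_nom = pd.DataFrame(A, index=list(FOOD_GROUPS), columns=list(STRATA4))

    # solve daily group energy shares p_g consistent with the meal shares
    p0 = config.group_energy_shares.to_numpy(float)
    active = [m for m in range(4) if t[m] > 0]
    cons = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
    for m in active[:-1]:  # last active constraint is implied by the others
        cons.append({"type": "eq",
                     "fun": lambda p, m=m: float(A[:, m] @ p) - t[m]})
    res = optimize.minimize(lambda p: float(((p - p0) ** 2).sum()), p0,
                            jac=lambda p: 2 * (p - p0),
                            bounds=[(1e-6, 1.0)] * len(p0),
                            constraints=cons, method="SLSQP",
                            options={"maxiter": 500, "ftol": 1e-14})
    if not res.success:
        raise RecordsError(f"group-share calibration failed: {res.message}")
    p_g = pd.Series(res.x, index=list(FOOD_GROUPS))

    # within-meal group sampling probabilities
    W = A * p_g.to_numpy()[:, None]
    colsum = W.sum(axis=0)
    q = np.divide(W, colsum, out=np.zeros_like(W), where=colsum > 0)
    q_df = pd.DataFrame(q, index=list(FOOD_GROUPS), columns=list(STRATA4))

    # beverage side-lines: host weights solved so the unconditional host
    # pattern matches the beverage allocation row despite skipped meals and
    # zero-snack days (same fixed point as the energy shares)
    bev_row = A_nom.loc["non_energetic_beverages"].to_numpy(float)
    bev_row = np.where(t > 0, bev_row, 0.0)
    bev_w = (_solve_share_weights(bev_row / bev_row.sum(), patterns)
             if bev_row.sum() > 0 else bev_row)

    return Calibration(presence=presence, snack_pmf=pmf,
                       redirect_fraction=lam, redirect_to_main=rho,
                       share_targets=t, share_weights=weights,
                       allocation_nominal=A_nom, group_shares=p_g,
                       group_probs=q_df, beverage_host_weights=bev_w)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_MEAL_START_CLIP = {"breakfast": (300, 610), "lunch": (665, 890),
                    "dinner": (965, 1340)}


def _sample_participants(cfg: GeneratorConfig, rng: np.random.Generator
                         ) -> list[Participant]:
    anthro = {"male": (168.0, 6.0, 67.0, 9.0), "female": (155.0, 5.5, 53.0, 7.5)}
    out = []
    for i in range(cfg.n_participants):
        sex = "male" if rng.random() < cfg.sex_ratio_male else "female"
        age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)),
                          cfg.age_range[0], cfg.age_range[1]))
        hm, hs, wm, ws = anthro[sex]
        height = float(np.clip(rng.normal(hm, hs), 135, 195))
        weight = float(np.clip(rng.normal(wm, ws), 35, 130))
        year = "2003" if rng.random() < cfg.pct_survey_2003 else "2013"
        out.append(Participant(f"P{i + 1:04d}", sex, age, round(height, 1),
                               round(weight, 1), year))
    return out


def _pick_nonoverlapping(rng, occupied, lo, hi, dur):
    """Sample a start in [lo, hi] whose [start, start+dur) avoids occupied
    intervals; falls back to appending after the last one."""
    if hi >= lo:
        for _ in range(12):
            start = int(rng.integers(lo, hi + 1))
            if all(start + dur <= s or start >= e for s, e in occupied):
                return start
    last_end = max((e for _, e in occupied), default=lo)
    return int(min(last_end + 5, 1435 - dur))


class _PopulationSampler:
    def __init__(self, cfg: GeneratorConfig, table: FoodCompositionTable):
        self.cfg = cfg
        self.cal = calibrate(cfg)
        self.table = table
        self.water_codes = [c for c in table.codes if table.is_water_only(c)]
        if cfg.water_only_rate > 0 and not self.water_codes:
            raise RecordsError("composition table has no water codes")
        self.bev_codes = [c for c in table.codes_in_group("non_energetic_beverages")
                          if not table.is_water_only(c)]
        self.group_codes = {g: table.codes_in_group(g, energy_bearing=True)
                            for g in FOOD_GROUPS}
        empty = [g for g, codes in self.group_codes.items()
                 if not codes and self.cal.group_shares[g] > 1e-9]
        if empty:
            raise RecordsError(f"no energy-bearing foods for groups: {empty}")
        self.kcal_per_g = (table.frame["energy_kcal"] / 100.0).to_dict()

    # -- person-level draws -------------------------------------------------

    def _person_profile(self, rng):
        cfg, cal = self.cfg, self.cal
        active = cal.share_weights > 0
        v = cal.share_weights.copy()
        if cfg.person_level_variation:
            v[active] = np.maximum(
                rng.dirichlet(cfg.meal_share_person_concentration
                              * cal.share_weights[active]), 1e-8)
        prefs = {}
        for m, meal in enumerate(STRATA4):
            q = cal.group_probs[meal].to_numpy()
            if cfg.person_level_variation and cfg.group_pref_concentration:
                pos = q > 0
                tilted = np.zeros_like(q)
                if pos.any():
                    tilted[pos] = rng.dirichlet(cfg.group_pref_concentration * q[pos])
                prefs[meal] = tilted
            else:
                prefs[meal] = q
        start_pref = {meal: rng.normal(cfg.meal_start_means[i],
                                       cfg.meal_start_person_sds[i])
                      if cfg.person_level_variation else cfg.meal_start_means[i]
                      for i, meal in enumerate(MAIN_MEALS)}
        return v, prefs, start_pref

    # -- occasion content ---------------------------------------------------

    def _emit_lines(self, rng, pid, day, section, start, end, energy, meal,
                    prefs, lines, n_lines):
        q = prefs[meal]
        groups = [FOOD_GROUPS[i]
                  for i in rng.choice(len(FOOD_GROUPS), size=n_lines, p=q)]
        shares = rng.dirichlet(np.full(n_lines, 2.0))
        next_day = end >= 1440
        for g, share in zip(groups, shares):
            codes = self.group_codes[g]
            code = codes[rng.integers(len(codes))]
            amount = energy * share / self.kcal_per_g[code]
            lines.append(FoodRecordLine(pid, day, section, start, end % 1440,
                                        code, float(amount), next_day))

    def _water_line(self, rng, pid, day, section, start, end, lo=100, hi=400):
        code = self.water_codes[rng.integers(len(self.water_codes))]
        lines_end = end % 1440
        return FoodRecordLine(pid, day, section, start, lines_end,
                              code, float(rng.integers(lo, hi)), end >= 1440)

    # -- one participant-day ------------------------------------------------

    def _sample_day(self, rng, participant, day, v, prefs, start_pref,
                    day_energy, lines):
        cfg, cal = self.cfg, self.cal
        present = np.array([rng.random() < cal.presence[m] for m in range(3)]
                           + [False])
        k = int(rng.choice(len(cal.snack_pmf), p=cal.snack_pmf))
        present[3] = k > 0
        if not present.any():
            present[2] = True  # a day with no intake at all is not modelled

        active = (cal.share_weights > 0) & present
        alpha = cfg.meal_share_day_concentration * v
        draw = np.zeros(4)
        draw[active] = rng.dirichlet(alpha[active])
        shares = draw  # stratum energy shares for this day

        # meal intervals
        meal_iv = {}
        for i, meal in enumerate(MAIN_MEALS):
            if not present[i]:
                continue
            lo, hi = _MEAL_START_CLIP[meal]
            start = int(np.clip(round(rng.normal(start_pref[meal],
                                                 cfg.meal_start_day_sds[i])),
                                lo, hi))
            dur = int(rng.integers(*cfg.meal_duration_range, endpoint=True))
            meal_iv[meal] = (start, start + dur)

        # snack intervals in the gaps between meals
        nominal = {m: (cfg.meal_start_means[i], cfg.meal_start_means[i] + 25)
                   for i, m in enumerate(MAIN_MEALS)}
        iv = {m: meal_iv.get(m, nominal[m]) for m in MAIN_MEALS}
        windows = [(iv["breakfast"][1] + 15, iv["lunch"][0] - 30),
                   (iv["lunch"][1] + 15, iv["dinner"][0] - 30),
                   (iv["dinner"][1] + 10, 1405)]
        win_p = np.array([0.20, 0.45, 0.35])
        occupied = list(meal_iv.values())
        snack_iv = []
        for _ in range(k):
            dur = int(rng.integers(*cfg.snack_duration_range, endpoint=True))
            w = int(rng.choice(3, p=win_p))
            lo, hi = windows[w]
            start = _pick_nonoverlapping(rng, occupied, lo, max(lo, hi - dur), dur)
            snack_iv.append((start, start + dur))
            occupied.append(snack_iv[-1])

        # anomales: a snack overlapping a main meal (exercises the merge
        # rule) and a snack written into a main-meal section (exercises the
        # multiple-entry rule)
        overlap_idx = None
        double_idx = None
        mains_present = [m for m in MAIN_MEALS if m in meal_iv]
        if (k > 0 and mains_present and rng.random() < cfg.overlap_rate):
            overlap_idx = 0
            host = mains_present[rng.integers(len(mains_present))]
            h0, h1 = meal_iv[host]
            start = int(rng.integers(h0 + 1, max(h0 + 2, h1 - 2)))
            snack_iv[0] = (start, start + int(rng.integers(3, 15)))
        if (k > 1 and "breakfast" in meal_iv
                and rng.random() < cfg.double_entry_rate):
            double_idx = k - 1 if overlap_idx != k - 1 else None

        # energy budgets per occasion
        pid = participant.id
        budgets: dict = {}
        for i, meal in enumerate(MAIN_MEALS):
            if meal in meal_iv:
                budgets[meal] = day_energy * shares[i]
        snack_split = rng.dirichlet(np.full(k, 2.0)) if k > 0 else []
        for j in range(k):
            budgets[j] = day_energy * shares[3] * snack_split[j]

        def occasion_of(key):
            if key in MAIN_MEALS:
                start, end = meal_iv[key]
                return key, start, end
            start, end = snack_iv[key]
            section = "breakfast" if key == double_idx else "snack"
            return section, start, end

        # beverage side-lines (tea, coffee, plain water) with bounded
        # amounts; their small energy comes out of the host's budget so the
        # day total is conserved exactly
        host_w = np.asarray(cal.beverage_host_weights, float).copy()
        for i, meal in enumerate(MAIN_MEALS):
            if meal not in meal_iv:
                host_w[i] = 0.0
        if k == 0:
            host_w[3] = 0.0
        n_bev = (int(rng.poisson(cfg.beverage_lines_per_day))
                 if host_w.sum() > 0 and (self.bev_codes or self.water_codes)
                 else 0)
        for _ in range(n_bev):
            m = int(rng.choice(4, p=host_w / host_w.sum()))
            key = MAIN_MEALS[m] if m < 3 else int(rng.integers(k))
            section, start, end = occasion_of(key)
            water = rng.random() < cfg.water_line_fraction
            codes = (self.water_codes if water and self.water_codes
                     else self.bev_codes or self.water_codes)
            code = codes[rng.integers(len(codes))]
            amount = float(rng.integers(*cfg.beverage_amount_range,
                                        endpoint=True))
            energy = amount * self.kcal_per_g[code]
            if energy > 0.4 * budgets[key]:
                amount *= 0.4 * budgets[key] / energy
                energy = 0.4 * budgets[key]
            budgets[key] -= energy
            lines.append(FoodRecordLine(pid, day, section, start, end % 1440,
                                        code, amount, end >= 1440))

        # food lines against the remaining budgets
        for meal in MAIN_MEALS:
            if meal not in meal_iv:
                continue
            section, start, end = occasion_of(meal)
            n_lines = 3 + int(rng.poisson(cfg.lines_per_meal_poisson))
            self._emit_lines(rng, pid, day, section, start, end,
                             budgets[meal], meal, prefs, lines, n_lines)
        for j in range(k):
            section, start, end = occasion_of(j)
            n_lines = 1 + int(rng.random() < cfg.second_snack_line_prob)
            self._emit_lines(rng, pid, day, section, start, end,
                             budgets[j], "snack", prefs, lines, n_lines)

        # an excluded water-only occasion now and then
        if rng.random() < cfg.water_only_rate:
            dur = int(rng.integers(5, 15))
            w = int(rng.choice(3, p=win_p))
            lo, hi = windows[w]
            start = _pick_nonoverlapping(rng, occupied, lo, max(lo, hi - dur), dur)
            lines.append(self._water_line(rng, pid, day, "snack",
                                          start, start + dur, 150, 400))

    def run(self) -> tuple[list[Participant], list[FoodRecordLine]]:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        participants = _sample_participants(cfg, rng)
        lines: list[FoodRecordLine] = []
        # energy is anchored to each person's BMR so the EI:BMR spread is
        # realistic: the configured sex-level mean/SD are mapped to a mean
        # and SD of the person-level EI:BMR ratio at the cohort-typical BMR
        from .misreporting import bmr_japanese_adult
        bmr_ref = {
            sex: bmr_japanese_adult(Participant(
                "ref", sex, int(cfg.age_mean),
                168.0 if sex == "male" else 155.0,
                67.0 if sex == "male" else 53.0, "2013"))
            for sex in ("male", "female")}
        for part in participants:
            v, prefs, start_pref = self._person_profile(rng)
            ref = bmr_ref[part.sex]
            pal = cfg.daily_energy_mean_kcal[part.sex] / ref
            pal_sd = cfg.daily_energy_sd_kcal[part.sex] / ref
            ratio = float(np.clip(rng.normal(pal, pal_sd), 0.85, 3.2))
            person_energy = max(ratio * bmr_japanese_adult(part), 1200.0)
            for day in range(1, cfg.n_days + 1):
                day_energy = max(float(rng.normal(
                    person_energy, cfg.energy_day_cv * person_energy)), 800.0)
                self._sample_day(rng, part, day, v, prefs, start_pref,
                                 day_energy, lines)
        return participants, lines


def generate_population(config: GeneratorConfig,
                        table: FoodCompositionTable | None = None
                        ) -> tuple[list[Participant], list[FoodRecordLine]]:
    """Generate a cohort of participants with n_days of diary lines each.

    Deterministic given ``config.seed``. See the module docstring for the
    structure the defaults are calibrated to.
    """
    table = table or FoodCompositionTable.default()
    return _PopulationSampler(config, table).run()


# ---------------------------------------------------------------------------
# Hand-worked classifier fixture
# ---------------------------------------------------------------------------

def generate_worked_fixtures() -> tuple[list[FoodRecordLine], pd.DataFrame]:
    """A small hand-written record set covering every classifier branch,
    with its expected final occasion labels.

    Returns ``(lines, expected)`` where *expected* has one row per final
    occasion: participant_id, day_index, label, start_time, end_time,
    n_lines.
    """
    L = FoodRecordLine
    lines = [
        # WF01: plain day -- three meals and an afternoon snack
        L("WF01", 1, "breakfast", 440, 460, "ric01", 150.0),
        L("WF01", 1, "breakfast", 440, 460, "egg01", 50.0),
        L("WF01", 1, "lunch", 750, 770, "nod02", 250.0),
        L("WF01", 1, "dinner", 1160, 1190, "fsh01", 80.0),
        L("WF01", 1, "dinner", 1160, 1190, "ric01", 150.0),
        L("WF01", 1, "snack", 900, 910, "cnf01", 40.0),
        # WF02: water-only occasion is excluded; water + food is retained
        L("WF02", 1, "breakfast", 420, 440, "brd01", 60.0),
        L("WF02", 1, "breakfast", 420, 440, "wat01", 200.0),
        L("WF02", 1, "snack", 600, 605, "wat01", 250.0),
        # WF03: two entries in the breakfast section -> first stays
        # breakfast, second becomes a snack
        L("WF03", 1, "breakfast", 420, 440, "ric01", 140.0),
        L("WF03", 1, "breakfast", 600, 610, "fru02", 100.0),
        # WF04: snack inside lunch, no earlier lunch -> merged, lunch label
        L("WF04", 1, "lunch", 720, 750, "ric02", 200.0),
        L("WF04", 1, "snack", 730, 740, "neb01", 150.0),
        L("WF04", 1, "dinner", 1150, 1180, "mea02", 120.0),
        # WF05: second lunch-section entry overlapping a snack after lunch
        # was already eaten -> relabelled and merged as one snack
        L("WF05", 1, "lunch", 720, 740, "nod01", 300.0),
        L("WF05", 1, "lunch", 900, 920, "cnf03", 30.0),
        L("WF05", 1, "snack", 905, 915, "neb02", 150.0),
        # WF06: two overlapping snacks merge into one snack
        L("WF06", 1, "breakfast", 430, 450, "dai01", 200.0),
        L("WF06", 1, "snack", 600, 610, "cnf04", 60.0),
        L("WF06", 1, "snack", 605, 615, "ssb01", 350.0),
    ]
    expected = pd.DataFrame(
        [("WF01", 1, "breakfast", 440, 460, 2),
         ("WF01", 1, "lunch", 750, 770, 1),
         ("WF01", 1, "snack", 900, 910, 1),
         ("WF01", 1, "dinner", 1160, 1190, 2),
         ("WF02", 1, "breakfast", 420, 440, 2),
         ("WF03", 1, "breakfast", 420, 440, 1),
         ("WF03", 1, "snack", 600, 610, 1),
         ("WF04", 1, "lunch", 720, 750, 2),
         ("WF04", 1, "dinner", 1150, 1180, 1),
         ("WF05", 1, "lunch", 720, 740, 1),
         ("WF05", 1, "snack", 900, 920, 2),
         ("WF06", 1, "breakfast", 430, 450, 1),
         ("WF06", 1, "snack", 600, 615, 2)],
        columns=["participant_id", "day_index", "label", "start_time",
                 "end_time", "n_lines"])
    return lines, expected


def fixture_participants() -> list[Participant]:
    """Participants matching the worked fixture records."""
    return [Participant(f"WF{i:02d}", "female" if i % 2 else "male",
                        30 + 5 * i, 160.0, 55.0, "2013") for i in range(1, 7)]
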