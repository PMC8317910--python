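"""DHS-like birth-history simulator with known ground truth.

Generates women aged 15-49 and their children in the shape of a survey child
recode: per-woman children-ever-born / children-dead counts, per-child birth
dates (century-month codes), survival status and age at death in months,
parental education, household covariates and sampling weights.

Mortality follows a piecewise-constant under-five baseline hazard on
[0, 60) months, scaled per child by ``exp(linear predictor)`` of the PEH
(parental educational homogamy) category and any configured covariate effects
-- proportional hazards hold by construction.  Fertility is a piecewise
age-dependent birth process (age-specific fertility rates per 5-year group)
with a shifted-gamma minimum spacing between births so preceding-birth-interval
categories are populated.  Children alive at the interview are censored at
their current age; every programmed quantity is recoverable through the
:func:`true_q5` closed-form oracle.

Randomness is organised as one root seed from which woman-level sub-streams
are derived deterministically per woman id, so each woman's record count does
not depend on iteration order; dataset-level draws (child covariates, death
times) use dedicated streams in the deterministic child order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import RelationalLogitStandard, alpha_from_q, survivorship_from_alpha

__all__ = [
    "ConfigError",
    "TimeVaryingEffect",
    "SimulationConfig",
    "generate_population",
    "true_q5",
    "write_child_recode",
    "read_child_recode",
    "baseline_segments_from_standard",
    "exclusions_demo_population",
    "AGE_GROUPS",
]

AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")

#: marginal sampling distributions of the woman-level household covariates
WOMAN_COVARIATES = {
    "residence": (("urban", "rural"), (0.35, 0.65)),
    "religion": (("christian", "muslim", "other"), (0.55, 0.40, 0.05)),
    "wealth": (("poor", "middle", "rich"), (0.40, 0.25, 0.35)),
    "water": (("improved", "unimproved"), (0.60, 0.40)),
    "toilet": (("improved", "unimproved"), (0.45, 0.55)),
    "fuel": (("biomass", "clean"), (0.80, 0.20)),
    "tetanus": (("1+", "none"), (0.75, 0.25)),
    "pod": (("facility", "home", "other"), (0.55, 0.43, 0.02)),
}
CHILD_COVARIATES = {
    "sex": (("male", "female"), (0.512, 0.488)),
    "bw_class": (("<2.5", "2.5-3.49", "3.5+"), (0.10, 0.55, 0.35)),
}

_EDU_WITHIN_LOW = (("none", "primary"), (0.45, 0.55))
_EDU_WITHIN_HIGH = (("secondary", "higher"), (0.75, 0.25))

WOMEN_SCHEMA = [
    "woman_id", "age_group", "wife_edu", "husband_edu", "cohabiting",
    "residence", "religion", "wealth", "water", "toilet", "fuel",
    "anc_visits", "tetanus", "pod", "ceb", "ceb_dead", "weight",
]
CHILDREN_SCHEMA = [
    "child_id", "woman_id", "birth_cmc", "sex", "birth_order", "bw_class",
    "pbi_months", "multiple", "died", "aad_months", "m_age_at_birth",
]


class ConfigError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class TimeVaryingEffect:
    """A deliberately non-proportional covariate effect (diagnostics testing).

    The log hazard ratio of ``covariate == level`` equals ``log_hr_before`` on
    ages ``[0, change_month)`` and ``log_hr_after`` afterwards.
    """

    covariate: str
    level: str
    log_hr_before: float
    log_hr_after: float
    change_month: float = 12.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic survey, with validated invariants.

    Attributes
    ----------
    n_women : int
        Women aged 15-49 to simulate (ages uniform over the range).
    seed : int
        Root seed; the run is fully deterministic given the config.
    education_joint_probs : 4 floats summing to 1
        Joint probability of the four PEH cells (1..4).
    baseline_hazard_segments : list of (start, end, rate)
        Piecewise-constant under-five hazard per month, tiling [0, 60).
    log_hr_peh : 3 floats
        Log hazard ratios of PEH categories 1..3 versus the reference 4.
    covariate_effects : {covariate: {level: log hazard ratio}}
        Additional proportional effects; unlisted levels are the reference.
    fertility_schedule : 7 floats
        Age-specific fertility rates (births per woman-year) for the 5-year
        groups 15-19 .. 45-49.
    interview_cmc : int
        Century-month code of the interview (months since January 1900).
    weight_distribution : (mean, dispersion)
        Sampling weights are gamma with this mean; dispersion is the squared
        coefficient of variation (0 gives constant weights).
    frac_multiple_births, frac_non_cohabiting : float in [0, 1)
        Proportion of twin birth events / of women flagged not cohabiting.
    pbi_min_months, pbi_gamma_shape, pbi_gamma_scale : floats
        Shifted-gamma birth spacing: intervals are at least ``pbi_min_months``
        with a Gamma(shape, scale) excess (months).
    heaping : float in [0, 1]
        Optional age-at-death heaping: with this probability a reported death
        age >= 6 months is rounded to the nearest multiple of 6 (off by
        default; no claim is made about matching any survey's heaping).
    time_varying : TimeVaryingEffect or None
        Optional injected proportional-hazards violation.
    """

    n_women: int = 2000
    seed: int = 0
    education_joint_probs: tuple = (0.35, 0.15, 0.15, 0.35)
    baseline_hazard_segments: tuple = ((0.0, 12.0, 0.0070), (12.0, 24.0, 0.0015), (24.0, 36.0, 0.0009), (36.0, 60.0, 0.0005))
    log_hr_peh: tuple = (0.0, 0.0, 0.0)
    covariate_effects: dict = field(default_factory=dict)
    fertility_schedule: tuple = (0.09, 0.23, 0.25, 0.22, 0.16, 0.08, 0.025)
    interview_cmc: int = 1450
    weight_distribution: tuple = (1.0, 0.0)
    frac_multiple_births: float = 0.015
    frac_non_cohabiting: float = 0.0
    pbi_min_months: float = 9.0
    pbi_gamma_shape: float = 2.0
    pbi_gamma_scale: float = 6.0
    heaping: float = 0.0
    time_varying: TimeVaryingEffect | None = None

    def validate(self) -> None:
        p = np.asarray(self.education_joint_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0):
            raise ConfigError("education_joint_probs must be 4 nonnegative probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError("education_joint_probs must sum to 1 within 1e-12")
        segs = sorted(self.baseline_hazard_segments)
        if not segs:
            raise ConfigError("baseline_hazard_segments must tile [0, 60)")
        t = 0.0
        for s, e, lam in segs:
            if abs(s - t) > 1e-9:
                raise ConfigError("baseline_hazard_segments must tile [0, 60) with no gaps or overlaps")
            if e <= s:
                raise ConfigError("baseline hazard segment has nonpositive width")
            if lam < 0:
                raise ConfigError("hazards must be nonnegative")
            t = e
        if abs(t - 60.0) > 1e-9:
            raise ConfigError("baseline_hazard_segments must end at 60 months")
        if len(self.log_hr_peh) != 3:
            raise ConfigError("log_hr_peh must have 3 entries (categories 1..3 vs reference 4)")
        if len(self.fertility_schedule) != 7 or any(r < 0 for r in self.fertility_schedule):
            raise ConfigError("fertility_schedule must be 7 nonnegative rates")
        if self.n_women <= 0:
            raise ConfigError("n_women must be positive")
        if not 0 <= self.frac_multiple_births < 1:
            raise ConfigError("frac_multiple_births must lie in [0, 1)")
        if not 0 <= self.frac_non_cohabiting < 1:
            raise ConfigError("frac_non_cohabiting must lie in [0, 1)")
        mean, disp = self.weight_distribution
        if mean <= 0 or disp < 0:
            raise ConfigError("weight_distribution requires positive mean and nonnegative dispersion")
        for cov, effects in self.covariate_effects.items():
            levels = self._covariate_levels(cov)
            for lvl in effects:
                if lvl not in levels:
                    raise ConfigError(f"unknown level {lvl!r} for covariate {cov!r}")
        if self.time_varying is not None:
            tv = self.time_varying
            if tv.level not in self._covariate_levels(tv.covariate):
                raise ConfigError(f"unknown level {tv.level!r} for covariate {tv.covariate!r}")
            if tv.covariate in self.covariate_effects:
                raise ConfigError("a covariate cannot have both fixed and time-varying effects")

    @staticmethod
    def _covariate_levels(cov: str) -> tuple:
        if cov in WOMAN_COVARIATES:
            return WOMAN_COVARIATES[cov][0]
        if cov in CHILD_COVARIATES:
            return CHILD_COVARIATES[cov][0]
        raise ConfigError(f"unknown covariate {cov!r}")


def baseline_segments_from_standard(
    standard: RelationalLogitStandard, q5: float
) -> tuple[tuple[float, float, float], ...]:
    """Piecewise-constant monthly hazards whose survivorship matches a
    relational-logit shift of ``standard`` with 5q0 equal to ``q5``.

    The level alpha is chosen so that ``1 - l(5) = q5``; segment hazards on
    [0,12), [12,24), [24,36), [36,60) months then reproduce l(1), l(2), l(3),
    l(5) of the shifted table exactly, so simulated child mortality has the
    standard's age pattern by construction.
    """
    alpha = alpha_from_q(q5, 5, standard)
    l = {x: survivorship_from_alpha(alpha, x, standard) for x in (1, 2, 3, 5)}
    return (
        (0.0, 12.0, -math.log(l[1]) / 12.0),
        (12.0, 24.0, -math.log(l[2] / l[1]) / 12.0),
        (24.0, 36.0, -math.log(l[3] / l[2]) / 12.0),
        (36.0, 60.0, -math.log(l[5] / l[3]) / 24.0),
    )


# ---------------------------------------------------------------------------
# ground-truth oracle


def true_q5(config: SimulationConfig, peh: int, covariate_profile: dict | None = None) -> float:
    """Closed-form programmed probability of dying by exact age five.

    ``1 - exp(-sum_s lambda_s * dt_s * exp(lp))`` over the baseline segments,
    with ``lp`` the programmed linear predictor of the given PEH category and
    covariate profile.  The profile must name a level for every covariate that
    carries an effect (including a time-varying one).
    """
    config.validate()
    covariate_profile = covariate_profile or {}
    if peh not in (1, 2, 3, 4):
        raise ValueError("peh category must be 1..4")
    lp = 0.0 if peh == 4 else float(config.log_hr_peh[peh - 1])
    for cov, effects in config.covariate_effects.items():
        if cov not in covariate_profile:
            raise ValueError(f"covariate_profile must specify a level for {cov!r}")
        lvl = covariate_profile[cov]
        if lvl not in SimulationConfig._covariate_levels(cov):
            raise ValueError(f"unknown level {lvl!r} for covariate {cov!r}")
        lp += float(effects.get(lvl, 0.0))
    segs = _effective_segments(config)
    tv = config.time_varying
    tv_on = False
    if tv is not None:
        if tv.covariate not in covariate_profile:
            raise ValueError(f"covariate_profile must specify a level for {tv.covariate!r}")
        tv_on = covariate_profile[tv.covariate] == tv.level
    total = 0.0
    for s, e, lam, tv_add in segs:
        total += lam * (e - s) * math.exp(lp + (tv_add if tv_on else 0.0))
    return 1.0 - math.exp(-total)


def _effective_segments(config: SimulationConfig):
    """Baseline segments, split at the time-varying change point if needed.

    Yields ``(start, end, lambda, tv_log_hr)`` where the last entry applies
    only to children carrying the time-varying covariate level.
    """
    segs = sorted(config.baseline_hazard_segments)
    tv = config.time_varying
    if tv is None:
        return [(s, e, lam, 0.0) for s, e, lam in segs]
    out = []
    c = float(tv.change_month)
    for s, e, lam in segs:
        if s < c < e:
            out.append((s, c, lam, tv.log_hr_before))
            out.append((c, e, lam, tv.log_hr_after))
        else:
            out.append((s, e, lam, tv.log_hr_before if e <= c else tv.log_hr_after))
    return out


# ---------------------------------------------------------------------------
# generation


def _birth_history(rng, asfr_month, age_months, cfg) -> list[float]:
    """Birth times (months since the woman's birth) from age 15 to now.

    Piecewise-exponential waiting times at the age-specific rate, with a
    shifted-gamma minimum spacing enforced between consecutive births.
    """
    births: list[float] = []
    t = 180.0
    last = -1e9
    while t < age_months:
        band = min(int((t - 180.0) // 60.0), 6)
        bound = min(180.0 + 60.0 * (band + 1), age_months)
        rate = asfr_month[band]
        if rate <= 0.0:
            t = bound
            continue
        gap = rng.exponential(1.0 / rate)
        if t + gap >= bound:
            t = bound
            continue
        tb = t + gap
        if tb - last < cfg.pbi_min_months:
            tb = last + cfg.pbi_min_months + rng.gamma(cfg.pbi_gamma_shape, cfg.pbi_gamma_scale)
            if tb >= age_months:
                break
        births.append(tb)
        last = tb
        t = tb
    return births


def generate_population(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the survey: returns ``(women, children)`` DataFrames.

    ``women`` follows the women.csv schema plus an internal exact
    ``age_months`` column; ``children`` follows the children.csv schema plus
    an internal continuous ``aad_exact`` column (exact death age in months,
    NaN for survivors) retained for oracle checks.  Deterministic given the
    config (byte-identical repeats).
    """
    config.validate()
    n = config.n_women
    seed = config.seed

    rng_w = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 101))))
    rng_c = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 202))))

    # -- woman-level draws (vectorized)
    age_months = rng_w.uniform(180.0, 600.0, size=n)
    peh_cell = rng_w.choice(4, size=n, p=np.asarray(config.education_joint_probs)) + 1
    wife_edu = np.empty(n, dtype=object)
    husband_edu = np.empty(n, dtype=object)
    low_w = np.isin(peh_cell, (1, 2))  # note: cell codes index *husband* low for 1,2
    # cell 1: both low; 2: husband low, wife high; 3: husband high, wife low; 4: both high
    wife_low = np.isin(peh_cell, (1, 3))
    husb_low = np.isin(peh_cell, (1, 2))
    del low_w
    wife_edu[wife_low] = rng_w.choice(_EDU_WITHIN_LOW[0], size=int(wife_low.sum()), p=_EDU_WITHIN_LOW[1])
    wife_edu[~wife_low] = rng_w.choice(_EDU_WITHIN_HIGH[0], size=int((~wife_low).sum()), p=_EDU_WITHIN_HIGH[1])
    husband_edu[husb_low] = rng_w.choice(_EDU_WITHIN_LOW[0], size=int(husb_low.sum()), p=_EDU_WITHIN_LOW[1])
    husband_edu[~husb_low] = rng_w.choice(_EDU_WITHIN_HIGH[0], size=int((~husb_low).sum()), p=_EDU_WITHIN_HIGH[1])
    cohabiting = rng_w.random(n) >= config.frac_non_cohabiting
    cov_cols = {}
    for cov, (levels, probs) in WOMAN_COVARIATES.items():
        cov_cols[cov] = rng_w.choice(levels, size=n, p=probs)
    anc_visits = np.minimum(rng_w.poisson(3.0, size=n), 10)
    mean_w, disp = config.weight_distribution
    if disp > 0:
        weight = rng_w.gamma(1.0 / disp, mean_w * disp, size=n)
    else:
        weight = np.full(n, float(mean_w))

    # -- birth histories (per-woman sub-streams)
    asfr_month = np.asarray(config.fertility_schedule, dtype=float) / 12.0
    child_rows = []
    ceb = np.zeros(n, dtype=int)
    for wid in range(n):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 303, wid))))
        births = _birth_history(rng, asfr_month, age_months[wid], config)
        order = 0
        prev = None
        for tb in births:
            twin = rng.random() < config.frac_multiple_births
            pbi = None if prev is None else float(round(tb - prev))
            for _ in range(2 if twin else 1):
                order += 1
                child_rows.append((wid, tb, order, pbi, twin))
            prev = tb
        ceb[wid] = order

    n_children = len(child_rows)
    woman_idx = np.fromiter((r[0] for r in child_rows), dtype=int, count=n_children)
    birth_t = np.fromiter((r[1] for r in child_rows), dtype=float, count=n_children)
    birth_order = np.fromiter((r[2] for r in child_rows), dtype=int, count=n_children)
    pbi_months = np.array([r[3] for r in child_rows], dtype=object)
    multiple = np.fromiter((r[4] for r in child_rows), dtype=bool, count=n_children)

    # -- child-level draws (vectorized, deterministic child order)
    sex = rng_c.choice(CHILD_COVARIATES["sex"][0], size=n_children, p=CHILD_COVARIATES["sex"][1])
    bw = rng_c.choice(CHILD_COVARIATES["bw_class"][0], size=n_children, p=CHILD_COVARIATES["bw_class"][1])

    lp = np.zeros(n_children)
    log_hr = np.asarray(config.log_hr_peh, dtype=float)
    cell = peh_cell[woman_idx]
    for k in (1, 2, 3):
        lp[cell == k] += log_hr[k - 1]
    child_values = {"sex": sex, "bw_class": bw}
    for cov, effects in config.covariate_effects.items():
        values = child_values[cov] if cov in child_values else cov_cols[cov][woman_idx]
        for lvl, b in effects.items():
            lp[values == lvl] += float(b)

    tv = config.time_varying
    segs = _effective_segments(config)
    starts = np.array([s for s, _, _, _ in segs])
    durs = np.array([e - s for s, e, _, _ in segs])
    lams = np.array([lam for _, _, lam, _ in segs])
    tv_adds = np.array([a for _, _, _, a in segs])
    if tv is not None:
        tv_vals = child_values[tv.covariate] if tv.covariate in child_values else cov_cols[tv.covariate][woman_idx]
        tv_on = (tv_vals == tv.level).astype(float)
    else:
        tv_on = np.zeros(n_children)

    # piecewise-exponential inversion: child i dies at the age where their
    # cumulative hazard first reaches a unit-exponential deviate
    rates = lams[None, :] * np.exp(lp[:, None] + tv_on[:, None] * tv_adds[None, :])
    increments = rates * durs[None, :]
    cum = np.cumsum(increments, axis=1)
    e_dev = rng_c.exponential(1.0, size=n_children)
    crossed = cum >= e_dev[:, None]
    dies_in_window = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)
    prev_cum = np.where(first > 0, np.take_along_axis(cum, np.maximum(first - 1, 0)[:, None], 1)[:, 0], 0.0)
    seg_rate = np.take_along_axis(rates, first[:, None], 1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_death = starts[first] + (e_dev - prev_cum) / seg_rate
    t_death = np.where(dies_in_window, t_death, np.nan)

    age_child = age_months[woman_idx] - birth_t  # exact current age in months
    died = dies_in_window & (t_death < age_child)
    aad = np.where(died, np.floor(t_death), np.nan)
    if config.heaping > 0:
        heap = died & (aad >= 6) & (rng_c.random(n_children) < config.heaping)
        aad = np.where(heap, np.minimum(np.round(aad / 6.0) * 6.0, 59.0), aad)

    birth_cmc = config.interview_cmc - np.floor(age_child).astype(int)
    m_age_at_birth = np.floor(birth_t / 12.0).astype(int)

    ceb_dead = np.zeros(n, dtype=int)
    np.add.at(ceb_dead, woman_idx, died.astype(int))

    age_group_idx = np.minimum(((age_months - 180.0) // 60.0).astype(int), 6)
    women = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "age_group": np.asarray(AGE_GROUPS, dtype=object)[age_group_idx],
            "wife_edu": wife_edu,
            "husband_edu": husband_edu,
            "cohabiting": cohabiting,
            **cov_cols,
            "anc_visits": anc_visits,
            "ceb": ceb,
            "ceb_dead": ceb_dead,
            "weight": weight,
            "age_months": age_months,
        }
    )[WOMEN_SCHEMA + ["age_months"]]

    children = pd.DataFrame(
        {
            "child_id": np.arange(n_children),
            "woman_id": woman_idx,
            "birth_cmc": birth_cmc,
            "sex": sex,
            "birth_order": birth_order,
            "bw_class": bw,
            "pbi_months": pd.array([None if v is None else int(v) for v in pbi_months], dtype="Int64"),
            "multiple": multiple,
            "died": died,
            "aad_months": pd.array([None if np.isnan(v) else int(v) for v in aad], dtype="Int64"),
            "m_age_at_birth": m_age_at_birth,
            "aad_exact": t_death,
        }
    )[CHILDREN_SCHEMA + ["aad_exact"]]
    return women, children


# ---------------------------------------------------------------------------
# flat-file round trip


def write_child_recode(women: pd.DataFrame, children: pd.DataFrame, directory) -> None:
    """Write ``women.csv`` and ``children.csv`` (documented flat schema).

    Flags are written as 1/0 and missing values as empty fields; internal
    columns (exact ages/death times) are not part of the schema and are
    dropped.  UTF-8 with a mandatory header row.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    w = women[WOMEN_SCHEMA].copy()
    w["cohabiting"] = w["cohabiting"].astype(int)
    w.to_csv(directory / "women.csv", index=False)
    c = children[CHILDREN_SCHEMA].copy()
    for col in ("multiple", "died"):
        c[col] = c[col].astype(int)
    c.to_csv(directory / "children.csv", index=False)


def read_child_recode(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the ``women.csv`` / ``children.csv`` pair.

    Enforces the record invariants (``ceb_dead <= ceb``; age at death present
    iff died) and names the offending rows; malformed CSV raises the parser's
    error, which carries the line number.
    """
    from pathlib import Path

    directory = Path(directory)
    women = pd.read_csv(directory / "women.csv", dtype={"wife_edu": object, "husband_edu": object})
    children = pd.read_csv(directory / "children.csv")
    for col, frame in (("woman_id", women), ("child_id", children)):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    women["cohabiting"] = women["cohabiting"].astype(bool)
    bad = women.index[women["ceb_dead"] > women["ceb"]]
    if len(bad):
        ids = women.loc[bad, "woman_id"].tolist()
        raise ValueError(f"ceb_dead > ceb for woman rows {ids}")
    children["multiple"] = children["multiple"].fillna(0).astype(bool)
    children["died"] = pd.array(
        [None if pd.isna(v) else bool(int(v)) for v in children["died"]], dtype="boolean"
    )
    children["pbi_months"] = pd.array(np.asarray(children["pbi_months"], dtype=float), dtype="Int64")
    children["aad_months"] = pd.array(np.asarray(children["aad_months"], dtype=float), dtype="Int64")
    mism = children["died"].fillna(False).astype(bool).to_numpy() != children["aad_months"].notna().to_numpy()
    if mism.any():
        ids = children.loc[mism, "child_id"].tolist()
        raise ValueError(f"age at death must be present iff died; child rows {ids}")
    return women[WOMEN_SCHEMA], children[CHILDREN_SCHEMA]


# ---------------------------------------------------------------------------
# deterministic hand-countable fixture


def exclusions_demo_population() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A fixed 20-child population exercising every exclusion rule.

    Ten mothers; mothers 7-9 are not cohabiting and contribute 5 children
    between them, mother 6 is missing the husband's education and contributes
    2 children; nobody else is excluded, so 13 of 20 children are kept with
    tally ``{multiple: 0, non_cohabiting: 5, missing_survival: 0,
    missing_education: 2}``.
    """
    base = {
        "age_group": "25-29", "wife_edu": "primary", "husband_edu": "secondary",
        "cohabiting": True, "residence": "rural", "religion": "christian",
        "wealth": "middle", "water": "improved", "toilet": "improved",
        "fuel": "biomass", "anc_visits": 3, "tetanus": "1+", "pod": "facility",
        "weight": 1.0,
    }
    kids_per_mother = [2, 2, 2, 2, 2, 3, 2, 2, 2, 1]  # 20 children
    women_rows = []
    for wid, k in enumerate(kids_per_mother):
        row = dict(base, woman_id=wid, ceb=k, ceb_dead=0)
        if wid in (7, 8, 9):
            row["cohabiting"] = False
        if wid == 6:
            row["husband_edu"] = None
        women_rows.append(row)
    women = pd.DataFrame(women_rows)[WOMEN_SCHEMA]

    child_rows = []
    cid = 0
    for wid, k in enumerate(kids_per_mother):
        for j in range(k):
            child_rows.append(
                dict(
                    child_id=cid, woman_id=wid, birth_cmc=1400 + j, sex="female",
                    birth_order=j + 1, bw_class="2.5-3.49",
                    pbi_months=None if j == 0 else 24, multiple=False,
                    died=False, aad_months=None, m_age_at_birth=24 + j,
                )
            )
            cid += 1
    children = pd.DataFrame(child_rows)[CHILDREN_SCHEMA]
    children["pbi_months"] = pd.array(children["pbi_months"], dtype="Int64")
    children["aad_months"] = pd.array(children["aad_months"], dtype="Int64")
    return women, children
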