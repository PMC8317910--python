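"""End-to-end validation studies with recoverable ground truth.

Each function simulates data under stated study conditions, runs the relevant
part of the pipeline, and returns the measured quantities.  They are the
computational core behind the acceptance checks and the analysis drivers; all
randomness flows from the ``seed`` argument.

Study conditions fixed here (sample sizes, programmed effects, replicate
counts) are the package's reference conditions; see docs/methods.md for the
rationale behind each choice.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import brass, cox, oracle, recode
from .association import chi_square, weighted_crosstab
from .lifetable import load_standard, q5_from_alpha, alpha_from_q
from .simulate import (
    SimulationConfig,
    TimeVaryingEffect,
    baseline_segments_from_standard,
    exclusions_demo_population,
    generate_population,
    true_q5,
)

__all__ = [
    "study_config",
    "brass_recovery_study",
    "logit_roundtrip_study",
    "cox_oracle_study",
    "hr_recovery_study",
    "chi_square_closed_form_study",
    "chi_square_type1_study",
    "schoenfeld_null_study",
    "schoenfeld_power_study",
    "exclusions_study",
    "ordering_study",
]

#: log hazard ratios giving the reference stratum ordering q5: 1 > 3 > 2 > 4
ORDERED_PEH_EFFECTS = (math.log(1.6), math.log(1.2), math.log(1.4))

DEFAULT_STANDARD = "west_pattern_synthetic"
Q5_REFERENCE = 0.150


def _sub_seed(seed: int, k: int) -> int:
    """Deterministic derived seed, kept below 2**31."""
    return (seed * 1_000_003 + k) % (2**31 - 1)


def study_config(
    seed: int,
    n_women: int,
    log_hr_peh=(0.0, 0.0, 0.0),
    q5: float = Q5_REFERENCE,
    standard_name: str = DEFAULT_STANDARD,
    **overrides,
) -> SimulationConfig:
    """Reference simulation: mortality pattern equal to the chosen standard,
    5q0 = ``q5`` in the reference PEH category, constant fertility/mortality."""
    standard = load_standard(standard_name)
    return SimulationConfig(
        n_women=n_women,
        seed=seed,
        baseline_hazard_segments=baseline_segments_from_standard(standard, q5),
        log_hr_peh=tuple(log_hr_peh),
        frac_non_cohabiting=overrides.pop("frac_non_cohabiting", 0.03),
        **overrides,
    )


def _eligible_women(women: pd.DataFrame) -> pd.DataFrame:
    """Women entering the indirect estimation: cohabiting, education known."""
    keep = (
        women["cohabiting"].astype(bool)
        & women["wife_edu"].notna()
        & women["husband_edu"].notna()
    )
    out = women.loc[keep].copy()
    out["peh"] = recode.derive_peh_series(out["wife_edu"], out["husband_edu"]).astype(int)
    return out


# ---------------------------------------------------------------------------


def brass_recovery_study(seed: int, n_women: int = 50_000) -> dict:
    """Indirect-method parameter recovery on a population that satisfies its
    assumptions (stationary fertility/mortality, pattern equal to the
    standard, programmed 5q0 = 0.150)."""
    cfg = study_config(_sub_seed(seed, 1), n_women)
    q5_true = true_q5(cfg, peh=4)
    women, _ = generate_population(cfg)
    standard = load_standard(DEFAULT_STANDARD)
    est = brass.estimate_u5m_by_stratum(_eligible_women(women), standard, stratifier=None)[0]
    return {
        "q5_true_per_1000": 1000.0 * q5_true,
        "q5_est_per_1000": est.q5_per_1000,
        "abs_error_per_1000": abs(est.q5_per_1000 - 1000.0 * q5_true),
        "alpha": est.alpha,
        "indices_used": est.indices_used,
        "n_women": int(len(women)),
    }


def logit_roundtrip_study(seed: int, n: int = 1000) -> dict:
    """alpha_from_q and q5_from_alpha must be exact mutual inverses at x=5."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    standard = load_standard(DEFAULT_STANDARD)
    q = rng.uniform(1e-6, 1.0 - 1e-6, size=n)
    back = np.array([q5_from_alpha(alpha_from_q(qi, 5, standard), standard) for qi in q])
    return {"max_abs_error": float(np.max(np.abs(back - q))), "n": n}


def cox_oracle_study(seed: int, n_fixtures: int = 25) -> dict:
    """Production Cox fit versus brute-force maximization of the explicitly
    enumerated partial likelihood, on tiny no-ties fixtures."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    worst = 0.0
    done = 0
    while done < n_fixtures:
        n = int(rng.integers(6, 11))
        levels = ("a", "b") if rng.random() < 0.5 else ("a", "b", "c")
        obs = pd.DataFrame(
            {
                "time_months": rng.uniform(0.5, 59.0, size=n),  # continuous: no ties a.s.
                "event": rng.random(n) < 0.7,
                "x": rng.choice(levels, size=n),
                "weight": 1.0,
            }
        )
        if (
            obs["x"].nunique() < len(levels)
            or obs["event"].sum() < 2
            or obs.groupby("x")["event"].sum().min() < 1
        ):
            continue
        try:
            fit = cox.fit_cox(obs, ["x"], tie_method="breslow")
        except RuntimeError:
            continue  # separated fixture; draw another
        beta_ref = oracle.brute_force_cox(
            fit.times, fit.events, fit.design.to_numpy(), x0=fit.params.to_numpy()
        )
        if np.any(np.abs(beta_ref) > 5):
            continue  # near-separation: outside the comparison domain
        worst = max(worst, float(np.max(np.abs(fit.params.to_numpy() - beta_ref))))
        done += 1
    return {"max_abs_diff": worst, "n_fixtures": done}


def hr_recovery_study(seed: int, n_reps: int = 200, n_women: int = 1800) -> dict:
    """Hazard-ratio recovery: programmed ln(1.6) effect of PEH category 1.

    Each replicate simulates ~5,000 children, fits the PEH-only Cox model and
    records the category-1 log hazard ratio and whether its Wald 95% CI covers
    the truth.  Reports the mean estimate and empirical coverage.
    """
    target = math.log(1.6)
    coefs, covered, sizes = [], [], []
    for r in range(n_reps):
        cfg = study_config(_sub_seed(seed, 10_000 + r), n_women, log_hr_peh=(target, 0.0, 0.0))
        women, children = generate_population(cfg)
        obs = recode.build_survival_data(women, children, cfg.interview_cmc)
        fit = cox.fit_cox(obs, ["peh"])
        row = fit.summary.loc["peh=1"]
        coefs.append(row["coef"])
        covered.append(row["ci_low"] <= 1.6 <= row["ci_high"])
        sizes.append(len(obs))
    return {
        "target_log_hr": target,
        "mean_log_hr": float(np.mean(coefs)),
        "bias": float(np.mean(coefs) - target),
        "ci_coverage": float(np.mean(covered)),
        "n_reps": n_reps,
        "mean_children": float(np.mean(sizes)),
    }


def chi_square_closed_form_study(seed: int, n_tables: int = 1000) -> dict:
    """Pearson statistic versus the 2x2 closed form n(ad-bc)^2 / product of
    margins, on random tables."""
    from .association import ContingencyTable

    rng = np.random.default_rng(_sub_seed(seed, 4))
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(1, 60, size=4)
        tab = ContingencyTable("x", ["r1", "r2"], [[a, b], [c, d]], [[a, b], [c, d]])
        stat, df, _ = chi_square(tab)
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        worst = max(worst, abs(stat - closed))
    return {"max_abs_diff": worst, "n_tables": n_tables}


def chi_square_type1_study(seed: int, n_reps: int = 1000, n_women: int = 450) -> dict:
    """Empirical type-I error of the association test under the generator's
    null (religion has no programmed effect on mortality)."""
    rejections = 0
    for r in range(n_reps):
        cfg = study_config(_sub_seed(seed, 20_000 + r), n_women)
        women, children = generate_population(cfg)
        obs = recode.build_survival_data(women, children, cfg.interview_cmc)
        _, _, p = chi_square(weighted_crosstab(obs, "religion"))
        rejections += p < 0.05
    return {"type1_rate": rejections / n_reps, "n_reps": n_reps}


def schoenfeld_null_study(seed: int, n_reps: int = 500, n_women: int = 650) -> dict:
    """Calibration of the proportional-hazards score test when proportionality
    holds by construction (rejection rate should sit at the nominal 5%)."""
    rejections = 0
    for r in range(n_reps):
        cfg = study_config(_sub_seed(seed, 30_000 + r), n_women, log_hr_peh=ORDERED_PEH_EFFECTS)
        women, children = generate_population(cfg)
        obs = recode.build_survival_data(women, children, cfg.interview_cmc)
        fit = cox.fit_cox(obs, ["peh"])
        rejections += cox.schoenfeld_test(fit).global_p < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def schoenfeld_power_study(seed: int, n_reps: int = 40, n_women: int = 3400) -> dict:
    """Power of the score test against an injected time-varying effect: the
    male log hazard ratio doubles from 0.47 to 0.94 after 12 months of age,
    at ~10,000 children per replicate."""
    tv = TimeVaryingEffect("sex", "male", 0.47, 0.94, change_month=12.0)
    rejections = 0
    sizes = []
    for r in range(n_reps):
        cfg = study_config(_sub_seed(seed, 40_000 + r), n_women, time_varying=tv)
        women, children = generate_population(cfg)
        obs = recode.build_survival_data(women, children, cfg.interview_cmc)
        fit = cox.fit_cox(obs, ["sex"])
        rejections += cox.schoenfeld_test(fit).global_p < 0.05
        sizes.append(len(obs))
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "mean_children": float(np.mean(sizes)),
    }


def exclusions_study() -> dict:
    """Deterministic eligibility filtering of the 20-child demo fixture."""
    women, children = exclusions_demo_population()
    kept, tally = recode.apply_exclusions(women, children)
    return {
        "n_input": int(len(children)),
        "n_kept": int(len(kept)),
        "tally": tally.to_dict(),
    }


def ordering_study(seed: int, n_women: int = 50_000) -> dict:
    """Recovery of the programmed stratum ordering of 5q0 across PEH cells
    (1 > 3 > 2 > 4) by the stratified indirect estimates."""
    cfg = study_config(_sub_seed(seed, 5), n_women, log_hr_peh=ORDERED_PEH_EFFECTS)
    truth = {k: 1000.0 * true_q5(cfg, peh=k) for k in (1, 2, 3, 4)}
    women, _ = generate_population(cfg)
    standard = load_standard(DEFAULT_STANDARD)
    ests = brass.estimate_u5m_by_stratum(_eligible_women(women), standard, stratifier="peh")
    q5 = {int(e.stratum): e.q5_per_1000 for e in ests}
    ordering_ok = q5[1] > q5[3] > q5[2] > q5[4]
    return {
        "q5_per_1000": q5,
        "q5_true_per_1000": truth,
        "ordering_correct": bool(ordering_ok),
        "n_women": int(len(women)),
    }
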