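"""Exposure derivation, eligibility exclusions, and the censored survival outcome.

The exposure of interest is *parental educational homogamy* (PEH): a four-level
joint classification of the wife's and husband's educational attainment, split
at "at most primary" (none or primary) versus "at least secondary" (secondary
or higher):

    1  both spouses at most primary
    2  husband at most primary, wife at least secondary
    3  husband at least secondary, wife at most primary
    4  both spouses at least secondary        (reference)

"None" and "primary" are merged because under-five mortality differs little
between them.  Eligibility follows the usual survey-analysis restrictions:
multiple births are dropped, as are children of mothers not currently
cohabiting / not in union, and records with missing survival status or either
parent's education (complete-case analysis).

The survival outcome is child survival over the first 59 months of life:
deaths at age <= 59 months are events at their reported age at death; children
still alive are right-censored at their current age, or at 59 months once they
have survived the whole window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "EDUCATION_LEVELS",
    "AT_MOST_PRIMARY",
    "PEH_LABELS",
    "EXCLUSION_REASONS",
    "RECODE_TABLE",
    "REFERENCE_LEVELS",
    "derive_peh",
    "derive_peh_series",
    "apply_exclusions",
    "censor_survival",
    "build_survival_data",
]

EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
AT_MOST_PRIMARY = frozenset({"none", "primary"})

PEH_LABELS = {
    1: "both at most primary",
    2: "husband at most primary & wife at least secondary",
    3: "husband at least secondary & wife at most primary",
    4: "both at least secondary",
}

#: fixed order in which exclusion reasons are applied and tallied; a child
#: excluded for several reasons is counted once, under the first that applies.
EXCLUSION_REASONS = (
    "multiple_birth",
    "non_cohabiting",
    "missing_survival",
    "missing_education",
)

#: covariate categorizations used throughout the descriptive and hazard models,
#: kept in one table so tests can assert them.  Bin edges are inclusive lower
#: bounds; labels follow the conventional survey groupings.
RECODE_TABLE = {
    "m_age_group": {"bins": [0, 20, 25, 35, np.inf], "labels": ["<20", "20-24", "25-34", "35+"]},
    "parity_group": {"bins": [1, 2, 4, 6, np.inf], "labels": ["1", "2-3", "4-5", "6+"]},
    "birth_order_group": {"bins": [1, 2, 4, 6, np.inf], "labels": ["1", "2-3", "4-5", "6+"]},
    "pbi_group": {"bins": [0, 24, 36, 60, np.inf], "labels": ["<24", "24-35", "36-59", "60+"]},
    "anc_group": {"bins": [0, 1, 4, np.inf], "labels": ["none", "1-3", "4+"]},
    "bw_class": {"labels": ["<2.5", "2.5-3.49", "3.5+"]},
}

#: reference level per covariate for indicator contrasts in the hazard models.
REFERENCE_LEVELS = {
    "peh": 4,
    "sex": "female",
    "residence": "urban",
    "religion": "christian",
    "wealth": "rich",
    "water": "improved",
    "toilet": "improved",
    "fuel": "clean",
    "tetanus": "1+",
    "pod": "facility",
    "m_age_group": "25-34",
    "parity_group": "2-3",
    "birth_order_group": "2-3",
    "pbi_group": "36-59",
    "anc_group": "4+",
    "bw_class": "3.5+",
}


def derive_peh(wife_edu: str, husband_edu: str) -> int:
    """Four-level PEH code from the two spouses' education levels.

    Total on ``{none, primary, secondary, higher}^2``; unchanged under swapping
    none<->primary or secondary<->higher within a spouse.
    """
    for side, lvl in (("wife", wife_edu), ("husband", husband_edu)):
        if lvl not in EDUCATION_LEVELS:
            raise ValueError(f"unknown {side} education level {lvl!r}; expected one of {EDUCATION_LEVELS}")
    wife_low = wife_edu in AT_MOST_PRIMARY
    husb_low = husband_edu in AT_MOST_PRIMARY
    if wife_low and husb_low:
        return 1
    if husb_low:  # wife at least secondary
        return 2
    if wife_low:  # husband at least secondary
        return 3
    return 4


def derive_peh_series(wife_edu: pd.Series, husband_edu: pd.Series) -> pd.Series:
    """Vectorized :func:`derive_peh`; NaN education propagates to NaN code."""
    known = set(EDUCATION_LEVELS)
    for s in (wife_edu, husband_edu):
        bad = set(s.dropna().unique()) - known
        if bad:
            raise ValueError(f"unknown education levels {sorted(bad)}")
    wife_low = wife_edu.isin(AT_MOST_PRIMARY)
    husb_low = husband_edu.isin(AT_MOST_PRIMARY)
    code = np.select(
        [wife_low & husb_low, husb_low & ~wife_low, wife_low & ~husb_low],
        [1, 2, 3],
        default=4,
    ).astype(float)
    code[wife_edu.isna().to_numpy() | husband_edu.isna().to_numpy()] = np.nan
    return pd.Series(code, index=wife_edu.index, name="peh")


def apply_exclusions(
    women: pd.DataFrame, children: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the eligibility exclusions to child records.

    Removes, in this fixed precedence order: multiple births; children of
    non-cohabiting mothers; records missing survival status; records missing
    either parent's education.  Returns the kept children and a per-reason
    tally (ordered as :data:`EXCLUSION_REASONS`).  Idempotent, and
    ``tally.sum() + len(kept) == len(children)``.

    Raises ``ValueError`` listing ids if a child has no mother record.
    """
    orphans = children.loc[~children["woman_id"].isin(women["woman_id"]), "child_id"]
    if len(orphans):
        raise ValueError(f"orphan child records (no mother present): {sorted(orphans.tolist())}")

    mother = women.set_index("woman_id")
    m = mother.reindex(children["woman_id"])
    missing_edu = m["wife_edu"].isna().to_numpy() | m["husband_edu"].isna().to_numpy()
    non_cohab = ~m["cohabiting"].astype(bool).to_numpy()

    reasons = {
        "multiple_birth": children["multiple"].astype(bool).to_numpy(),
        "non_cohabiting": non_cohab,
        "missing_survival": children["died"].isna().to_numpy(),
        "missing_education": missing_edu,
    }
    excluded = np.zeros(len(children), dtype=bool)
    tally = {}
    for reason in EXCLUSION_REASONS:
        hit = reasons[reason] & ~excluded
        tally[reason] = int(hit.sum())
        excluded |= hit
    kept = children.loc[~excluded].copy()
    return kept, pd.Series(tally, name="excluded").reindex(list(EXCLUSION_REASONS))


def censor_survival(
    aad_months: float | None, died: bool, age_at_interview_months: float
) -> tuple[float, bool] | None:
    """Censored survival outcome for one child: ``(time_months, event)``.

    Deaths at age <= 59 months are events at the reported age at death;
    survivors are censored at ``min(current age, 59)``.  Zero times (deaths in
    the month of birth, or interviews in the month of birth) are lifted to 0.5
    months, the half-interval convention, so the partial likelihood is defined.
    Returns ``None`` (with a warning) for deaths reported beyond the window.
    """
    if died:
        if aad_months is None or np.isnan(aad_months):
            raise ValueError("died child without age at death")
        if aad_months > 59:
            warnings.warn("death beyond 59 months excluded from the under-five window", stacklevel=2)
            return None
        return max(float(aad_months), 0.5), True
    return max(min(float(age_at_interview_months), 59.0), 0.5), False


def _categorize(values: pd.Series, bins, labels) -> pd.Series:
    return pd.cut(values, bins=bins, labels=labels, right=False, include_lowest=True)


def build_survival_data(
    women: pd.DataFrame,
    children: pd.DataFrame,
    interview_cmc: int,
    drop_incomplete_exposure: bool = False,
) -> pd.DataFrame:
    """Assemble the child-level analysis table after exclusions.

    One row per eligible child with the censored outcome (``time_months``,
    ``event``), the mother's PEH and covariates, the recoded covariate groups
    of :data:`RECODE_TABLE`, and the mother's sampling weight.  Children of
    age < 59 months who are alive contribute censored time at their current
    age unless ``drop_incomplete_exposure`` asks for the stricter cohort.
    """
    kept, _ = apply_exclusions(women, children)
    mother = women.set_index("woman_id")
    m = mother.reindex(kept["woman_id"]).reset_index(drop=True)
    kept = kept.reset_index(drop=True)

    age_iv = (interview_cmc - kept["birth_cmc"]).astype(float)
    died = kept["died"].astype(bool)
    aad = kept["aad_months"].astype(float)

    over_window = died & (aad > 59)
    if over_window.any():
        warnings.warn(
            f"{int(over_window.sum())} deaths beyond 59 months excluded from the under-five window",
            stacklevel=2,
        )
    time = np.where(died, aad, np.minimum(age_iv, 59.0))
    time = np.maximum(time, 0.5)

    out = pd.DataFrame(
        {
            "child_id": kept["child_id"],
            "time_months": time,
            "event": died.to_numpy(),
            "weight": m["weight"].to_numpy(),
            "peh": derive_peh_series(m["wife_edu"], m["husband_edu"]).astype(int).to_numpy(),
            "sex": kept["sex"].to_numpy(),
            "bw_class": kept["bw_class"].to_numpy(),
        }
    )
    for cov in ("residence", "religion", "wealth", "water", "toilet", "fuel", "tetanus", "pod"):
        if cov in m.columns:
            out[cov] = m[cov].to_numpy()
    out["m_age_group"] = _categorize(
        kept["m_age_at_birth"].astype(float), **RECODE_TABLE["m_age_group"]
    ).astype(object)
    out["parity_group"] = _categorize(m["ceb"].astype(float), **RECODE_TABLE["parity_group"]).astype(object)
    out["birth_order_group"] = _categorize(
        kept["birth_order"].astype(float), **RECODE_TABLE["birth_order_group"]
    ).astype(object)
    pbi = kept["pbi_months"].astype(float)
    pbi_grp = _categorize(pbi, **RECODE_TABLE["pbi_group"]).astype(object)
    pbi_grp[pbi.isna().to_numpy()] = "first"  # first births have no preceding interval
    out["pbi_group"] = pbi_grp.to_numpy()
    if "anc_visits" in m.columns:
        out["anc_group"] = _categorize(m["anc_visits"].astype(float), **RECODE_TABLE["anc_group"]).astype(object)

    out = out.loc[~over_window.to_numpy()].reset_index(drop=True)
    if drop_incomplete_exposure:
        full = out["event"] | (out["time_months"] >= 59.0)
        out = out.loc[full].reset_index(drop=True)
    return out
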