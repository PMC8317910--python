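"""Brass indirect estimation of under-five mortality from CEB/CD summaries.

The children-ever-born / children-dead method: women are classified in 5-year
age groups i = 1..7 (15-19 .. 45-49); the proportion dead D(i) among children
ever born to group i approximates the probability of dying by an exact
childhood age x(i) once multiplied by a factor k(i) that corrects for the age
pattern of fertility:

    q(x(i)) = k(i) * D(i),
    k(i)    = a(i) + b(i) * (P1/P2) + c(i) * (P2/P3),

where P(i) is mean parity and the a, b, c are the Trussell regression
coefficients with the standard Manual-X correspondence i -> x of
1,2,3,5,10,15,20.  Each q(x) is converted to the level parameter alpha of a
one-parameter relational logit life-table system over a chosen standard, the
alphas of the retained indices are combined, and 5q0 is read back from the
combined level.  No time-location (reference date) of the estimates is
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .lifetable import RelationalLogitStandard, alpha_from_q, q5_from_alpha

__all__ = [
    "AGE_GROUP_INDEX",
    "INDEX_TO_AGE",
    "load_trussell_coefficients",
    "summarize_by_age_group",
    "trussell_k",
    "qx_from_summaries",
    "fit_alpha_and_q5",
    "estimate_u5m_by_stratum",
    "U5MEstimate",
]

AGE_GROUP_INDEX = {
    "15-19": 1, "20-24": 2, "25-29": 3, "30-34": 4, "35-39": 5, "40-44": 6, "45-49": 7,
}
#: Manual-X correspondence between the woman's age-group index and the exact
#: childhood age whose death probability D(i) informs.
INDEX_TO_AGE = {1: 1, 2: 2, 3: 3, 4: 5, 5: 10, 6: 15, 7: 20}

#: indices whose alphas enter the combined level by default: q(2), q(3), q(5)
#: from women 20-34.  The 15-19 group is conventionally unstable (few, highly
#: selected births) and older groups reflect increasingly distant mortality.
DEFAULT_INDICES = (2, 3, 4)


def load_trussell_coefficients() -> pd.DataFrame:
    """Trussell multiplier coefficients (West family), indexed by i = 1..7.

    Shipped as package data with a provenance note; columns ``age_x, a, b, c``.
    """
    import io

    text = resources.files("pehsurv.data").joinpath("trussell_west.csv").read_text()
    rows = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(rows))).set_index("i")
    if list(df.index) != list(range(1, 8)):
        raise ValueError("Trussell coefficient table must have rows i = 1..7")
    if not all(df.loc[i, "age_x"] == x for i, x in INDEX_TO_AGE.items()):
        raise ValueError("Trussell table violates the standard index -> age correspondence")
    return df


def summarize_by_age_group(women: pd.DataFrame) -> pd.DataFrame:
    """Per-age-group CEB/CD totals, mean parity P(i) and proportion dead D(i).

    Requires non-empty input; groups with zero children ever born get D = NaN
    and are flagged by the ``usable`` column.
    """
    if len(women) == 0:
        raise ValueError("no women to summarize")
    out = []
    for grp, i in AGE_GROUP_INDEX.items():
        sub = women.loc[women["age_group"] == grp]
        n = len(sub)
        ceb = int(sub["ceb"].sum()) if n else 0
        dead = int(sub["ceb_dead"].sum()) if n else 0
        out.append(
            {
                "i": i,
                "age_group": grp,
                "n_women": n,
                "total_ceb": ceb,
                "total_dead": dead,
                "P": ceb / n if n else np.nan,
                "D": dead / ceb if ceb else np.nan,
                "usable": bool(n and ceb),
            }
        )
    return pd.DataFrame(out).set_index("i")


def trussell_k(i: int, p1_over_p2: float, p2_over_p3: float, coeffs: pd.DataFrame) -> float:
    """Multiplier ``k(i) = a(i) + b(i) P1/P2 + c(i) P2/P3``.

    Ratios must be finite and positive.  A nonpositive linear form is clipped
    to a small positive value with a warning (can occur far outside the
    fitted fertility domain).
    """
    for name, r in (("P1/P2", p1_over_p2), ("P2/P3", p2_over_p3)):
        if not np.isfinite(r) or r <= 0:
            raise ValueError(f"parity ratio {name} must be finite and positive, got {r}")
    row = coeffs.loc[i]
    k = float(row["a"] + row["b"] * p1_over_p2 + row["c"] * p2_over_p3)
    if k <= 0:
        warnings.warn(f"multiplier k({i}) = {k:.4f} nonpositive; clipped", stacklevel=2)
        k = 1e-6
    return k


def qx_from_summaries(summaries: pd.DataFrame, coeffs: pd.DataFrame) -> dict[int, float]:
    """Map exact age x -> q(x) = k(i) D(i) for every usable index.

    Mean parities P1..P3 must be positive to form the ratios; q values above
    1 are truncated just below 1 with a warning; unusable groups are omitted.
    """
    P = summaries["P"]
    if not (P.get(1, np.nan) > 0 and P.get(2, np.nan) > 0 and P.get(3, np.nan) > 0):
        raise ValueError("mean parities P1, P2, P3 must be positive to form the Trussell ratios")
    r1 = float(P[1] / P[2])
    r2 = float(P[2] / P[3])
    out: dict[int, float] = {}
    for i, x in INDEX_TO_AGE.items():
        if i not in summaries.index or not summaries.loc[i, "usable"]:
            continue
        d = float(summaries.loc[i, "D"])
        q = trussell_k(i, r1, r2, coeffs) * d
        if q >= 1.0:
            warnings.warn(f"q({x}) = {q:.4f} truncated below 1", stacklevel=2)
            q = 1.0 - 1e-9
        out[x] = q
    return out


@dataclass
class U5MEstimate:
    """An indirect under-five mortality estimate for one stratum."""

    stratum: str
    qx: dict = field(default_factory=dict)  # exact age -> q(x)
    alpha_by_index: dict = field(default_factory=dict)  # index i -> alpha
    alpha: float = np.nan  # combined level
    q5_per_1000: float = np.nan
    indices_used: tuple = ()
    standard: str = ""
    combine: str = "mean"


def fit_alpha_and_q5(
    qx_map: dict[int, float],
    standard: RelationalLogitStandard,
    indices_used: tuple = DEFAULT_INDICES,
    combine: str = "mean",
    stratum: str = "all",
) -> U5MEstimate:
    """Convert per-age q(x) into a combined level alpha and 5q0 (per 1000).

    Each q(x(i)) for i in ``indices_used`` becomes an alpha through the
    relational logit system; the combined alpha is their arithmetic mean
    (``combine='median'`` available), and 5q0 is the relational table's
    ``1 - l(5)`` at that level, scaled per 1000 live births.
    """
    alphas = {}
    for i in indices_used:
        x = INDEX_TO_AGE[i]
        q = qx_map.get(x)
        if q is None or not 0.0 < q:
            continue
        if q >= 1.0:
            continue
        if q == 0.0:
            continue
        alphas[i] = alpha_from_q(q, x, standard)
    if not alphas:
        raise ValueError(f"no usable index among {indices_used} for stratum {stratum!r}")
    vals = np.array(list(alphas.values()))
    if combine == "mean":
        a = float(vals.mean())
    elif combine == "median":
        a = float(np.median(vals))
    else:
        raise ValueError("combine must be 'mean' or 'median'")
    return U5MEstimate(
        stratum=stratum,
        qx=dict(qx_map),
        alpha_by_index=alphas,
        alpha=a,
        q5_per_1000=1000.0 * q5_from_alpha(a, standard),
        indices_used=tuple(alphas),
        standard=standard.name,
        combine=combine,
    )


def estimate_u5m_by_stratum(
    women: pd.DataFrame,
    standard: RelationalLogitStandard,
    stratifier: str | None = "peh",
    coeffs: pd.DataFrame | None = None,
    indices_used: tuple = DEFAULT_INDICES,
    combine: str = "mean",
) -> list[U5MEstimate]:
    """Run the full indirect chain per stratum of ``stratifier``.

    ``stratifier=None`` estimates one overall level.  Empty or degenerate
    strata are omitted with a warning.  Returns one estimate per stratum, in
    sorted stratum order.
    """
    if coeffs is None:
        coeffs = load_trussell_coefficients()
    if stratifier is None:
        groups = [("all", women)]
    else:
        if stratifier not in women.columns:
            raise KeyError(f"stratifier {stratifier!r} not in women table")
        groups = sorted(women.groupby(stratifier, observed=True), key=lambda kv: str(kv[0]))
    out = []
    for label, sub in groups:
        try:
            summaries = summarize_by_age_group(sub)
            qx = qx_from_summaries(summaries, coeffs)
            out.append(
                fit_alpha_and_q5(qx, standard, indices_used, combine=combine, stratum=str(label))
            )
        except ValueError as err:
            warnings.warn(f"stratum {label!r} omitted: {err}", stacklevel=2)
    return out
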