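"""Two-stage proportional-hazards workflow with diagnostics.

Stage one screens each candidate covariate in a single-covariate Cox model and
keeps those significant at a liberal alpha (default 0.10); the exposure of
interest (PEH) is always retained.  Stage two fits the adjusted model.  The
semi-parametric Cox model assumes hazards proportional over age, which is
checked two ways: the scaled-Schoenfeld-residual score test of Grambsch and
Therneau, and parallel ``log(-log S)`` Kaplan-Meier curves.

The partial likelihood is maximized by ``statsmodels`` ``PHReg`` (Newton-type
optimization, Breslow or Efron tie handling).  Ages at death are reported in
whole months, so event times are heavily tied; the tie method therefore
travels with every fit and into every report header (Breslow by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .recode import REFERENCE_LEVELS

__all__ = [
    "HazardModelFit",
    "SchoenfeldResult",
    "make_design",
    "fit_cox",
    "unadjusted_screen",
    "schoenfeld_residuals",
    "schoenfeld_test",
    "km_loglog",
]


def make_design(observations: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Indicator contrasts for categorical covariates against fixed references.

    Columns are named ``covariate=level``; the reference level per covariate
    comes from :data:`pehsurv.recode.REFERENCE_LEVELS` (PEH reference is
    category 4), falling back to the most frequent level for ad-hoc factors.
    """
    cols = {}
    for cov in covariates:
        if cov not in observations.columns:
            raise KeyError(f"covariate {cov!r} not in observations")
        values = observations[cov]
        levels = sorted(values.dropna().unique(), key=str)
        ref = REFERENCE_LEVELS.get(cov)
        if ref not in levels:
            ref = values.mode().iloc[0]
        for lvl in levels:
            if lvl == ref:
                continue
            cols[f"{cov}={lvl}"] = (values == lvl).astype(float).to_numpy()
    return pd.DataFrame(cols, index=observations.index)


@dataclass
class HazardModelFit:
    """A fitted proportional-hazards model.

    ``summary`` has one row per indicator term: coefficient, hazard ratio,
    standard error, Wald 95% CI bounds on the HR scale, and Wald p-value.
    Reference levels are implicit (HR = 1).  The design matrix and outcome are
    retained for residual diagnostics.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    tie_method: str
    covariates: list[str]
    design: pd.DataFrame = field(repr=False)
    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)
    cov_params: np.ndarray = field(repr=False)

    @property
    def params(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]


def fit_cox(
    observations: pd.DataFrame,
    covariates: list[str],
    tie_method: str = "breslow",
) -> HazardModelFit:
    """Fit the Cox model of under-five death on the given covariates.

    Unweighted (the multivariate stage of the workflow deliberately ignores
    the sampling weights).  Raises on non-convergence (with the optimizer
    message) and on apparent complete separation, naming the covariate term.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")
    X = make_design(observations, covariates)
    if X.shape[1] == 0:
        raise ValueError("design matrix has no columns (all covariates degenerate)")
    times = observations["time_months"].to_numpy(float)
    events = observations["event"].astype(bool).to_numpy()
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    model = PHReg(times, X.to_numpy(), status=events.astype(int), ties=tie_method)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"non-convergence (singular information matrix): {err}") from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        bad = X.columns[~np.isfinite(params)].tolist()
        raise RuntimeError(f"non-convergence or separation for terms {bad}")
    if np.any(np.abs(params) > 15):
        bad = X.columns[np.abs(params) > 15].tolist()
        raise RuntimeError(f"apparent complete separation (monotone likelihood) for terms {bad}")
    se = np.asarray(res.bse, dtype=float)
    z = params / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": params,
            "hr": np.exp(params),
            "se": se,
            "ci_low": np.exp(params - zcrit * se),
            "ci_high": np.exp(params + zcrit * se),
            "p": pvals,
        },
        index=pd.Index(X.columns, name="term"),
    )
    return HazardModelFit(
        summary=summary,
        log_likelihood=float(model.loglike(params)),
        n=len(times),
        n_events=int(events.sum()),
        tie_method=tie_method,
        covariates=list(covariates),
        design=X,
        times=times,
        events=events,
        cov_params=np.atleast_2d(res.cov_params()),
    )


def unadjusted_screen(
    observations: pd.DataFrame,
    candidate_vars: list[str],
    alpha: float = 0.10,
    always_keep: tuple = ("peh",),
    tie_method: str = "breslow",
) -> tuple[list[str], dict[str, HazardModelFit]]:
    """Single-covariate screening at the given alpha.

    Each candidate gets its own one-covariate Cox fit; a candidate is selected
    if any of its levels has Wald p below ``alpha`` (minimum-p rule).  The
    main exposure(s) in ``always_keep`` are selected regardless.  Degenerate
    candidates (fewer than two populated levels, or separation) are dropped
    with a warning.
    """
    fits: dict[str, HazardModelFit] = {}
    selected: list[str] = []
    for var in candidate_vars:
        levels = observations[var].dropna().unique()
        if len(levels) < 2:
            warnings.warn(f"candidate {var!r} has fewer than two populated levels; dropped", stacklevel=2)
            continue
        try:
            fit = fit_cox(observations, [var], tie_method=tie_method)
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"candidate {var!r} dropped: {err}", stacklevel=2)
            continue
        fits[var] = fit
        if var in always_keep or fit.summary["p"].min() < alpha:
            selected.append(var)
    for var in always_keep:
        if var not in selected and var in observations.columns:
            selected.append(var)
    # keep the main exposure(s) first, then screened covariates in input order
    ordered = [v for v in always_keep if v in selected] + [
        v for v in candidate_vars if v in selected and v not in always_keep
    ]
    return ordered, fits


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics


def schoenfeld_residuals(fit: HazardModelFit) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals at each event, Breslow risk-set convention.

    Returns ``(event_times, residuals)`` with one row per event:
    ``x_k - xbar(t_k)`` where ``xbar`` is the hazard-weighted covariate mean
    over everyone still at risk at ``t_k`` (tied events share a risk set).
    """
    X = fit.design.to_numpy(float)
    beta = fit.params.to_numpy(float)
    times = fit.times
    events = fit.events
    order = np.argsort(-times, kind="stable")  # descending: cumulative sums give risk sets
    Xs, ts, es = X[order], times[order], events[order]
    w = np.exp(Xs @ beta)
    cw = np.cumsum(w)
    cwx = np.cumsum(Xs * w[:, None], axis=0)
    # risk set of t = all with time >= t; with descending sort that is a prefix,
    # extended over ties via searchsorted on the negated times
    neg = -ts
    resid = []
    etimes = []
    for k in np.flatnonzero(es):
        hi = np.searchsorted(neg, -ts[k], side="right") - 1
        xbar = cwx[hi] / cw[hi]
        resid.append(Xs[k] - xbar)
        etimes.append(ts[k])
    etimes = np.asarray(etimes)
    resid = np.asarray(resid)
    asc = np.argsort(etimes, kind="stable")
    return etimes[asc], resid[asc]


@dataclass
class SchoenfeldResult:
    """Grambsch-Therneau test of the proportional-hazards assumption."""

    table: pd.DataFrame  # per-term: correlation with time, chi2, df, p
    global_chi2: float
    global_df: int
    global_p: float
    transform: str


def schoenfeld_test(fit: HazardModelFit, transform: str = "identity") -> SchoenfeldResult:
    """Score test for a linear trend of scaled Schoenfeld residuals with time.

    Under proportional hazards the scaled residuals are trendless in time; a
    significant per-term or global statistic signals violation.  ``transform``
    maps event time to the trend variable: ``identity`` (default) or ``rank``.
    Needs at least two events.
    """
    if fit.n_events < 2:
        raise ValueError("Schoenfeld test needs at least two events")
    etimes, resid = schoenfeld_residuals(fit)
    d, p = resid.shape
    if transform == "identity":
        g = etimes.astype(float)
    elif transform == "rank":
        g = stats.rankdata(etimes).astype(float)
    else:
        raise ValueError("transform must be 'identity' or 'rank'")
    gc = g - g.mean()
    gss = float(np.sum(gc**2))
    if gss <= 0:
        raise ValueError("degenerate time transform (all event times equal)")
    vinv = fit.cov_params  # = I^{-1} of the fit
    u = resid.T @ gc  # per-term weighted residual sums
    scaled = d * (resid @ vinv)  # scaled residuals (constant beta-hat offset omitted)
    per_chi2 = (scaled.T @ gc) ** 2 / (d * gss * np.diag(vinv))
    per_p = stats.chi2.sf(per_chi2, 1)
    corr = np.array(
        [np.corrcoef(scaled[:, j], g)[0, 1] if np.std(scaled[:, j]) > 0 else np.nan for j in range(p)]
    )
    global_chi2 = float(d * (u @ vinv @ u) / gss)
    global_p = float(stats.chi2.sf(global_chi2, p))
    table = pd.DataFrame(
        {"rho": corr, "chi2": per_chi2, "df": 1, "p": per_p},
        index=fit.summary.index,
    )
    return SchoenfeldResult(table, global_chi2, p, global_p, transform)


def km_loglog(observations: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-group ``log(-log S(t))`` versus ``log t`` Kaplan-Meier coordinates.

    Under proportional hazards the group curves are parallel (constant
    vertical offsets).  Points with S = 1 are undefined and omitted; groups
    without any event are omitted with a warning.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    for lvl, sub in observations.groupby(group, observed=True):
        if not sub["event"].astype(bool).any():
            warnings.warn(f"group {lvl!r} has no events; curve omitted", stacklevel=2)
            continue
        km = KaplanMeierFitter()
        km.fit(sub["time_months"], sub["event"].astype(bool))
        s = km.survival_function_.iloc[:, 0]
        s = s[(s < 1.0) & (s > 0.0)]
        t = s.index.to_numpy(float)
        keep = t > 0
        frames.append(
            pd.DataFrame(
                {
                    group: lvl,
                    "time_months": t[keep],
                    "log_time": np.log(t[keep]),
                    "loglog_survival": np.log(-np.log(s.to_numpy()[keep])),
                }
            )
        )
    if not frames:
        raise ValueError("no group with events")
    return pd.concat(frames, ignore_index=True)
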