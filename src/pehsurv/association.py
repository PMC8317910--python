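"""Weighted descriptive mortality tables and chi-square association tests.

Descriptive percentages use the survey sampling weights; the chi-square tests
are computed on the unweighted counts (a deliberate simplification: no
design-corrected Rao-Scott statistic is attempted, since only scalar weights
are modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "weighted_crosstab",
    "chi_square",
    "significance_marker",
    "u5m_percentage_table",
]


@dataclass
class ContingencyTable:
    """Factor-level x {died, survived} table, weighted and unweighted."""

    factor: str
    row_labels: list
    counts: np.ndarray  # weighted, shape (r, 2), columns (died, survived)
    unweighted_counts: np.ndarray  # integer, same shape

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.unweighted_counts = np.asarray(self.unweighted_counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), 2):
            raise ValueError("counts must be (n_levels, 2)")
        if np.any(self.counts < 0) or np.any(self.unweighted_counts < 0):
            raise ValueError("cell counts must be nonnegative")

    @property
    def pct_dead(self) -> pd.Series:
        """Weighted percent dead per row (the %d column of a Table-1 layout)."""
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts[:, 0] / totals
        return pd.Series(pct, index=self.row_labels, name="pct_dead")

    @property
    def row_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.row_labels, name="total")


def weighted_crosstab(observations: pd.DataFrame, factor: str) -> ContingencyTable:
    """Cross-tabulate deaths against a categorical factor, weighted.

    Cell (level, died) is the sum of sampling weights of deaths at that
    level.  Empty strata are kept as zero rows (flagged with a warning, not
    fatal).  Percent dead is invariant under rescaling all weights.
    """
    if factor not in observations.columns:
        raise KeyError(f"factor {factor!r} not in observations")
    obs = observations.dropna(subset=[factor])
    levels = sorted(obs[factor].unique(), key=str)
    died = obs["event"].astype(bool).to_numpy()
    w = obs["weight"].to_numpy(float)
    counts = np.zeros((len(levels), 2))
    unweighted = np.zeros((len(levels), 2), dtype=int)
    for i, lvl in enumerate(levels):
        mask = (obs[factor] == lvl).to_numpy()
        counts[i, 0] = w[mask & died].sum()
        counts[i, 1] = w[mask & ~died].sum()
        unweighted[i, 0] = int((mask & died).sum())
        unweighted[i, 1] = int((mask & ~died).sum())
    if np.any(counts.sum(axis=1) == 0):
        warnings.warn(f"empty stratum in factor {factor!r}", stacklevel=2)
    return ContingencyTable(factor, list(levels), counts, unweighted)


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on the unweighted counts.

    ``X^2 = sum (O-E)^2 / E`` with ``df = (r-1)(c-1)``; zero rows/columns are
    dropped (with a warning) before testing.  No continuity correction by
    default.
    """
    counts = table.unweighted_counts
    keep_rows = counts.sum(axis=1) > 0
    keep_cols = counts.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("zero rows/columns dropped before chi-square test", stacklevel=2)
    counts = counts[keep_rows][:, keep_cols]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square test needs at least a 2x2 table after dropping empty levels")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def significance_marker(p: float) -> str:
    """Footnote marker at the thresholds *p<0.001, **p<0.01, ***p<0.005.

    The marker-to-threshold mapping is reproduced verbatim from the reporting
    convention this package mirrors, unusual ordering included: the most
    extreme p-values get a single star.
    """
    if p < 0.001:
        return "*"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def u5m_percentage_table(observations: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Tidy Table-1 analog: per factor level %dead, weighted total, marker.

    Single-level factors get descriptives only (no test).  The marker encodes
    the factor-level chi-square p-value per :func:`significance_marker`.
    """
    rows = []
    for factor in factors:
        tab = weighted_crosstab(observations, factor)
        if len(tab.row_labels) >= 2 and (tab.unweighted_counts.sum(axis=1) > 0).sum() >= 2:
            stat, df, p = chi_square(tab)
            marker = significance_marker(p)
        else:
            stat = df = p = np.nan
            marker = ""
        pct = tab.pct_dead
        totals = tab.row_totals
        for lvl in tab.row_labels:
            rows.append(
                {
                    "factor": factor,
                    "level": lvl,
                    "pct_dead": pct[lvl],
                    "total_weighted": totals[lvl],
                    "chi2": stat,
                    "df": df,
                    "p_value": p,
                    "marker": marker,
                }
            )
    return pd.DataFrame(rows)
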