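"""Correlation analysis of descriptor time series and equilibration checks.

A trajectory window sampled around a relative conformational minimum
should show no systematic trend in the contact-network descriptors: the
check computes Pearson correlations of every descriptor against time (and
against each other), with two-sided p-values from the t-distribution with
n−2 degrees of freedom, and calls a descriptor "drifting" when its
correlation with time is significant.  Frames are treated as independent
observations — reasonable at typical 10 ps spacing, and stated as a
caveat in the report — so the p-values are the plain textbook ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

STATIONARY = "stationary"
DRIFTING = "drifting"


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of descriptor series (incl. time)."""

    variables: list[str]
    r: pd.DataFrame  # symmetric, diagonal 1
    p: pd.DataFrame  # two-sided p-values
    n: int
    constant: dict[str, bool]  # variables with zero variance (r undefined)
    caveat: str = (
        "p-values assume independent frames; no autocorrelation correction"
    )

    def to_table(self) -> pd.DataFrame:
        """Upper-triangle correlation table for TSV export."""
        out = self.r.copy().astype(object)
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if j <= i:
                    out.loc[a, b] = ""
        return out


@dataclass
class EquilibrationVerdict:
    """Per-descriptor stationary/drifting verdict at level alpha."""

    verdicts: dict[str, str]
    alpha: float
    r_with_time: dict[str, float]
    p_with_time: dict[str, float]

    def stationary(self) -> bool:
        return all(v == STATIONARY for v in self.verdicts.values())


def correlation_matrix(
    series: pd.DataFrame, time_col: str | None = None
) -> CorrelationReport:
    """Pearson correlation matrix of a descriptor table.

    ``series`` is the per-frame descriptor table (as produced by
    ``descriptor_series``); the time column defaults to the first column.
    Constant series have undefined correlation: their entries are NaN and
    they are flagged in ``constant``.
    """
    if time_col is None:
        time_col = series.columns[0]
    numeric = series.select_dtypes(include=[np.number])
    cols = [time_col] + [c for c in numeric.columns if c != time_col]
    data = numeric[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 4:
        raise InsufficientDataError(f"need >= 4 frames, got {n}")
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    constant = {c: bool(np.isclose(np.std(data[:, i]), 0)) for i, c in enumerate(cols)}
    for i in range(m):
        for j in range(i + 1, m):
            if constant[cols[i]] or constant[cols[j]]:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                res = sps.pearsonr(data[:, i], data[:, j])
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationReport(variables=cols, r=r_df, p=p_df, n=n, constant=constant)


def equilibration_check(
    report: CorrelationReport, alpha: float = 0.05
) -> EquilibrationVerdict:
    """Call each descriptor stationary or drifting from its time correlation.

    A descriptor drifts when its correlation with time is significant at
    ``alpha``.  An undefined correlation (constant descriptor) is no
    evidence of drift, hence stationary.
    """
    time_var = report.variables[0]
    verdicts: dict[str, str] = {}
    r_t: dict[str, float] = {}
    p_t: dict[str, float] = {}
    for var in report.variables[1:]:
        r = float(report.r.loc[time_var, var])
        pv = float(report.p.loc[time_var, var])
        r_t[var] = r
        p_t[var] = pv
        drifting = (not np.isnan(pv)) and pv < alpha
        verdicts[var] = DRIFTING if drifting else STATIONARY
    return EquilibrationVerdict(
        verdicts=verdicts, alpha=alpha, r_with_time=r_t, p_with_time=p_t
    )
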