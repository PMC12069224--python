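"""Covariate screening: pairwise Pearson correlation and stepwise VIF elimination.

Collinear covariates destabilize distribution models. Pairs with |r| above a
threshold (default 0.8) are flagged for the report; actual removal is driven
by stepwise variance-inflation-factor elimination: while any remaining
variable has VIF = 1/(1-R^2) above the threshold (default 10), the worst
offender is removed (ties broken to the lexicographically smallest name).
Exact collinearity yields a non-finite VIF, treated as +infinity (removable),
so the loop always terminates with every survivor at VIF <= threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionReport", "pearson_matrix", "vif", "vif_stepwise"]

log = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    corr_matrix: pd.DataFrame
    flagged_pairs: list = field(default_factory=list)  # (var, var, r)
    elimination_order: list = field(default_factory=list)  # (var, vif at removal)
    retained: list = field(default_factory=list)

    @property
    def eliminated(self) -> list:
        return [name for name, _ in self.elimination_order]


def pearson_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation for every column pair; raises on zero-variance columns."""
    if data.isna().any().any():
        raise ValueError("design table contains missing values")
    sd = data.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    x = data.to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(r, index=data.columns, columns=data.columns)


def flag_pairs(corr: pd.DataFrame, r_threshold: float = 0.8) -> list:
    """Upper-triangle pairs with |r| strictly above the threshold."""
    names = corr.columns
    out = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            r = float(corr.iat[a, b])
            if abs(r) > r_threshold:
                out.append((names[a], names[b], r))
    return out


def vif(data: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1-R^2_j) of each column regressed (with intercept) on the rest.

    Non-finite values (perfect collinearity) come back as +inf.
    """
    if data.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    if data.shape[0] < data.shape[1] + 1:
        raise ValueError("need more rows than columns for VIF")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)  # centering absorbs the intercept
    out = {}
    for j, name in enumerate(data.columns):
        yj = x[:, j]
        xj = np.delete(x, j, axis=1)
        sst = float(yj @ yj)
        if sst == 0:
            raise ValueError(f"zero-variance column {name!r}")
        coef, *_ = np.linalg.lstsq(xj, yj, rcond=None)
        resid = yj - xj @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        denom = 1.0 - r2
        out[name] = np.inf if denom <= np.finfo(float).eps else 1.0 / denom
    return pd.Series(out)


def vif_stepwise(
    data: pd.DataFrame,
    vif_threshold: float = 10.0,
    r_threshold: float = 0.8,
) -> SelectionReport:
    """Iteratively drop the highest-VIF variable until all survivors pass.

    The correlation screen only flags pairs for the report; removal is decided
    by VIF alone (flagged pairs necessarily contain a high-VIF member, so a
    member of each is eliminated whenever |r| is high enough to push VIF past
    the threshold).
    """
    corr = pearson_matrix(data)
    report = SelectionReport(corr_matrix=corr, flagged_pairs=flag_pairs(corr, r_threshold))
    remaining = data.copy()
    while remaining.shape[1] >= 2:
        v = vif(remaining)
        worst = float(v.max())
        if not (worst > vif_threshold):
            break
        # ties: lexicographically smallest name, logged
        at_max = sorted(v.index[v == worst])
        victim = at_max[0]
        if len(at_max) > 1:
            log.info("VIF tie among %s; removing %r", at_max, victim)
        report.elimination_order.append((victim, worst))
        remaining = remaining.drop(columns=[victim])
    report.retained = list(remaining.columns)
    return report
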