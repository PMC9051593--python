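"""Cohort-level statistics: Pearson correlation, linear regression,
one-way ANOVA and group summaries.

Thin, contract-checked wrappers over scipy.stats: two-sided p-values
throughout, no multiple-testing correction (a handful of planned
correlations is reported raw), and pairwise deletion of missing values
since covariates may be absent for some subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tac_core import packaged_fixture

__all__ = ["pearson", "linreg", "oneway_anova", "summarize", "load_cohort_fixture"]


def _pairwise(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> dict:
    """Sample Pearson r with the two-sided p from t = r·√((n−2)/(1−r²))."""
    x, y = _pairwise(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(n)}


def linreg(x, y) -> dict:
    """OLS y on x: slope, intercept, R² (= r²) and 95% t-based CIs."""
    x, y = _pairwise(x, y)
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (zero variance)")
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "slope_ci95": (float(fit.slope - tcrit * fit.stderr),
                       float(fit.slope + tcrit * fit.stderr)),
        "intercept_ci95": (
            float(fit.intercept - tcrit * fit.intercept_stderr),
            float(fit.intercept + tcrit * fit.intercept_stderr),
        ),
        "n": int(n),
    }


def oneway_anova(groups: list) -> dict:
    """Classic one-way ANOVA between/within decomposition."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    f, p = stats.f_oneway(*arrs)
    k = len(arrs)
    n = sum(a.size for a in arrs)
    return {"F": float(f), "p": float(p), "df_between": k - 1,
            "df_within": n - k}


def summarize(column) -> dict:
    """mean ± SD (n−1), min, max, median; SD is NaN for a single value."""
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty column")
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
    }


def load_cohort_fixture() -> pd.DataFrame:
    """Packaged per-subject table: pancreatic volume, SUV_55min, Patlak Ki
    and fit R² for the 13-subject human cohort."""
    return pd.read_csv(packaged_fixture("human_cohort.csv"))
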