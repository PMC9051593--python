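"""Patlak and Logan graphical analyses.

Both linearize a tissue TAC against a plasma input past an equilibration
time t*:

* Patlak (irreversible uptake):  C_T/C_p  vs  ∫C_p/C_p; the slope is the
  net influx rate Ki, reported in mL/(mL·h) = 60 × slope per minute.
* Logan (reversible binding):  ∫C_T/C_T  vs  ∫C_p/C_T; the slope is the
  total distribution volume Vt (mL/mL).

Plain unweighted OLS on the transformed coordinates, with integrals
taken at frame midpoints (trapezoid, zero anchor at injection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .input_function import InputFunction
from .kinetic_models import data_checksum
from .tac_core import TimeActivityCurve, cumulative_integral

__all__ = ["PatlakResult", "LoganResult", "patlak_fit", "logan_fit", "tstar_scan"]

# Equilibration cut-off: the Patlak/Logan transient decays with the tissue
# efflux rate, and at this tracer's low specific-trapping rates the plot is
# only reliably linear from ~30 min; earlier windows bias the slope low.
DEFAULT_T_STAR = 30.0
DEFAULT_R2_FLOOR = 0.95


@dataclass
class PatlakResult:
    ki: float  # mL/(mL·h)
    intercept: float  # V0, mL/mL
    r_squared: float
    t_star: float
    n_points: int
    failed: bool
    aic: float = np.nan
    model_label: str = "patlak"
    n_params: int = 2
    data_hash: str = ""

    @property
    def ki_per_min(self) -> float:
        return self.ki / 60.0


@dataclass
class LoganResult:
    vt: float  # mL/mL
    intercept: float
    r_squared: float
    t_star: float
    n_points: int
    aic: float = np.nan
    model_label: str = "logan"
    n_params: int = 2
    data_hash: str = ""


def _window(schedule, t_star: float) -> np.ndarray:
    idx = np.flatnonzero(schedule.midpoints_min >= t_star - 1e-9)
    if idx.size < 3:
        raise ValueError(
            f"fewer than 3 frames with midpoint >= t* = {t_star} min"
        )
    return idx


def _ols(x: np.ndarray, y: np.ndarray):
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(np.sum(resid**2))
    n = x.size
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 2
    return fit.slope, fit.intercept, fit.rvalue**2, aic


def patlak_fit(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_star: float = DEFAULT_T_STAR,
    r2_floor: float = DEFAULT_R2_FLOOR,
) -> PatlakResult:
    """Patlak net-influx fit of one tissue TAC.

    ``failed`` flags a non-positive slope or R² below ``r2_floor`` —
    the behaviour expected when the irreversible-trapping assumption is
    violated (e.g. in tissue with fast tracer efflux).
    """
    idx = _window(tac.schedule, t_star)
    cp = input_fn.values
    if np.any(cp[idx] <= 0):
        raise ValueError("plasma input must be positive in the fit window")
    icp = cumulative_integral(input_fn.as_tac())
    x = icp[idx] / cp[idx]
    y = tac.values[idx] / cp[idx]
    slope, intercept, r2, aic = _ols(x, y)
    ki = 60.0 * slope
    failed = bool(slope <= 0 or r2 < r2_floor)
    return PatlakResult(
        ki=ki, intercept=intercept, r_squared=r2, t_star=t_star,
        n_points=idx.size, failed=failed, aic=aic,
        data_hash=data_checksum(tac.values),
    )


def logan_fit(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_star: float = DEFAULT_T_STAR,
) -> LoganResult:
    """Logan distribution-volume fit of one tissue TAC."""
    idx = _window(tac.schedule, t_star)
    ct = tac.values
    if np.any(ct[idx] <= 0):
        raise ValueError("tissue activity must be positive in the fit window")
    ict = cumulative_integral(tac)
    icp = cumulative_integral(input_fn.as_tac())
    x = icp[idx] / ct[idx]
    y = ict[idx] / ct[idx]
    slope, intercept, r2, aic = _ols(x, y)
    return LoganResult(
        vt=slope, intercept=intercept, r_squared=r2, t_star=t_star,
        n_points=idx.size, aic=aic, data_hash=data_checksum(tac.values),
    )


def tstar_scan(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_stars,
    method: str = "patlak",
    tol: float = 0.05,
) -> pd.DataFrame:
    """Slope stability vs candidate t* values.

    Returns one row per candidate with the fitted slope (Ki or Vt), R²
    and point count; ``recommended`` marks the smallest t* whose slope
    differs from the next larger candidate's by less than ``tol``
    (relative).  The last candidate has no successor and is recommended
    only if nothing earlier stabilized.
    """
    t_stars = sorted(t_stars)
    if len(t_stars) < 2:
        raise ValueError("need at least 2 candidate t* values")
    rows = []
    for ts in t_stars:
        try:
            if method == "patlak":
                r = patlak_fit(tac, input_fn, t_star=ts)
                rows.append({"t_star": ts, "slope": r.ki, "R2": r.r_squared,
                             "n_points": r.n_points, "failed": r.failed})
            elif method == "logan":
                r = logan_fit(tac, input_fn, t_star=ts)
                rows.append({"t_star": ts, "slope": r.vt, "R2": r.r_squared,
                             "n_points": r.n_points, "failed": False})
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError as err:
            if "unknown method" in str(err):
                raise
            rows.append({"t_star": ts, "slope": np.nan, "R2": np.nan,
                         "n_points": 0, "failed": True})
    table = pd.DataFrame(rows)
    table["recommended"] = False
    slopes = table["slope"].to_numpy()
    for i in range(len(table) - 1):
        s0, s1 = slopes[i], slopes[i + 1]
        if np.isfinite(s0) and np.isfinite(s1) and s1 != 0:
            if abs(s0 - s1) / abs(s1) < tol:
                table.loc[i, "recommended"] = True
                break
    else:
        ok = np.flatnonzero(np.isfinite(slopes))
        if ok.size:
            table.loc[ok[-1], "recommended"] = True
    return table
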