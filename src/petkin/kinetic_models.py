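"""One- and two-tissue compartment models: simulation, fitting, macros.

Model (plasma input C_p, tissue compartments C1 free/nonspecific, C2
specifically bound):

    dC1/dt = K1·C_p − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2

The 1-tissue model is the special case k3 = k4 = 0; the irreversible
2-tissue model fixes k4 = 0 (tracer trapped after binding, the regime in
which Patlak analysis applies).  The measured PET value per frame is the
frame-time average of (1 − vB)·(C1 + C2) + vB·C_blood.

The tissue response is the convolution of C_p with a bi-exponential
kernel; with C_p interpolated piecewise-linearly between frame mid-times
the convolution has a closed form, evaluated here exactly (no ODE
stepping).  Frame averages use Gauss–Legendre nodes inside each frame.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .input_function import InputFunction
from .tac_core import FrameSchedule, TimeActivityCurve

__all__ = [
    "CompartmentParams",
    "CompartmentFitResult",
    "simulate_tissue",
    "macro_vt",
    "macro_ki",
    "fit_compartment",
    "compare_models",
    "MODELS",
]

MODELS = ("1tcm", "2tcm", "2tcm-irr")

_INIT_GRID = {
    "K1": (0.1, 0.5),
    "k2": (0.1, 0.5),
    "k3": (0.01, 0.1),
    "k4": (0.0, 0.05),
}


@dataclass(frozen=True)
class CompartmentParams:
    """Micro-parameters.  K1 in mL plasma/(mL tissue · min); k's in 1/min."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0
    model: str = "2tcm"

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.vB < 1.0:
            raise ValueError("vB must lie in [0, 1)")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "2tcm-irr" and self.k4 != 0.0:
            raise ValueError("irreversible model requires k4 == 0")
        if self.model == "1tcm" and (self.k3 != 0.0 or self.k4 != 0.0):
            raise ValueError("1-tissue model requires k3 == k4 == 0")


@dataclass
class CompartmentFitResult:
    params: CompartmentParams
    r_squared: float
    aic: float
    converged: bool
    residuals: np.ndarray
    rss: float = 0.0
    n_params: int = 0
    model_label: str = ""
    data_hash: str = ""


def macro_vt(params: CompartmentParams) -> float:
    """Total distribution volume Vt = (K1/k2)·(1 + k3/k4), mL/mL.

    Defined only for reversible kinetics; an irreversible model (k4 = 0)
    has no finite equilibrium volume.
    """
    if params.k2 <= 0:
        raise ValueError("Vt requires k2 > 0")
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 <= 0:
        raise ValueError("Vt undefined for irreversible kinetics (k4 = 0)")
    return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)


def macro_ki(params: CompartmentParams) -> float:
    """Net influx rate K1·k3/(k2 + k3), 1/min (× 60 for mL/[mL·h])."""
    denom = params.k2 + params.k3
    if denom <= 0:
        raise ValueError("Ki requires k2 + k3 > 0")
    return params.K1 * params.k3 / denom


# ---------------------------------------------------------------------------
# Exact convolution of a piecewise-linear input with exp(-theta * t)
# ---------------------------------------------------------------------------

def _exp_conv_pwl(theta: float, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """y(t_i) = ∫₀^{t_i} e^{−θ(t_i−s)} C(s) ds for piecewise-linear C.

    Recursive per segment; exact for each linear piece including θ = 0
    (where the kernel is constant and the integral is the trapezoid).
    """
    y = np.zeros_like(t)
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        a = c[i - 1]
        b = (c[i] - c[i - 1]) / dt
        if theta * dt < 1e-12:
            y[i] = y[i - 1] + (c[i - 1] + c[i]) * dt / 2.0
        else:
            e = np.exp(-theta * dt)
            g = (1.0 - e) / theta  # ∫₀^Δ e^{-θ(Δ-s)} ds
            y[i] = y[i - 1] * e + a * g + b * (dt - g) / theta
    return y


def _kernel_terms(p: CompartmentParams) -> list[tuple[float, float]]:
    """(weight, rate) pairs of the tissue impulse response h(t) = Σ wᵢ e^{−θᵢ t}."""
    s = p.k2 + p.k3 + p.k4
    disc = s * s - 4.0 * p.k2 * p.k4
    root = np.sqrt(max(disc, 0.0))
    th1 = (s - root) / 2.0
    th2 = (s + root) / 2.0
    if th2 - th1 < 1e-10:  # repeated eigenvalue: perturb; error O(1e-10)
        th2 = th1 + 1e-10
    w1 = p.K1 * (p.k3 + p.k4 - th1) / (th2 - th1)
    w2 = p.K1 * (th2 - p.k3 - p.k4) / (th2 - th1)
    return [(w1, th1), (w2, th2)]


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


def simulate_tissue(
    params: CompartmentParams,
    input_fn: InputFunction,
    schedule: FrameSchedule | None = None,
    whole_blood: np.ndarray | None = None,
) -> TimeActivityCurve:
    """Noise-free tissue TAC predicted by a compartment model.

    The plasma input is interpolated linearly between (0, 0) and the
    frame mid-time samples, held constant past the last mid-time.  Frame
    values are exact 5-node Gauss–Legendre averages over each frame.
    """
    if schedule is None:
        schedule = input_fn.schedule
    cp = np.asarray(input_fn.values, dtype=float)
    if not np.all(np.isfinite(cp)):
        raise ValueError("input function must be finite")
    t_in = input_fn.schedule.midpoints_min
    knots_t = np.concatenate(([0.0], t_in, [schedule.ends[-1] / 60.0 + 1.0]))
    knots_c = np.concatenate(([0.0], cp, [cp[-1]]))

    # Gauss-Legendre nodes within every frame, merged with the input knots
    f0 = schedule.starts / 60.0
    f1 = schedule.ends / 60.0
    nodes = (f0[:, None] + f1[:, None]) / 2.0 + (
        (f1 - f0)[:, None] / 2.0
    ) * _GL_NODES[None, :]
    grid = np.unique(np.concatenate([knots_t, nodes.ravel()]))
    c_grid = np.interp(grid, knots_t, knots_c)

    ct_grid = np.zeros_like(grid)
    for w, theta in _kernel_terms(params):
        if w != 0.0:
            ct_grid += w * _exp_conv_pwl(theta, grid, c_grid)

    idx = np.searchsorted(grid, nodes.ravel()).reshape(nodes.shape)
    frame_vals = (ct_grid[idx] * _GL_WEIGHTS[None, :]).sum(axis=1) / 2.0

    if params.vB > 0.0:
        cb = cp if whole_blood is None else np.asarray(whole_blood, dtype=float)
        cb_nodes = np.interp(nodes, knots_t, np.concatenate(([0.0], cb, [cb[-1]])))
        cb_frame = (cb_nodes * _GL_WEIGHTS[None, :]).sum(axis=1) / 2.0
        frame_vals = (1.0 - params.vB) * frame_vals + params.vB * cb_frame

    return TimeActivityCurve(
        schedule=schedule, values=frame_vals, region_label=f"sim_{params.model}"
    )


# ---------------------------------------------------------------------------
# Nonlinear fitting
# ---------------------------------------------------------------------------

def _param_names(model: str, fit_vb: bool) -> list[str]:
    names = {"1tcm": ["K1", "k2"], "2tcm-irr": ["K1", "k2", "k3"],
             "2tcm": ["K1", "k2", "k3", "k4"]}[model]
    return names + (["vB"] if fit_vb else [])


def _make_params(model: str, theta: np.ndarray, fit_vb: bool) -> CompartmentParams:
    kw = dict(zip(_param_names(model, fit_vb), theta))
    return CompartmentParams(model=model, **kw)


def data_checksum(values: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(values, dtype=float).tobytes()).hexdigest()[:12]


def fit_compartment(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    model: str = "2tcm",
    init: np.ndarray | None = None,
    bounds: tuple | None = None,
    weights: str | np.ndarray | None = None,
    fit_vb: bool = False,
) -> CompartmentFitResult:
    """Weighted least-squares compartment fit with a deterministic
    multi-start grid (no random restarts, so refits are reproducible).

    ``weights``: None for uniform, ``"duration"`` for w ∝ frame length,
    or an explicit per-frame array.  AIC = n·ln(RSS/n) + 2p.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    names = _param_names(model, fit_vb)
    n_par = len(names)
    y = tac.values
    n = y.size
    if n < n_par + 2:
        raise ValueError("too few frames for the requested model")
    if np.allclose(y, 0.0):
        raise ValueError("degenerate TAC (all zeros): nothing to fit")

    if weights is None:
        w = np.ones(n)
    elif isinstance(weights, str) and weights == "duration":
        w = tac.schedule.durations_min.copy()
    else:
        w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w / w.sum() * n)

    if bounds is None:
        hi = {"K1": 10.0, "k2": 10.0, "k3": 5.0, "k4": 5.0, "vB": 0.999}
        bounds = (np.zeros(n_par), np.array([hi[p] for p in names]))

    def residuals(theta):
        pred = simulate_tissue(_make_params(model, theta, fit_vb), input_fn,
                               tac.schedule)
        return sw * (pred.values - y)

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        axes = [_INIT_GRID[p] if p in _INIT_GRID else (0.02,) for p in names]
        mesh = np.meshgrid(*axes, indexing="ij")
        starts = [np.array(pt) for pt in zip(*(m.ravel() for m in mesh))]

    best = None
    for x0 in starts:
        x0c = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            sol = least_squares(residuals, x0c, bounds=bounds,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    res = best.fun / sw  # unweighted residuals for reporting
    rss = float(np.sum(best.fun**2))
    tss = float(np.sum((sw * (y - y.mean())) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_par
    return CompartmentFitResult(
        params=_make_params(model, best.x, fit_vb),
        r_squared=r2,
        aic=float(aic),
        converged=bool(best.success),
        residuals=res,
        rss=rss,
        n_params=n_par,
        model_label=model + ("+vB" if fit_vb else ""),
        data_hash=data_checksum(y),
    )


def compare_models(fits: list) -> pd.DataFrame:
    """Rank candidate fits of ONE tissue curve by AIC.

    Accepts compartment and graphical results alike (anything exposing
    ``model_label``, ``r_squared``, ``aic``, ``n_params`` and
    ``data_hash``).  Ties in AIC go to the model with fewer parameters.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits if getattr(f, "data_hash", "")}
    if len(hashes) > 1:
        raise ValueError("fits come from different TACs; comparison is meaningless")
    rows = [
        {
            "model": f.model_label,
            "R2": f.r_squared,
            "AIC": f.aic,
            "n_params": f.n_params,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["AIC", "n_params"], kind="stable"
    ).reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table
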