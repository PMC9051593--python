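"""Arterial plasma input-function construction.

An image-derived whole-blood curve (descending-aorta ROI) is converted to
the plasma concentration of intact tracer by two multiplicative
population corrections measured in venous/arterial samples:

* the plasma-to-whole-blood partition ratio R_pb(t), and
* the intact (parent) fraction f_intact(t) of plasma radioactivity.

C_p,intact(t) = C_blood(t) · R_pb(t) · f_intact(t)

Both corrections are sparse sample tables interpolated linearly; with
three sample points there is no basis for fitting curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tac_core import FrameSchedule, TimeActivityCurve, packaged_fixture

__all__ = [
    "CorrectionCurve",
    "InputFunction",
    "interpolate_correction",
    "blood_to_plasma",
    "metabolite_correct",
    "build_idif",
    "intact_fraction_default",
    "plasma_blood_ratio_default",
    "read_correction_csv",
]


@dataclass(frozen=True)
class CorrectionCurve:
    """Sparse population correction samples vs time.

    ``anchor_at_zero``: value assumed at t = 0.  For the intact fraction
    this is 1.0 (freshly injected tracer is by definition unmetabolized);
    for the partition ratio no physical anchor exists and ``None`` holds
    the first sample constant back to t = 0.
    """

    times_min: np.ndarray
    values: np.ndarray
    anchor_at_zero: float | None = None
    name: str = ""

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if t.size == 0:
            raise ValueError("correction curve needs at least one sample")
        if t.shape != v.shape:
            raise ValueError("times and values must match")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("correction values must be positive")


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma concentration per frame."""

    schedule: FrameSchedule
    values: np.ndarray
    provenance: dict | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.schedule),):
            raise ValueError("input-function length must equal frame count")
        if not np.all(np.isfinite(v)):
            raise ValueError("input-function values must be finite")

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.schedule.midpoints_min

    def as_tac(self) -> TimeActivityCurve:
        return TimeActivityCurve(
            schedule=self.schedule, values=self.values, region_label="plasma_input"
        )


def interpolate_correction(curve: CorrectionCurve, t) -> np.ndarray | float:
    """Evaluate a correction curve at time(s) ``t`` (minutes).

    Linear between samples; constant beyond the last sample; before the
    first sample, linear toward ``anchor_at_zero`` when one is given,
    otherwise constant at the first sample.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("correction times must be non-negative")
    if curve.anchor_at_zero is not None:
        xs = np.concatenate(([0.0], curve.times_min))
        ys = np.concatenate(([curve.anchor_at_zero], curve.values))
        if curve.times_min[0] == 0.0:
            xs, ys = curve.times_min, curve.values
    else:
        xs, ys = curve.times_min, curve.values
    out = np.interp(t_arr, xs, ys)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def blood_to_plasma(
    blood_tac: TimeActivityCurve, ratio_curve: CorrectionCurve
) -> TimeActivityCurve:
    """Whole-blood → plasma: multiply by R_pb at each frame mid-time."""
    factors = interpolate_correction(ratio_curve, blood_tac.schedule.midpoints_min)
    return blood_tac.with_values(blood_tac.values * factors, region_label="plasma")


def metabolite_correct(
    plasma_tac: TimeActivityCurve, intact_curve: CorrectionCurve
) -> InputFunction:
    """Plasma → intact-tracer plasma: multiply by the parent fraction."""
    factors = np.atleast_1d(
        interpolate_correction(intact_curve, plasma_tac.schedule.midpoints_min)
    )
    if np.any(factors > 1.0 + 1e-12) or np.any(factors <= 0):
        raise ValueError("intact fractions must lie in (0, 1]")
    return InputFunction(
        schedule=plasma_tac.schedule,
        values=plasma_tac.values * factors,
        provenance={
            "blood_tac": plasma_tac.region_label,
            "intact_curve": intact_curve.name,
        },
    )


def build_idif(
    blood_tac: TimeActivityCurve,
    ratio_curve: CorrectionCurve,
    intact_curve: CorrectionCurve,
) -> InputFunction:
    """Image-derived input function: partition then metabolite correction.

    Exactly the composition ``metabolite_correct(blood_to_plasma(...))``;
    per frame the output/input ratio is R_pb(t_mid) · f_intact(t_mid).
    """
    plasma = blood_to_plasma(blood_tac, ratio_curve)
    fn = metabolite_correct(plasma, intact_curve)
    return InputFunction(
        schedule=fn.schedule,
        values=fn.values,
        provenance={
            "blood_tac": blood_tac.region_label,
            "ratio_curve": ratio_curve.name,
            "intact_curve": intact_curve.name,
        },
    )


# ---------------------------------------------------------------------------
# Packaged population corrections (arterial samples at 5/30/60 min, n=3)
# ---------------------------------------------------------------------------

def read_correction_csv(path, anchor_at_zero=None, name="") -> CorrectionCurve:
    df = pd.read_csv(path)
    return CorrectionCurve(
        times_min=df["time_min"].to_numpy(float),
        values=df["value"].to_numpy(float),
        anchor_at_zero=anchor_at_zero,
        name=name or str(path),
    )


def intact_fraction_default() -> CorrectionCurve:
    """Population intact-tracer fraction, anchored to 1.0 at injection."""
    return read_correction_csv(
        packaged_fixture("intact_fraction.csv"), anchor_at_zero=1.0,
        name="intact_fraction",
    )


def plasma_blood_ratio_default() -> CorrectionCurve:
    """Population plasma-to-whole-blood partition ratio (≈1.8 throughout)."""
    return read_correction_csv(
        packaged_fixture("plasma_blood_ratio.csv"), name="plasma_blood_ratio"
    )
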