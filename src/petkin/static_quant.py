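"""Static quantification: SUV, the 50–60-min simplified readout, and
whole-organ receptor content (Ki × segmented volume).

SUV normalizes tissue concentration by injected activity per body
weight, assuming 1 g ≡ 1 mL of tissue:

    SUV = C [kBq/mL] / (A_inj [kBq] / W [g]) = C · W / A_inj

with C in kBq/mL, W in kg and A_inj in MBq (the kilo factors cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tac_core import TimeActivityCurve

__all__ = ["SubjectDose", "StaticResult", "suv", "suv_55min", "total_content",
           "DEFAULT_SUV_WINDOW_MIN"]

DEFAULT_SUV_WINDOW_MIN = (50.0, 60.0)


@dataclass(frozen=True)
class SubjectDose:
    """Injected activity, body weight and co-injected peptide mass."""

    injected_MBq: float
    weight_kg: float
    peptide_ug_per_kg: float = 0.0

    def __post_init__(self):
        if self.injected_MBq <= 0 or self.weight_kg <= 0:
            raise ValueError("injected activity and weight must be positive")
        if self.peptide_ug_per_kg < 0:
            raise ValueError("peptide mass dose cannot be negative")


@dataclass
class StaticResult:
    suv_55min: float
    volume_ml: float
    ki: float | None = None  # mL/(mL·h)
    total_content: float | None = None  # mL²/(mL·h)


def suv(concentration_kBq_mL: float, dose: SubjectDose) -> float:
    """Body-weight SUV of a single concentration value."""
    return concentration_kBq_mL * dose.weight_kg / dose.injected_MBq


def suv_55min(
    tac: TimeActivityCurve,
    dose: SubjectDose,
    window_min: tuple[float, float] = DEFAULT_SUV_WINDOW_MIN,
) -> float:
    """SUV of the mean concentration over the late static window.

    With the packaged 30-frame schedule the default 50–60-min window is
    exactly the last 600-s frame; for other schedules the mean is
    duration-weighted over the overlapping frames.
    """
    lo_s, hi_s = window_min[0] * 60.0, window_min[1] * 60.0
    sched = tac.schedule
    exact = sched.frame_covering(lo_s, hi_s)
    if exact is not None:
        return suv(tac.values[exact], dose)
    overlap = np.minimum(sched.ends, hi_s) - np.maximum(sched.starts, lo_s)
    overlap = np.clip(overlap, 0.0, None)
    if overlap.sum() <= 0:
        raise ValueError(
            f"schedule has no frames inside the {window_min} min window"
        )
    mean_c = float(np.sum(tac.values * overlap) / overlap.sum())
    return suv(mean_c, dose)


def total_content(ki_mL_per_mL_h: float, volume_ml: float) -> float:
    """Whole-organ receptor content: Ki (mL/[mL·h]) × organ volume (mL)."""
    if ki_mL_per_mL_h <= 0 or volume_ml <= 0:
        raise ValueError("Ki and volume must be positive")
    return ki_mL_per_mL_h * volume_ml
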