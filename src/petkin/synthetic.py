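"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of (config, seed): identical calls
are bit-identical.  Each returns a *truth record* holding every
generating parameter, so downstream estimates (Patlak Ki, Logan Vt,
SUV, IC50) can be checked against analytic ground truth at any stage.

What is emulated
----------------
* a smooth arterial plasma curve — linear upslope to an early peak,
  then tri-exponential washout — plus the matching whole-blood curve
  obtained by *dividing out* the plasma-partition and intact-fraction
  corrections, so input-function construction round-trips exactly;
* tissue TACs from compartment models over the 30-frame/60-min
  schedule: pancreas irreversible 2-tissue (receptor trapping), spleen
  and muscle 1-tissue with low Vt (receptor-negative), kidney
  irreversible with high influx (excretion);
* a cohort whose true Ki is linear in age (negative) and BMI
  (positive) with noise, sized so the population correlations are
  about −0.6 and +0.5 at n = 13;
* dose-escalation series from a one-site competition curve;
* a labeled 4-D phantom for ROI-extraction tests.

Frame noise is Gaussian with SD = c·√(C/Δt) — the count-statistics
heuristic that longer frames and lower activity mean lower relative
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseEscalationSeries, one_site_binding
from .input_function import (
    CorrectionCurve,
    InputFunction,
    intact_fraction_default,
    interpolate_correction,
    plasma_blood_ratio_default,
)
from .kinetic_models import CompartmentParams, simulate_tissue
from .static_quant import SubjectDose, suv_55min
from .tac_core import FrameSchedule, LabeledImage4D, TimeActivityCurve, default_schedule

__all__ = [
    "GeneratorConfig",
    "SubjectBundle",
    "synth_input_function",
    "synth_subject",
    "synth_cohort",
    "synth_dose_escalation",
    "synth_phantom",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all generators.  Defaults mirror the imaging
    protocol being emulated: 0.46 ± 0.03 MBq/kg injected, 0.14 ± 0.04
    µg/kg peptide (ceiling 0.2), ages 50–76 y, BMI 31.2 ± 3.0 kg/m²,
    pancreatic volumes 48–135 mL, net-influx rates centred near
    0.63 mL/(mL·h) spanning roughly 0.38–0.97."""

    seed: int = 0
    schedule: FrameSchedule = field(default_factory=default_schedule)

    # arterial input: linear rise to the peak, tri-exponential decay
    input_peak_time_min: float = 1.0
    input_peak_suv: float = 82.0
    input_exp_fractions: tuple = (0.65, 0.30, 0.05)
    input_exp_rates_per_min: tuple = (3.0, 0.30, 0.035)

    # subject-level distributions
    age_range_y: tuple = (50.0, 76.0)
    bmi_mean: float = 31.2
    bmi_sd: float = 3.0
    height_mean_m: float = 1.75
    height_sd_m: float = 0.07
    mbq_per_kg_mean: float = 0.46
    mbq_per_kg_sd: float = 0.03
    peptide_mean_ug_kg: float = 0.14
    peptide_sd_ug_kg: float = 0.04
    peptide_ceiling_ug_kg: float = 0.2
    volume_range_ml: tuple = (48.0, 135.0)

    # pancreatic kinetic truth: Ki (mL/[mL·h]) linear in age and BMI
    ki_mean: float = 0.63
    beta_age_per_y: float = -0.016
    beta_bmi: float = 0.0333
    ki_noise_sd: float = 0.125
    ki_clip: tuple = (0.20, 1.20)
    pancreas_K1: float = 0.5
    pancreas_k2: float = 0.25

    # receptor-negative / excretory reference tissues
    spleen_params: tuple = (0.6, 0.6)     # 1TCM (K1, k2), Vt = 1.0
    muscle_params: tuple = (0.10, 0.25)   # 1TCM, Vt = 0.4
    kidney_params: tuple = (0.7, 0.3, 0.15)  # 2TCM-irr (K1, k2, k3)

    # frame noise SD = noise_coeff * sqrt(C / frame_minutes)
    noise_coeff: float = 0.10

    # dose-escalation truth (binding in Vt-like units)
    ic50_truth_ug_kg: float = 0.45
    binding_b0: float = 30.0
    binding_ns: float = 2.0
    escalation_noise_frac: float = 0.10


@dataclass
class SubjectBundle:
    """Everything one synthetic subject contributes to the pipeline."""

    subject_id: str
    tacs: dict  # region -> TimeActivityCurve (noisy)
    blood_tac: TimeActivityCurve  # uncorrected aorta whole-blood curve
    input_fn: InputFunction  # noise-free generating plasma-intact input
    dose: SubjectDose
    truth: dict


def _plasma_curve(config: GeneratorConfig, t_min: np.ndarray,
                  peak_kbq_ml: float) -> np.ndarray:
    tp = config.input_peak_time_min
    fr = np.asarray(config.input_exp_fractions, dtype=float)
    lam = np.asarray(config.input_exp_rates_per_min, dtype=float)
    if np.any(lam < 0):
        raise ValueError("washout rates must be non-negative")
    t = np.asarray(t_min, dtype=float)
    rising = np.clip(t / tp, 0.0, 1.0) * peak_kbq_ml
    decay = peak_kbq_ml * np.sum(
        fr[None, :] * np.exp(-lam[None, :] * np.clip(t - tp, 0.0, None)[:, None]),
        axis=1,
    ) / fr.sum()
    return np.where(t < tp, rising, decay)


def synth_input_function(
    config: GeneratorConfig,
    dose: SubjectDose | None = None,
    ratio_curve: CorrectionCurve | None = None,
    intact_curve: CorrectionCurve | None = None,
) -> tuple[InputFunction, TimeActivityCurve]:
    """Deterministic plasma-intact input plus the matching blood curve.

    The whole-blood TAC is the plasma curve divided by R_pb·f_intact at
    each frame mid-time, so `build_idif(blood, ...)` reproduces the
    generating input to machine precision.
    """
    sched = config.schedule
    t = sched.midpoints_min
    per_g = (dose.injected_MBq / dose.weight_kg) if dose is not None else 0.46
    peak = config.input_peak_suv * per_g  # kBq/mL at the arterial peak
    plasma = _plasma_curve(config, t, peak)
    ratio_curve = ratio_curve or plasma_blood_ratio_default()
    intact_curve = intact_curve or intact_fraction_default()
    factors = interpolate_correction(ratio_curve, t) * interpolate_correction(
        intact_curve, t
    )
    blood = TimeActivityCurve(
        schedule=sched, values=plasma / factors, region_label="aorta"
    )
    fn = InputFunction(schedule=sched, values=plasma,
                       provenance={"generator": "synth_input_function"})
    return fn, blood


def _frame_noise(rng, values, durations_min, coeff):
    sd = coeff * np.sqrt(np.clip(values, 1e-6, None) / durations_min)
    return rng.normal(0.0, 1.0, size=values.shape) * sd


def _draw_covariates(config: GeneratorConfig, rng) -> dict:
    age = rng.uniform(*config.age_range_y)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd)
    height = rng.normal(config.height_mean_m, config.height_sd_m)
    weight = bmi * height**2
    mbq_kg = rng.normal(config.mbq_per_kg_mean, config.mbq_per_kg_sd)
    peptide = float(np.clip(
        rng.normal(config.peptide_mean_ug_kg, config.peptide_sd_ug_kg),
        0.01, config.peptide_ceiling_ug_kg,
    ))
    return {
        "age_y": float(age), "bmi": float(bmi), "weight_kg": float(weight),
        "injected_MBq": float(mbq_kg * weight), "peptide_ug_per_kg": peptide,
        "sex": "F" if rng.random() < 1.0 / 13.0 else "M",
    }


def _ki_truth(config: GeneratorConfig, cov: dict, rng) -> float:
    age_mid = 0.5 * (config.age_range_y[0] + config.age_range_y[1])
    ki = (
        config.ki_mean
        + config.beta_age_per_y * (cov["age_y"] - age_mid)
        + config.beta_bmi * (cov["bmi"] - config.bmi_mean)
        + rng.normal(0.0, config.ki_noise_sd)
    )
    return float(np.clip(ki, *config.ki_clip))


def _pancreas_params(config: GeneratorConfig, ki_h: float) -> CompartmentParams:
    # invert Ki = K1*k3/(k2+k3) for k3 given fixed K1, k2
    kappa = ki_h / 60.0
    K1, k2 = config.pancreas_K1, config.pancreas_k2
    if kappa >= K1:
        raise ValueError("requested Ki exceeds the deliverable flow K1")
    k3 = k2 * kappa / (K1 - kappa)
    return CompartmentParams(K1=K1, k2=k2, k3=k3, k4=0.0, model="2tcm-irr")


def synth_subject(
    config: GeneratorConfig,
    seed: int,
    covariates: dict | None = None,
    subject_id: str = "synthetic",
) -> SubjectBundle:
    """One subject: noisy tissue TACs, blood curve, dose and full truth."""
    rng = np.random.default_rng(seed)
    cov = covariates if covariates is not None else _draw_covariates(config, rng)
    ki_h = cov.get("ki_true") or _ki_truth(config, cov, rng)
    dose = SubjectDose(
        injected_MBq=cov["injected_MBq"],
        weight_kg=cov["weight_kg"],
        peptide_ug_per_kg=cov["peptide_ug_per_kg"],
    )
    input_fn, blood = synth_input_function(config, dose=dose)
    params = {
        "pancreas": _pancreas_params(config, ki_h),
        "spleen": CompartmentParams(*config.spleen_params, model="1tcm"),
        "muscle": CompartmentParams(*config.muscle_params, model="1tcm"),
        "kidney": CompartmentParams(*config.kidney_params, model="2tcm-irr"),
    }
    volume = float(rng.uniform(*config.volume_range_ml))
    durations = config.schedule.durations_min
    tacs, clean = {}, {}
    for region, p in params.items():
        tac = simulate_tissue(p, input_fn, config.schedule)
        clean[region] = tac
        noisy = tac.values + _frame_noise(rng, tac.values, durations,
                                          config.noise_coeff)
        vol = volume if region == "pancreas" else None
        tacs[region] = tac.with_values(noisy, region_label=region,
                                       volume_ml=vol)
    tacs["aorta"] = blood
    truth = {
        "ki_true_mL_per_mL_h": ki_h,
        "params": params,
        "suv55_true": suv_55min(clean["pancreas"], dose),
        "volume_ml": volume,
        "covariates": cov,
        "seed": seed,
    }
    return SubjectBundle(
        subject_id=subject_id, tacs=tacs, blood_tac=blood,
        input_fn=input_fn, dose=dose, truth=truth,
    )


def synth_cohort(
    config: GeneratorConfig, n: int = 13, seed: int | None = None
) -> tuple[pd.DataFrame, list[SubjectBundle]]:
    """A cohort of subjects with covariate-linked true Ki.

    The returned table holds the *generating* truth per subject; the
    pipeline's job is to recover it from the TAC bundles.
    """
    if n < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n)
    bundles, rows = [], []
    for i, s in enumerate(sub_seeds):
        b = synth_subject(config, int(s), subject_id=f"S{i + 1:02d}")
        bundles.append(b)
        cov = b.truth["covariates"]
        rows.append({
            "subject_id": b.subject_id,
            "ki_true": b.truth["ki_true_mL_per_mL_h"],
            "suv55_true": b.truth["suv55_true"],
            "volume_mL": b.truth["volume_ml"],
            "total_content_true": b.truth["ki_true_mL_per_mL_h"]
            * b.truth["volume_ml"],
            "age_y": cov["age_y"],
            "bmi": cov["bmi"],
            "sex": cov["sex"],
            "weight_kg": cov["weight_kg"],
            "injected_MBq": cov["injected_MBq"],
            "peptide_ug_per_kg": cov["peptide_ug_per_kg"],
        })
    return pd.DataFrame(rows), bundles


# 12-scan escalation grid: 5 animals, each scanned at increasing mass dose
DEFAULT_ESCALATION_DOSES = (
    2.0, 0.05, 1.0, 10.0, 0.15, 20.0, 0.05, 1.0, 3.0, 0.0025, 0.5, 15.0
)


def synth_dose_escalation(
    config: GeneratorConfig,
    doses=DEFAULT_ESCALATION_DOSES,
    seed: int | None = None,
) -> tuple[DoseEscalationSeries, dict]:
    """One-site self-blocking series over a mass-dose escalation."""
    doses = np.asarray(doses, dtype=float)
    if doses.size < 4:
        raise ValueError("an escalation needs at least 4 doses")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    clean = one_site_binding(
        np.where(doses == 0.0, 1e-3, doses),
        config.binding_b0, config.binding_ns, config.ic50_truth_ug_kg,
    )
    noisy = clean * (1.0 + config.escalation_noise_frac * rng.normal(size=doses.size))
    series = DoseEscalationSeries(
        doses_ug_per_kg=doses, binding=noisy,
        scan_ids=tuple(f"scan{i + 1}" for i in range(doses.size)),
        metric="vt",
    )
    truth = {
        "ic50": config.ic50_truth_ug_kg, "b0": config.binding_b0,
        "ns": config.binding_ns, "clean_binding": clean, "seed": seed,
    }
    return series, truth


def synth_phantom(
    config: GeneratorConfig,
    seed: int | None = None,
    grid: int = 16,
    voxel_volume_ml: float = 0.5,
    voxel_noise_sd: float = 0.0,
    tacs: dict | None = None,
) -> tuple[LabeledImage4D, dict]:
    """A small labeled 4-D phantom: disjoint boxes filled with region TACs.

    With zero voxel noise the extracted ROI mean equals the generating
    TAC exactly; with noise its standard error shrinks as 1/√voxels.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if tacs is None:
        bundle = synth_subject(config, seed)
        tacs = {k: v for k, v in bundle.tacs.items() if k != "aorta"}
    n_frames = len(config.schedule)
    vox = np.zeros((grid, grid, grid, n_frames))
    labels = np.zeros((grid, grid, grid), dtype=int)
    names = {}
    slab = max(grid // (len(tacs) + 1), 2)
    for code, (region, tac) in enumerate(tacs.items(), start=1):
        z0 = (code - 1) * slab
        block = (slice(2, grid - 2), slice(2, grid - 2), slice(z0, z0 + slab - 1))
        if np.any(labels[block] != 0):
            raise ValueError("phantom labels overlap")
        labels[block] = code
        names[code] = region
        vox[block] = tac.values[None, None, None, :]
        if voxel_noise_sd > 0:
            vox[block] += rng.normal(
                0.0, voxel_noise_sd, size=vox[block].shape
            )
    truth = {"label_names": names, "tacs": tacs, "seed": seed,
             "voxel_volume_ml": voxel_volume_ml}
    return (
        LabeledImage4D(voxels=vox, voxel_volume_ml=voxel_volume_ml,
                       labels=labels, label_names=names),
        truth,
    )
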