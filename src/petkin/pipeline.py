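"""End-to-end orchestration: per-subject quantification and cohort assembly.

run_subject: aorta blood TAC → input function (partition + metabolite
corrections) → Patlak Ki (the primary readout), Logan Vt, optional
compartment fits → SUV over the late static window → whole-organ
receptor content → QC flags.  run_cohort assembles subjects and reports
the cross-subject correlations (notably SUV_55min vs Ki).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort_stats
from .dose_response import DEFAULT_MASS_CEILING
from .graphical import DEFAULT_R2_FLOOR, DEFAULT_T_STAR, logan_fit, patlak_fit
from .input_function import (
    CorrectionCurve,
    build_idif,
    intact_fraction_default,
    plasma_blood_ratio_default,
)
from .kinetic_models import fit_compartment
from .static_quant import DEFAULT_SUV_WINDOW_MIN, SubjectDose, suv_55min, total_content

__all__ = ["RunConfig", "run_subject", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    t_star: float = DEFAULT_T_STAR
    mass_ceiling_ug_kg: float = DEFAULT_MASS_CEILING
    suv_window_min: tuple = DEFAULT_SUV_WINDOW_MIN
    r2_floor: float = DEFAULT_R2_FLOOR
    models: tuple = ()  # e.g. ("1tcm", "2tcm-irr"); empty = graphical only
    target_region: str = "pancreas"
    blood_region: str = "aorta"
    ratio_curve: CorrectionCurve | None = None
    intact_curve: CorrectionCurve | None = None


def run_subject(
    tacs: dict,
    dose: SubjectDose,
    config: RunConfig = RunConfig(),
    volume_ml: float | None = None,
) -> dict:
    """Quantify one subject from its region TACs.

    ``tacs`` maps region name → TimeActivityCurve and must contain the
    blood region (input signal) and the target region.  Failed fits are
    propagated as QC flags, not exceptions.
    """
    for required in (config.blood_region, config.target_region):
        if required not in tacs:
            raise KeyError(f"required region {required!r} missing from TACs")
    ratio = config.ratio_curve or plasma_blood_ratio_default()
    intact = config.intact_curve or intact_fraction_default()
    input_fn = build_idif(tacs[config.blood_region], ratio, intact)

    target = tacs[config.target_region]
    pat = patlak_fit(target, input_fn, t_star=config.t_star,
                     r2_floor=config.r2_floor)
    try:
        log = logan_fit(target, input_fn, t_star=config.t_star)
        logan_vt = log.vt
    except ValueError:
        log, logan_vt = None, np.nan

    compartment, fit_errors = {}, []
    for model in config.models:
        try:
            compartment[model] = fit_compartment(target, input_fn, model=model)
        except (ValueError, RuntimeError) as err:
            compartment[model] = None
            fit_errors.append(f"compartment fit {model} failed: {err}")

    suv = suv_55min(target, dose, window_min=config.suv_window_min)
    vol = volume_ml if volume_ml is not None else target.volume_ml
    content = (
        total_content(pat.ki, vol)
        if (vol is not None and vol > 0 and pat.ki > 0)
        else np.nan
    )

    qc = {
        "patlak_failed": pat.failed,
        "patlak_r2": pat.r_squared,
        "mass_dose_exceeds_ceiling":
            dose.peptide_ug_per_kg > config.mass_ceiling_ug_kg,
        "volume_known": vol is not None,
        "fit_errors": fit_errors,
        "provenance": {
            "input_fn": input_fn.provenance,
            "Ki": "patlak_fit",
            "Vt": "logan_fit",
            "SUV55": "suv_55min",
            "total_content": "Ki * volume",
        },
    }
    return {
        "input_fn": input_fn,
        "patlak": pat,
        "logan": log,
        "compartment": compartment,
        "Ki": pat.ki,
        "Vt": logan_vt,
        "SUV55": suv,
        "volume_mL": vol,
        "total_content": content,
        "qc": qc,
    }


def run_cohort(
    subjects: list,
    config: RunConfig = RunConfig(),
    pairs: tuple = (("SUV55", "Ki"),),
) -> dict:
    """Run every subject and correlate the requested column pairs.

    ``subjects``: iterable of (subject_id, tacs, dose, volume_ml).
    Returns the per-subject table plus a Pearson report per pair.
    """
    subjects = list(subjects)
    if len(subjects) < 3:
        raise ValueError("cohort analysis needs at least 3 subjects")
    rows = []
    for sid, tacs, dose, vol in subjects:
        res = run_subject(tacs, dose, config=config, volume_ml=vol)
        rows.append({
            "subject_id": sid,
            "Ki": res["Ki"],
            "Vt": res["Vt"],
            "SUV55": res["SUV55"],
            "volume_mL": res["volume_mL"],
            "total_content": res["total_content"],
            "patlak_failed": res["qc"]["patlak_failed"],
            "patlak_r2": res["qc"]["patlak_r2"],
        })
    table = pd.DataFrame(rows)
    correlations = {}
    for x, y in pairs:
        if x in table.columns and y in table.columns:
            correlations[f"{x}:{y}"] = cohort_stats.pearson(
                table[x].to_numpy(), table[y].to_numpy()
            )
    return {"table": table, "correlations": correlations}
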