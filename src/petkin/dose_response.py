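"""Self-blocking dose-response analysis.

A receptor agonist tracer co-injected with increasing amounts of its own
unlabeled peptide occupies the target and lowers the apparent binding.
Binding (Vt or SUV) vs mass dose D follows a one-site competition curve

    B(D) = NS + (B0 − NS) / (1 + D / IC50)

with baseline binding B0, a nonspecific floor NS, and the in vivo IC50 —
the mass dose halving specific binding.  Fitting this across a dose
escalation locates the ceiling below which self-blocking is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .static_quant import SubjectDose

__all__ = [
    "DoseEscalationSeries",
    "InhibitionFit",
    "one_site_binding",
    "fit_inhibition",
    "percent_of_baseline",
    "mass_ceiling_check",
    "DEFAULT_MASS_CEILING",
]

DEFAULT_MASS_CEILING = 0.2  # µg/kg; tracer-only scans sit below this


@dataclass(frozen=True)
class DoseEscalationSeries:
    """(mass dose µg/kg, binding value) pairs across escalation scans.

    A recorded dose of exactly 0 is replaced by ``carrier_ug_per_kg``,
    the tracer's own unavoidable carrier mass — the log-dose axis has no
    place for a true zero.
    """

    doses_ug_per_kg: np.ndarray
    binding: np.ndarray
    scan_ids: tuple = ()
    metric: str = "vt"
    carrier_ug_per_kg: float = 1e-3

    def __post_init__(self):
        d = np.asarray(self.doses_ug_per_kg, dtype=float)
        b = np.asarray(self.binding, dtype=float)
        if d.shape != b.shape or d.ndim != 1:
            raise ValueError("doses and binding must be 1-D and equal length")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        d = np.where(d == 0.0, self.carrier_ug_per_kg, d)
        object.__setattr__(self, "doses_ug_per_kg", d)
        object.__setattr__(self, "binding", b)

    def __len__(self):
        return self.doses_ug_per_kg.size


@dataclass
class InhibitionFit:
    b0: float
    ns: float
    ic50_ug_per_kg: float
    r_squared: float
    converged: bool
    ill_posed: bool = False
    flags: list = field(default_factory=list)

    def predict(self, dose) -> np.ndarray:
        return one_site_binding(np.asarray(dose, dtype=float), self.b0,
                                self.ns, self.ic50_ug_per_kg)


def one_site_binding(dose, b0, ns, ic50):
    return ns + (b0 - ns) / (1.0 + dose / ic50)


def fit_inhibition(series: DoseEscalationSeries) -> InhibitionFit:
    """Least-squares one-site competition fit on a dose escalation.

    Requires ≥4 scans spanning ≥2 decades of dose for a well-posed IC50;
    narrower designs are fitted anyway but flagged ``ill_posed``.  IC50
    is parameterized on a log10 scale internally, keeping it positive
    without an active bound.  Flat binding series are flagged degenerate.
    """
    d = series.doses_ug_per_kg
    b = series.binding
    flags = []
    ill_posed = False
    if len(series) < 4:
        ill_posed = True
        flags.append("fewer than 4 scans")
    if d.max() / d.min() < 100.0:
        ill_posed = True
        flags.append("dose range spans < 2 decades")
    spread = b.max() - b.min()
    if spread < 1e-12 or spread < 0.05 * abs(b).max():
        flags.append("degenerate: binding nearly flat across doses")
        return InhibitionFit(
            b0=float(b.mean()), ns=float(b.mean()), ic50_ug_per_kg=np.nan,
            r_squared=0.0, converged=False, ill_posed=True, flags=flags,
        )

    def model(dose, b0, ns, log10_ic50):
        return one_site_binding(dose, b0, ns, 10.0**log10_ic50)

    p0 = (float(b.max()), float(b.min()),
          float(np.log10(np.sqrt(d.min() * d.max()))))
    try:
        popt, _ = curve_fit(
            model, d, b, p0=p0,
            bounds=([0.0, 0.0, -6.0], [np.inf, np.inf, 6.0]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
        flags.append("optimizer failed to converge")
    b0, ns, lic50 = popt
    pred = model(d, *popt)
    ss_res = float(np.sum((b - pred) ** 2))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if b0 <= ns:
        flags.append("fitted baseline does not exceed nonspecific floor")
        converged = False
    return InhibitionFit(
        b0=float(b0), ns=float(ns), ic50_ug_per_kg=float(10.0**lic50),
        r_squared=r2, converged=converged, ill_posed=ill_posed, flags=flags,
    )


def percent_of_baseline(
    series: DoseEscalationSeries,
    baseline_ceiling: float = DEFAULT_MASS_CEILING,
) -> np.ndarray:
    """Binding as % of the mean over tracer-only (dose ≤ ceiling) scans."""
    base = series.binding[series.doses_ug_per_kg <= baseline_ceiling]
    if base.size == 0:
        raise ValueError(
            f"no baseline scans with dose <= {baseline_ceiling} µg/kg"
        )
    return 100.0 * series.binding / base.mean()


def mass_ceiling_check(
    subjects: list[SubjectDose],
    ceiling: float = DEFAULT_MASS_CEILING,
) -> pd.DataFrame:
    """Flag subjects whose co-injected peptide mass exceeds the ceiling.

    The summary row carries the cohort mean ± SD of the mass dose; an
    empty subject list yields an empty report.
    """
    rows = [
        {
            "index": i,
            "peptide_ug_per_kg": s.peptide_ug_per_kg,
            "exceeds_ceiling": s.peptide_ug_per_kg > ceiling,
        }
        for i, s in enumerate(subjects)
    ]
    report = pd.DataFrame(rows, columns=["index", "peptide_ug_per_kg",
                                         "exceeds_ceiling"])
    if len(report):
        doses = report["peptide_ug_per_kg"].to_numpy()
        report.attrs["mean"] = float(doses.mean())
        report.attrs["sd"] = float(doses.std(ddof=1)) if doses.size > 1 else np.nan
        report.attrs["n_flagged"] = int(report["exceeds_ceiling"].sum())
    return report
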