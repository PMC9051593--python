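# Methods

## Scope and data flow

The package quantifies receptor binding of a ⁶⁸Ga-labeled agonist
peptide (exendin4, targeting pancreatic GLP1R) from dynamic PET. The
processing chain is:

1. **TACs** — region time–activity curves over a frame schedule, either
   read from CSV or extracted as label means from a 4-D image with an
   integer mask (`tac_core`). Time is minutes internally; file formats
   carry seconds. Frames are assumed decay-corrected to injection time
   on ingest (the scanner convention); explicit decay operations exist
   for fixture manipulation only (Ga-68 half-life 67.71 min).
2. **Input function** — the aorta whole-blood TAC multiplied, at each
   frame mid-time, by the plasma-to-whole-blood partition ratio and the
   intact-tracer fraction (`input_function`).
3. **Kinetics** — compartment-model fits and Patlak/Logan graphical
   analysis against that input (`kinetic_models`, `graphical`).
4. **Static readout** — SUV over the 50–60-min window, and whole-organ
   receptor content Ki × volume (`static_quant`).
5. **Dose–response** — one-site competition fit of binding vs
   co-injected peptide mass (`dose_response`).
6. **Cohort statistics** — Pearson, OLS regression, one-way ANOVA,
   mean ± SD summaries (`cohort_stats`), assembled per-subject by
   `pipeline`.

## Frame schedule and integration

The default acquisition is 30 frames over 60 min (12×10 s, 6×30 s,
5×120 s, 5×300 s, 2×600 s); the last 600-s frame is exactly the
50–60-min static window. A 33-frame, 90-min variant (`long_schedule`,
5×600-s tail) exists because reversible-tracer quantification needs the
longer acquisition (below).

Integrals ∫₀ᵗC dτ are trapezoids on the grid {0, frame mid-times…} with
C(0) = 0: no tracer is present before injection, and the 10-s early
frames make the gridding error over the arterial peak negligible. No
resampling is done anywhere; all transforms are evaluated at frame
mid-times.

## Input-function corrections

The two population correction curves are sparse tables (samples at 5,
30 and 60 min, from arterial sampling in a 3-subject subset):

* intact fraction 0.981 / 0.952 / 0.901, anchored to 1.0 at t = 0 —
  freshly injected tracer is unmetabolized by definition;
* plasma-to-blood ratio 1.76 / 1.80 / 1.79, held constant before the
  first sample (no physical anchor exists) and after the last.

Interpolation is linear: three points cannot constrain curvature, and
any smoother rule would be an invention. Population (not per-subject)
corrections are applied to every subject. The same corrections are used
for the synthetic pathway; a species-specific partition value can be
passed as a custom `CorrectionCurve`.

## Compartment simulation and fitting

The tissue response is the convolution of the plasma input with the
bi-exponential impulse response of the two-tissue system (eigenrates
θ₁,₂ = [(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]/2). With the input
interpolated piecewise-linearly between (0,0) and the frame mid-time
samples, the convolution has a closed form which is evaluated exactly,
segment by segment — no ODE stepping, no stiffness issues, and exact
linearity in K₁. Model predictions are frame-time **averages** (5-node
Gauss–Legendre per frame), not mid-time samples, because 300–600-s
frames are long relative to early kinetics.

Fitting is bounded nonlinear least squares (scipy `least_squares`) from
a small deterministic multi-start grid (K₁∈{0.1,0.5}, k₂∈{0.1,0.5},
k₃∈{0.01,0.1}, k₄∈{0,0.05}); no random restarts, so refits are
bit-reproducible. Weights are uniform by default with an optional
frame-duration weighting (w ∝ Δt). The blood-volume fraction vB is fixed
to 0 by default and fit only on request; when vB > 0 and no separate
whole-blood curve is supplied, the plasma input is used for the blood
term (a documented approximation). Model comparison reports
AIC = n·ln(RSS/n) + 2p; ties go to the model with fewer parameters, and
fits of different TACs are refused (each result carries a checksum of
the data it was fit to).

## Graphical analysis and the choice of t\*

Patlak and Logan fits are unweighted OLS on the transformed coordinates
— the standard practice, and the transparent spreadsheet-equivalent
computation. Ki is reported in mL/(mL·h) (60 × the per-minute slope).
A Patlak fit is flagged `failed` when the slope is non-positive or R²
falls below a configurable floor (default 0.95): the expected behaviour
when the irreversible-trapping assumption is violated or the signal is
noise-dominated.

**Default t\* = 30 min.** The Patlak transient decays with the tissue
efflux rate k₂+k₃ *as seen through the still-decaying input*: the
apparent intercept drifts until the intermediate washout component of
the plasma curve (≈0.3/min here) is negligible relative to its slow
tail. At this tracer's low specific-trapping rates (Ki of
0.4–1.0 mL/(mL·h) ⇒ k₃ ≈ 0.003–0.009/min) the slope is small, so the
drift that remains at 20 min biases Ki ~15% low on noise-free data; by
30 min the bias is <1% with 4 fit points on the 30-frame schedule.
`tstar_scan` automates the slope-stability check (smallest t\* whose
slope is within 5% of the next larger candidate).

**Logan on a 90-min schedule.** For reversible two-tissue kinetics with
slow binding (e.g. K₁=0.5, k₂=0.25, k₃=0.05, k₄=0.025, slow eigenrate
0.0205/min ⇒ τ ≈ 49 min), the Logan slope on a 60-min scan is ~7% below
the true Vt at any feasible t\*; with the 90-min schedule and t\* = 50
the agreement is within 3%. Distribution-volume quantification therefore
uses `long_schedule`; the 60-min protocol is intended for the
irreversible (Patlak/SUV) readouts.

## SUV and receptor content

SUV = C·W/A_inj (C in kBq/mL, W in kg, A_inj in MBq; 1 g ≡ 1 mL tissue
assumed). Plain body-weight SUV — no lean-mass or BSA variants. The
50–60-min window is resolved by exact frame match first, else as a
duration-weighted mean of overlapping frames. Whole-organ content is
the definitional product Ki × mask-derived volume (voxel count × voxel
volume); its units mL²/(mL·h) are kept explicit rather than cancelled.

## Dose–response

One-site competition with a free nonspecific floor (3 parameters:
B₀, NS, IC₅₀), least squares on linear binding with IC₅₀ parameterized
as log₁₀(IC₅₀) internally, which keeps it positive without an active
bound. A recorded dose of exactly 0 is mapped to the tracer's own
carrier mass (default 10⁻³ µg/kg) — the log-dose axis has no zero. Fits
are flagged ill-posed with <4 scans or <2 decades of dose span, and
degenerate when binding is flat. With 10% multiplicative noise a single
12-scan series gives a scattered IC₅₀ estimate (unlucky draws at the
extreme doses can move the global optimum several-fold), so recovery
claims are made about the median over replicate series, which is within
a few percent of truth.

## Synthetic data: what it emulates, and what it does not

Defaults encode the study conditions being emulated: 0.46 ± 0.03 MBq/kg
injected activity, 0.14 ± 0.04 µg/kg peptide (ceiling 0.2 µg/kg), ages
uniform 50–76 y, BMI 31.2 ± 3.0 kg/m², pancreatic volume uniform
48–135 mL (independent of covariates), and true Ki linear in age
(−0.016 per year) and BMI (+0.033 per kg/m²) around 0.63 mL/(mL·h) with
residual SD 0.125, clipped to [0.2, 1.2] — calibrated so the population
correlations are ≈−0.6 with age and ≈+0.5 with BMI at n = 13. These
covariate effect sizes emulate reported cohort-level correlations; they
are not fits to per-subject data.

The arterial input is a linear upslope to a peak at 1 min (amplitude
82 SUV-equivalent, scaled by each subject's injected activity per gram)
followed by tri-exponential washout (fractions 0.65/0.30/0.05, rates
3.0/0.30/0.035 per min) — chosen once so the pancreatic SUV₅₅ spans
roughly 2–6 across a default cohort, with blood at ~2.5% of peak by
60 min. Pancreas TACs come from the irreversible two-tissue model
(K₁ = 0.5, k₂ = 0.25, k₃ solved from the subject's Ki); spleen and
muscle are one-tissue with Vt 1.0 and 0.4 (receptor-negative
references); kidney is irreversible with high influx (excretion). The
whole-blood curve is the plasma curve *divided* by the corrections at
frame mid-times, so input-function construction round-trips to machine
precision — a deliberate inverse construction, not a physiological
model of red-cell partitioning dynamics.

Frame noise is Gaussian with SD = c·√(C/Δt) (c = 0.1 by default), the
count-statistics heuristic. Not emulated: scanner physics (PSF, scatter,
randoms), partial-volume and spill-over effects (e.g. kidney into the
pancreatic tail), patient motion, per-subject metabolite variation, and
anatomically realistic geometry. Passing tests therefore demonstrate
correctness of the estimators under the assumed kinetic and noise model,
not robustness to those real-data effects.

Every generator is a pure function of (config, seed) — identical calls
are bit-identical — and returns a truth record sufficient to compute any
downstream quantity analytically.

## Numerical choices and degenerate inputs

* Repeated compartment eigenvalues are separated by 10⁻¹⁰ (error of the
  same order); θ·Δt < 10⁻¹² falls back to the trapezoid limit.
* All-zero TACs are rejected before fitting; non-convergence is a flag,
  not an exception, in the pipeline.
* Patlak requires C_p > 0 and Logan C_T > 0 over the fit window; both
  require ≥3 points past t\*.
* Pearson/regression use pairwise deletion of missing values (cohort
  covariates may be partial); two-sided p-values; no multiple-testing
  correction (a handful of planned correlations is reported raw).
* SD uses n−1; a single observation reports SD = NaN rather than 0.

## Known limitations

* The Patlak failure criterion (R² floor) and t\* are conventions;
  different GUI tools use other, usually undocumented, rules.
* No partial-volume or spill-over correction is implemented.
* Logan estimates carry the well-known noise-induced negative bias at
  high noise; no multilinear or bias-corrected variants are provided.
* The in vivo IC₅₀ conflates receptor occupancy with delivery effects;
  no conversion to Bmax/Kd is attempted (the design cannot support it).
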