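# petkin

Quantification of dynamic PET scans of receptor-binding peptide tracers,
built around pancreatic GLP1R imaging with ⁶⁸Ga-labeled exendin4. The
package turns region time–activity curves (TACs) and an aorta blood
signal into receptor-binding readouts, and ships a synthetic-data module
that generates every input the pipeline needs, with known ground truth.

## Who it is for

PET kinetic modellers and imaging scientists who need a scripted,
auditable alternative to GUI kinetic-analysis tools for:

* image-derived input functions (IDIF) with plasma-partition and
  metabolite (intact-fraction) corrections,
* compartment-model and graphical (Patlak, Logan) kinetic analysis,
* SUV-based protocol simplification (a 50–60-min static scan in place of
  a full dynamic acquisition),
* in vivo self-blocking dose–response (IC₅₀) analysis for agonist
  tracers, and
* cohort statistics (Pearson/regression/ANOVA) over the resulting
  per-subject readouts.

## The model

Tissue kinetics follow the standard two-tissue compartment model with
plasma input C_p(t):

    dC₁/dt = K₁·C_p − (k₂ + k₃)·C₁ + k₄·C₂
    dC₂/dt = k₃·C₁ − k₄·C₂

For a tracer that is trapped after receptor binding and internalization
(k₄ = 0), the Patlak plot

    C_T(t)/C_p(t)  vs  ∫₀ᵗ C_p dτ / C_p(t)

becomes linear past an equilibration time t\*, with slope the net influx
rate **Ki = K₁k₃/(k₂+k₃)**, reported in mL/(mL·h). For reversible
kinetics the Logan plot yields the total distribution volume
**Vt = (K₁/k₂)(1 + k₃/k₄)**. The input C_p is built from the aorta blood
TAC as C_blood(t)·R_pb(t)·f_intact(t), using packaged population curves
for the plasma-to-blood partition ratio (≈1.8) and the intact-tracer
fraction (98→90% over an hour). The simplified static readout is
SUV₅₅ = C̄(50–60 min)·W/A_inj, and whole-organ receptor content is
Ki × segmented organ volume. Self-blocking across co-injected peptide
mass doses D follows one-site competition,
B(D) = NS + (B₀−NS)/(1+D/IC₅₀).

## Worked example

```python
import petkin as pk

cfg = pk.GeneratorConfig()                      # protocol defaults
truth, bundles = pk.synth_cohort(cfg, n=13, seed=7)
subjects = [(b.subject_id, b.tacs, b.dose, b.truth["volume_ml"])
            for b in bundles]
report = pk.run_cohort(subjects)

row = report["table"].iloc[0]
print(f"subject {row.subject_id}: Ki = {row.Ki:.2f} mL/(mL*h), "
      f"SUV55 = {row.SUV55:.2f}, volume = {row.volume_mL:.0f} mL, "
      f"total content = {row.total_content:.1f}")
corr = report["correlations"]["SUV55:Ki"]
print(f"cohort r(SUV55, Ki) = {corr['r']:.3f} "
      f"(p = {corr['p']:.2e}, n = {corr['n']})")
```

prints

```
subject S01: Ki = 0.65 mL/(mL*h), SUV55 = 4.02, volume = 79 mL, total content = 51.6
cohort r(SUV55, Ki) = 0.961 (p = 1.73e-07, n = 13)
```

Subject S01's pancreas clears 0.65 mL of plasma per mL of tissue per
hour into irreversible binding (the generating truth for that subject is
also 0.65); its static SUV and organ volume give a whole-organ content
of 51.6 mL²/(mL·h). Across the cohort the simplified SUV₅₅ readout
tracks the fully modelled Ki closely (r = 0.96), which is the evidence
needed to replace a dynamic scan with a short static one.

The same steps are available from the shell:

```
petkin synth --n 13 --seed 7 -o data/
petkin run --subjects data/ -o results/
petkin patlak --tac data/S01_tacs.csv --input input.csv --region pancreas
```

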