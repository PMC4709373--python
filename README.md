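# ferrodyn

Drug–disease modelling of serum ferritin under deferoxamine iron-chelation
therapy, for pharmacometricians and clinical-pharmacology researchers
working on transfusional iron overload (e.g. β-thalassaemia major).

Patients on chronic red-blood-cell transfusion accumulate iron; serum
ferritin is the routine biomarker, and keeping it below ~2500 μg/L is a
standard therapeutic goal.  `ferrodyn` implements a population PKPD
(drug–disease) model of that process end to end:

* **Disease model** — an indirect-response (turnover) equation,

  `dF/dt = Kin + CRT(F) − Kout · F · (1 + SLP · TCss_av)`,

  where the transfusion-driven production `CRT = SCL·exp(−SHP·F)` is damped
  by the current ferritin level and both `SCL` and `SHP` scale with disease
  status as power laws in `F / F_med`.
* **PK exposure** — a two-compartment deferoxamine model with zero-order
  (infusion) input, allometric scaling (weight^0.75 on clearances,
  weight^1.0 on volumes) and the average steady-state concentration
  `Css_av` as the exposure metric.
* **Adherence** — dosing calendars (250 scheduled doses/year at 5
  days/week), the two canonical non-adherence patterns (random missed doses
  and drug holidays at four stratification periods), and the observational
  adherence proxy `CMPL` deflating exposure as `TCss_av = Css_av·(1−CMPL)`.
* **Decision support** — time to reach the 2500 μg/L threshold (censored at
  5 years) over dose × weight × baseline grids and adherence scenarios.
* **Estimation** — nonlinear mixed-effects fitting (Laplace approximation
  with exact forward-sensitivity gradients): log-normal between-subject
  variability on the drug-effect slope, between-occasion variability on the
  conversion rate, proportional residual error; bootstrap and visual
  predictive checks.
* **Synthetic cohorts** — a generator reproducing the reference study's
  design (27 patients, 2–3-monthly sampling for up to 10 years, ~40
  observations/patient, latent adherence traits), so the whole pipeline is
  testable without clinical data.

See `docs/methods.md` for the model, parameterisation and numerical
choices.

## Worked example

```python
from ferrodyn import (DEFAULT_PK, InfusionRegimen, css_average,
                      DiseaseParameters, DrugEffectParameters,
                      steady_state, time_to_threshold)
from ferrodyn.scenarios import compliance_grid, effectiveness_boundary

regimen = InfusionRegimen(dose_per_kg=45.0, body_weight=45.0)  # 5 d/wk, 8 h
css = css_average(DEFAULT_PK, regimen).css_av
disease, drug = DiseaseParameters(), DrugEffectParameters()

print(f"Css_av = {css:.3f} mg/L")
print(f"untreated steady state = {steady_state(disease, drug, 0.0):.0f} ug/L")
print(f"on-treatment steady state = {steady_state(disease, drug, css):.0f} ug/L")
t = time_to_threshold(4000.0, css, disease, drug, warn_above_untreated=False)
print(f"time to 2500 ug/L from 4000 = {t:.3f} years")

grid = compliance_grid(baselines=(3000.0,), n_seeds=20, seed=0)
print(f"largest effective missed-dose fraction = "
      f"{effectiveness_boundary(grid, 3000.0):.0%}")
```

prints

```
Css_av = 4.350 mg/L
untreated steady state = 4937 ug/L
on-treatment steady state = 2190 ug/L
time to 2500 ug/L from 4000 = 1.202 years
largest effective missed-dose fraction = 20%
```

Reading: a fully adherent 45 kg patient on 45 mg/kg/day sees an average
deferoxamine exposure of 4.35 mg/L, which pulls the ferritin equilibrium
from 4937 down to 2190 μg/L — below the moderate/severe boundary — and a
patient starting at 4000 μg/L crosses 2500 μg/L after ~1.2 years.  Once
more than ~20% of doses are missed, the equilibrium under these parameter
values sits above 2500 μg/L and the target is no longer reachable from a
3000 μg/L baseline within 5 years under any missing pattern.

A command-line interface mirrors the library:

```sh
ferrodyn synthesize --seed 1 --out cohort.csv      # virtual cohort dataset
ferrodyn fit --data cohort.csv --out fit.json      # population estimation
ferrodyn scenarios --mode compliance --out grid.csv
ferrodyn simulate --baseline 4000 --exposure 4.35 --years 3 --out traj.csv
ferrodyn vpc --data cohort.csv --out vpc.csv
```

Datasets use the NONMEM column convention
(`ID, TIME, DV, AMT, RATE, WT, OCC, CMPL, EVID, MDV`, TIME in hours);
configuration is YAML merged over the package defaults.

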