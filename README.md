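# eqdose

Mechanistic PK/PD modelling of doxorubicin treatment response and the
**equivalent dose** metric.

Conventional dose–response assays summarise treatment by the extracellular
drug concentration, conflating how much drug a cell line takes up with how
sensitive it is to the drug once inside. `eqdose` implements a framework
that decouples the two: a compartmental pharmacokinetic model of drug
uptake, a population pharmacodynamic model of cell-count dynamics, and a
single biophysically based summary of any treatment schedule — the
equivalent dose — that can be inverted to quantify how a sensitizing agent
(an efflux-pump inhibitor such as tariquidar, or a DNA-repair inhibitor
such as a DNA-PK inhibitor) modulates an individual pharmacologic rate
constant using only population-scale cell counts.

It is intended for quantitative pharmacologists and systems biologists
analysing time-lapse *in vitro* treatment-response and drug-uptake assays.

## Models

**Uptake (PK).** Doxorubicin concentration in three pools — extracellular
(`C_E`), free intracellular (`C_F`), nucleus-bound (`C_B`), all in nM:

```
dC_E/dt = k_FE (v_I/v_E) C_F − k_EF C_E
dC_F/dt = k_EF (v_E/v_I) C_E − (k_FE + k_FB) C_F
dC_B/dt = k_FB C_F
```

`k_EF`, `k_FE`, `k_FB` (h⁻¹) are influx, efflux and *net* binding (binding
mixed with DNA repair). Media replacements reset `C_E` instantaneously.
Each inter-event segment is linear, so the package solves it analytically
(symmetrised eigendecomposition plus exact quadrature); a stiff adaptive
integrator is kept as an independent cross-check.

**Equivalent dose.** `D_eq` of a treatment schedule is the maximum
nucleus-bound concentration `C_B` the model predicts — a functional
measure of delivered drug that absorbs cell-line differences in uptake,
efflux and binding.

**Response (PD).** Cell counts follow logistic growth with a
treatment-induced death rate switched on at `t = 0`:

```
dN/dt = (k_p − k_d(t)) N (1 − N/θ),
k_d(t) = (1−λ) k_d,a + λ k_d,b · r t e^(1−rt)
```

mixing an immediate stable death rate (apoptosis-like) with a transient
kernel peaking at `t = 1/r` (mitotic-catastrophe-like). The equation has a
closed-form solution, used throughout.

**Inverse procedure.** Monotherapy fits define a response surface
`p(D_eq) = [k_d,a, k_d,b, r]`. A co-treatment condition's fitted `p` is
matched onto the surface (L2, range- or uncertainty-normalised) to
estimate its equivalent dose `D_est`, and the per-level sensitizer effect
on a single rate `k_x` is recovered by minimising
`G(k_x) = Σᵢ (D_est,i − Dᵢ(k_x))²` under a hard monotonicity constraint
across sensitizer levels (the reciprocal is optimised for rates the
sensitizer decreases).

A companion `unmixing` module reproduces the imaging pipeline behind the
uptake measurements: median-disc illumination correction (`I = L(C+b)`),
a fluorophore×channel mixing matrix built from control images, QR-based
linear unmixing, and linear signal-to-concentration calibration. The
`synthetic` module generates every input kind with known ground truth.

## Worked example

```python
import numpy as np
from eqdose import PKParams, TreatmentCourse, equivalent_dose, simulate_pk, UptakeModel
from eqdose.synthetic import StudyDesign, UPTAKE_PK, gen_pk_dataset

# rates measured for an MDR1-overexpressing breast-cancer line
params = PKParams(k_EF=3.08e-6, k_FE=0.313, k_FB=0.0212, v_ratio=1e4)
course = TreatmentCourse.pulse(1000.0, 8.0, horizon_h=24.0)  # 1 uM x 8 h, watch 24 h
print(simulate_pk(params, course, np.linspace(0, 24, 5)).to_dataframe().round(3))
print("D_eq =", round(equivalent_dose(params, course), 2), "nM")

# fit the model to a synthetic uptake assay (3 wells, 25-min sampling, 50 nM noise)
design = StudyDesign()
df, truth = gen_pk_dataset(UPTAKE_PK, design.uptake_course(), design, seed=0)
res = UptakeModel.from_dataframe(df, design.uptake_course()).fit(n_starts=16, seed=0)
print(res.summary())
```

prints

```
   time_h    C_E_nM  C_F_nM  C_B_nM
0     0.0  1000.000   0.000   0.000
1     6.0   999.991  79.752   6.664
2    12.0     0.006  22.539  14.201
3    18.0     0.008   3.035  15.438
4    24.0     0.008   0.409  15.605
D_eq = 86.68 nM
UptakeResults
  observations: 174   converged: True
  mean |residual|: 38.8453
  parameter      estimate                       95% CI
  k_EF         5.0239e-05 [  4.8947e-05,   5.1566e-05]
  k_FE            0.31553 [     0.30382,      0.32769]
  k_FB           0.021776 [    0.020253,     0.023413]
```

The trajectory shows uptake during exposure, the washout at 8 h, and the
slow late growth of the bound pool; `D_eq` = 86.68 nM is the bound
concentration this schedule ultimately delivers. The fit recovers the
generating rates (truth: `k_EF` 5.0e-05, `k_FE` 0.313, `k_FB` 0.0212) well
within their 95% intervals, with a mean absolute residual of ~39 nM — the
scale of the injected measurement noise.

The full inverse study — generate a sensitizer study, fit every
condition, match equivalent doses and recover the per-level rate — is one
call (`eqdose.run_study("k_FE", seed=0)`) or, from the shell,
`eqdose run --config config.yaml`. The `eqdose` CLI also exposes the
individual steps (`generate`, `simulate-pk`, `eqdose`, `fit-pk`, `fit-pd`,
`fit-hill`, `build-surface`, `match-dose`, `estimate-kx`, `unmix`).

## Documentation

The modelling assumptions, parameter meanings, numerical choices and known
limitations are described in [`docs/methods.md`](docs/methods.md).
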