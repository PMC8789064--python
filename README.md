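# methylfp

Modelling and screening analytics for fluorescence-polarization (FP)
"methyl-reader" assays of DNA/RNA methyltransferases and demethylases
(DNMT1, TET2, METTL3/14, ALKBH5).

## The problem

Methylation reactions are hard to follow in high throughput: the methyl mark
itself is spectroscopically silent. A methyl-reader coupling sidesteps this: a
reader protein (a methyl-CpG-binding domain such as tri-MBD1 for 5mC DNA, or
a YTH-domain reader such as GST-YTHDF1 for m⁶A RNA) binds the FAM-labelled
reaction product far more tightly than the substrate. Adding the reader after
the reaction converts the extent of methylation into an FP signal: bound
tracer tumbles slowly and polarizes the emission.

`methylfp` implements the quantitative machinery behind such an assay, for
assay developers and screening scientists:

* **Binding model** — the competitive 1:1 mass-action equilibrium of one
  reader with a substrate/product tracer mixture (optional enzyme
  competitor), and the linear mP coupling
  `mP = mP_min + (mP_max − mP_min)·f_bound`.
* **Assay design** — the signal window ΔFP(P) = FP(100% product) − FP(0%
  product), its maximiser (in the trace-tracer limit the reader optimum is
  `[P]* = √(K_A·K_B)` for dissociation constants K_A ≥ K_B), the working
  concentration band, and the FP-vs-conversion standard curve with R²
  linearity diagnostics.
* **Enzyme kinetics** — Michaelis–Menten substrate→product conversion with
  cofactor saturation, competitive (substrate or cofactor) and noncompetitive
  inhibition, staggered-start time courses, Km/kcat fitting, and conversion
  quantitation `conversion% = (S − S_N)/(S_P − S_N)·100`.
* **Screening pipeline** — Z′ = 1 − (3σ_P + 3σ_N)/|μ_P − μ_N|, percent
  inhibition, four-parameter-logistic IC50 fits, Cheng–Prusoff analysis
  `IC50 = K_i·(1 + [S]/K_m)` (K_i from the y-intercept of IC50 vs. [S]), a
  30% total-fluorescence QC rule, and counter-screen triage of
  false positives (quenchers, oligo binders, reader-binding disruptors) on an
  enzyme-free 50/50 substrate/product mix.
* **Synthetic data** — named presets for the four assay configurations,
  labelled compound libraries, and seeded 384-well plate simulation through
  the full physics chain, for validating every analysis step end to end.

## Worked example

```python
import numpy as np
from methylfp import (make_assay_presets, optimal_reporter_conc, working_window,
                      standard_curve, cheng_prusoff_experiment, NoiseModel,
                      simulate_plate, analyze_plate)

p = make_assay_presets()["DNMT1"]          # 20 nM DNA tracer, tri-MBD1 reader
opt = optimal_reporter_conc(p.reporter, p.tracer_total, full_output=True)
print(f"optimal reporter conc: {opt.conc:.3f} uM (sqrt(KA*KB) = {opt.analytic_conc:.3f} uM)")
print(f"max signal window dFP: {opt.delta_fp_max:.1f} mP")
low, high = working_window(p.reporter, p.tracer_total, 0.8)
print(f"80% working window:    {low:.2f} - {high:.2f} uM")
sc = standard_curve(p.reporter, p.tracer_total, opt.conc, np.linspace(0, 1, 11))
print(f"standard curve:        slope {sc.slope:.1f} mP/fraction, R^2 = {sc.r_squared:.4f}")
plate, _ = simulate_plate(p, noise=NoiseModel(seed=1))
print(f"control plate Z':      {analyze_plate(plate).z_prime:.2f}")
tbl, cp = cheng_prusoff_experiment(p, ki=2.0, cofactor_concs=[0.5, 1, 2, 4],
                                   target_conversion=0.05)
print(f"Cheng-Prusoff Ki:      {cp.ki:.2f} uM (truth 2.00), R^2 = {cp.r_squared:.3f}")
```

prints

```
optimal reporter conc: 1.520 uM (sqrt(KA*KB) = 1.500 uM)
max signal window dFP: 81.7 mP
80% working window:    0.33 - 7.26 uM
standard curve:        slope 81.7 mP/fraction, R^2 = 1.0000
control plate Z':      0.82
Cheng-Prusoff Ki:      2.04 uM (truth 2.00), R^2 = 1.000
```

Reading the numbers: with a 100-fold selective reader (K_A = 15 µM, K_B =
0.15 µM) the numeric ΔFP optimum (1.52 µM) sits within ~1% of √(K_A·K_B)
because 20 nM tracer barely depletes the reader; the mP-vs-conversion
calibration is linear to machine precision; a 50+50 control plate at default
noise reaches the Z′ ≈ 0.8 "excellent assay" regime; and a simulated
SAM-competitive inhibitor pushed through reaction, FP readout and 4PL fitting
returns its true K_i from the IC50-vs-[SAM] intercept.

A CLI mirrors the library (`methylfp design|simulate|analyze|doseresponse|
counterscreen`); every command takes `--config` (YAML defaults) and exits
with code 2 on validation errors.

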