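# Methods

## Model

### Binding equilibrium and FP coupling

A reader protein P binds two fluorescent oligonucleotide species, the
reaction substrate A and product B, by independent 1:1 mass action with
dissociation constants K_A ≥ K_B (the product is the tight binder; a spec
passed the other way round is swapped with a warning). For totals P_T, A_T,
B_T the free reader p solves

    p + A_T·p/(K_A + p) + B_T·p/(K_B + p) = P_T ,

whose left side is strictly increasing in p, so the root is unique and
bracketed by [0, P_T]. An optional second protein (the enzyme, whose
oligo binding high-salt buffers are designed to suppress) is modelled as a
competitor with its own Kd pair; its free concentration is found by a nested
bracketed search, each level seen by the other as a Kd inflation.
Mass balances of every solved state are verified to 1e−9 relative.

The FP readout is taken to be linear in the bound tracer fraction,
mP = mP_min + (mP_max − mP_min)·f_bound. True polarization is not strictly
additive across bound/free populations; the linear form is the
anisotropy-with-equal-quantum-yields approximation, and it is the assumption
under which measured FP standard curves are linear. Tracer bound to the
enzyme competitor counts as bound — that is precisely the background signal
the salt conditions remove. Concentrations are µM throughout; mP are plain
numbers.

### Signal window and reader optimum

ΔFP(P) = FP(x=1) − FP(x=0) at reader concentration P is the assay window. In
the trace-tracer limit ΔFP(P) = W·(P/(K_B+P) − P/(K_A+P)) with W the mP
window, maximised at P = √(K_A·K_B). At finite tracer the optimum shifts
(ligand depletion), so `optimal_reporter_conc` computes the numeric argmax —
400-point log grid on [K_B/100, K_A·100], then bounded scalar refinement in
log-concentration — and reports the analytic value alongside, warning when
they differ by more than 5%. The "proper concentration" band
(`working_window`) is the interval where ΔFP ≥ 80% of its maximum by
default; the threshold is a design choice (published titration figures draw
the band without stating a criterion).

### Reaction kinetics

Conversion is a single irreversible step with multiplicative Michaelis–Menten
saturation in substrate and cofactor:

    dS/dt = −kcat·[E] · S/(Km,S + S) · C/(Km,C + C) .

The cofactor is treated as unconsumed (µM cofactor vs. tens of nM oligo).
Multi-step oxidation chemistry (5mC→5hmC→5fC→5caC) is collapsed to one
substrate→product step, which is all the binding readout distinguishes.
Inhibitors follow three textbook mechanisms: substrate-competitive and
cofactor-competitive inflate the corresponding Km by (1 + [I]/K_i);
noncompetitive scales Vmax by 1/(1 + [I]/K_i). Adding the reader quenches the
reaction instantly (no post-quench drift), which is what staggered-start time
courses exploit: a well whose enzyme is added last is the 0-minute control.
Integration uses adaptive RK45 at rtol 1e−8; the closed-form Lambert-W
progress curve is reserved for independent test oracles.

The rate constants in the synthetic presets (Km 0.1 µM, kcat 0.5 min⁻¹,
cofactor Km of order its assay concentration) are order-of-magnitude
placeholders — the measured values are not reproduced here — chosen so the
uninhibited reaction approaches completion within each preset's reaction
time.

### Screening statistics

Z′ = 1 − (3σ_P + 3σ_N)/|μ_P − μ_N| with sample (n−1) standard deviations
(the HTS convention; the defining formula does not specify). Percent
inhibition is anchored at the uninhibited reaction (neg control, 0%) and the
no-reaction well (pos control, 100%). Dose–response uses the
log(inhibitor)-vs-response variable-slope 4PL,
y = bottom + (top − bottom)/(1 + 10^((logIC50 − logD)·h)), fitted by
Levenberg–Marquardt with quartile-based initialisation, h ∈ [0.2, 5], IC50
bounded to the dosed range ±1 decade, and top ≥ bottom enforced via a
non-negative span parameter. Cheng–Prusoff K_i is the y-intercept of the OLS
line IC50 = K_i·(1 + [S]/K_m); a negative intercept is flagged as
inconsistent with a competitive mechanism. The FI QC rule flags wells whose
total fluorescence deviates more than 30% from the negative-control median.
Counter-screen verdicts compare a compound's mP on the enzyme-free 50/50
substrate/product mix against DMSO reference wells: |Δ| > 3σ is a false
positive. Hits are wells whose inhibition exceeds 3 sample SDs of the
negative-control inhibition (the primary-screen cutoff is a design choice;
none is stated for the published screen).

### Endpoint readouts and Cheng–Prusoff linearity

An endpoint conversion c(I) = 1 − exp(−k·f(I)·t) is nonlinear in the rate
factor f. Solving for the dose that halves the endpoint shows
IC50(C) = K_i·(K_c + C)·(1 − f\*)/(f\*·K_c) with f\* the rate factor at
half-endpoint: the IC50-vs-cofactor line stays exactly linear at any
conversion (so R² criteria are conversion-independent), but its intercept is
K_i·(1 − f\*)/f\*, which equals K_i only as f\* → 1/2, i.e. in the
initial-rate regime. `cheng_prusoff_experiment` therefore defaults to a
reaction time giving ~8% uninhibited conversion for K_i estimation
(intercept bias < 3%); when a larger signal window matters more than
intercept accuracy (noisy R² studies) a higher target conversion can be set.

## Synthetic data

The generator emulates the four published assay configurations: DNMT1
(20 nM FAM DNA tracer, 1.5 µM tri-MBD1-like reader, 1 µM SAM), TET2 (20 nM
tracer, 500 nM reader, 1 mM 2-OG), METTL3/14 (40 nM RNA tracer, 750 nM
GST-YTH-like reader, 1 µM SAM) and ALKBH5 (40 nM tracer, 20 nM enzyme,
750 nM reader, 200 µM 2-OG); MBD-like readers carry a ~100 mP window and
YTH-like ~250 mP, all with 100-fold product selectivity, and each preset's
reader concentration sits at the √(K_A·K_B) optimum of its Kd pair.
Demethylase presets invert the signal by mapping conversion to
1 − (tight-binder fraction).

Plates are 384-well with the published control layout (50 positive and 50
negative controls, 5 columns × 10 rows each). Every well is computed through
the full chain reaction → equilibrium → mP, FI and then perturbed with
Gaussian noise from a single seed. Default mP noise is 2.5 mP — about 3% of
the usable window — putting control-plate Z′ near 0.8–0.9, the validated
regime; this is a tuning choice, not a measurement. FI noise is 2% CV around
a nominal 10,000 counts.

Compound classes and default effect sizes: inhibitors draw K_i log-uniformly
from 0.5–20 µM; quenchers cut FI by 50% (quenching is modelled as hitting
free and bound tracer equally, so mP is unchanged and detection falls to the
FI rule — binding-state-dependent quenching is deliberately not the default);
oligo binders add +40 mP; reader disruptors inflate the product Kd 10-fold at
the screening concentration — the strong, dose-dependent disruption a counter
screen exists to catch. Dose–response simulations read each dose in
triplicate (standard bench practice) and normalise to on-plate control
means.

What passing tests on these data do **not** show about real plates: no
spatial/edge effects, no drift or batch structure, Gaussian noise only,
single-mechanism compounds, one-step kinetics with unconsumed cofactor, and
salt dependence enters only through user-supplied condition-specific Kd sets
(no electrostatics). Non-monotone behaviour of RNA substrates at high
concentration (dimerisation) is not modelled.

## Numerical choices

* Root finding: bracketed Brent on [0, P_T] (xtol 1e−15) for scalar solves;
  a plain vectorized bisection (90 iterations) for design-grid evaluations.
  The two paths agree to ~1e−9 and are cross-checked in tests.
* Mass-balance verification at 1e−9 relative on every solved state; failure
  raises a numerical error rather than returning a state.
* ODE: RK45, rtol 1e−8, atol 1e−14, substrate clipped at 0 inside the RHS.
* 4PL and Michaelis–Menten fits: lmfit/Levenberg–Marquardt with xtol/ftol
  1e−14 so noiseless recovery is limited by conditioning, not termination.
* Degenerate inputs: K_A = K_B yields a zero window (flagged, √(K_A·K_B)
  returned); coincident Z′ control means return −inf with a warning;
  degenerate normalization controls raise; responses spanning < 5% are
  flagged inactive with NaN IC50.
* Problem sizes in the validation suite: 11-point standard curves, 100
  random Kd pairs for optimum recovery, 1000 Monte-Carlo control plates,
  a 284-compound labelled screen, and 5-level × 12-dose × triplicate
  Cheng–Prusoff studies.

## Known limitations

* The mP-linearity assumption breaks when bound and free tracer differ
  strongly in quantum yield; real assays correct or tolerate this.
* K_i recovery from endpoint data is biased at high conversion (see above);
  the package surfaces this through the target-conversion parameter rather
  than hiding it.
* The counter-screen rule is a per-compound z-test against plate noise; at
  k = 3 a ~0.3% false-exclusion rate per true hit is expected and inherent
  to the threshold.
* CSV is the only plate format; vendor exports must be converted to the
  documented dialect.
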