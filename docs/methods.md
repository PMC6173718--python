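# Methods

## Model

Antibody amounts `a(t)` (µg) in a set of compartments obey the linear
time-invariant system `da/dt = A·a + r(t)`, where the off-diagonal entries
of `A` are the first-order transfer constants `k_{j→i}` (min⁻¹), diagonal
entries collect each compartment's total outflow plus any first-order
elimination, and `r(t)` is the dosing input (bolus by default; a zero-order
infusion of configurable duration is supported, and at this design's time
scale — first sample at 1 h — the two are indistinguishable, which is why
bolus is the default).  For a bolus the solution is exactly
`a(t) = expm(A·t)·a(0)`; the package evaluates it by eigendecomposition with
a `scipy.linalg.expm` fallback, and keeps an adaptive LSODA integration as
an independent cross-check (the two agree to <1e-8 relative in the test
suite).  Infusions use the augmented-matrix exponential, which avoids
inverting `A` and is therefore valid for singular rate matrices.

The reference topology has five compartments — blood (central, distribution
volume `Vd`), L2–L4 vertebrae, liver, spleen, and a deep compartment
aggregating all unsampled tissue including tumor.  Blood exchanges
bidirectionally with vertebrae, liver and deep; the spleen fills from blood
only and drains into the liver; elimination is first order from blood.
Blood concentration is amount/`Vd`; organ concentrations divide the tissue
amount by the CT organ volume.

A note on labels: cohort tables for this design print the spleen's rates in
the same `k13`/`k31` positions used for the liver block, while the
accompanying structural description routes spleen efflux to the liver.  The
package follows the structure and names the spleen rates `k14`
(blood→spleen) and `k43` (spleen→liver); every run manifest records this
mapping.

## Activity→mass conversion and vascular partition

Well-counter activity becomes antibody mass through
`Am = (Ac/eff)/(exp(−ln2·t/T½)·MAc)` with defaults `T½ = 67 h` (the value
conventionally used for ¹¹¹In in this setting, configurable), counting
efficiency 0.933 and specific activity 138 MBq/mg.  Times are carried in
minutes throughout (rate constants are min⁻¹); masses are carried in µg.

The intra-organ blood volume is estimated once per patient-fraction as the
4 h whole-organ amount divided by the 1 h blood concentration, assuming a
purely vascular distribution phase over the first hour.  If no sample
exists at exactly 60 min, the 1 h concentration is log-linearly
interpolated and the interpolation is recorded in the partition table.
Two properties of this estimator are asserted in the tests rather than
assumed: it is exact when tissue exchange is absent and the blood curve is
flat (the premise under which it was designed), and it is biased **upward**
under full exchange kinetics, because tissue uptake by 4 h and the falling
blood curve both inflate the numerator relative to the denominator.  For
that reason the end-to-end recovery experiments feed the subtraction stage
the generator's true vascular volumes (`vascular_volumes="truth"` in the
pipeline); runs on real data use the estimator, inheriting its documented
bias.  Negative tissue amounts after subtraction are clamped to zero and
flagged, never passed silently to the fitter.

## Fitting and model selection

Parameters are estimated by least squares on all observed concentration
series simultaneously, with rates and `Vd` optimized on a log10 scale
(positivity plus uniform sensitivity across orders of magnitude), bounds
log10 k ∈ [−9, −1] and log10 Vd ∈ [1, 6], a neutral start (all rates
1e-4 min⁻¹ — the scale typical of antibody organ exchange — and Vd
4900 mL ≈ 0.07 L/kg × 70 kg) and seeded multi-start jitter (default 5
starts, SD 0.5 log10 units).  The objective is unweighted SSR by default; a
`1/ŷ²` (proportional-error) weighting flag is available and is the
statistically matched choice when measurement noise is proportional, as it
is in the synthetic cohorts.  Candidates lacking a sampled compartment
predict zero there, so every catalogue member competes on the same
observation set.

Candidates are ranked by `AIC = n·ln(SSR/n) + 2p`, ties broken by fewer
parameters then topology id.  An SSR below `n·(1e-7·RMS(obs))²` is treated
as an exact fit (AIC −∞ sentinel): on noise-free data several nested
topologies reach floating-point-level SSR, where the logarithm would
otherwise rank them on numerical noise; the floor hands the decision to the
parsimony tie-break.  The default catalogue enumerates all structural
variants describing the three sampled organs — each of vertebrae/liver
bidirectional or inflow-only, spleen efflux to blood or liver, deep
compartment present or absent, single elimination site among
blood/liver/spleen — plus the classic central+peripheral two-compartment
model: 49 topologies, containing the reference model.

## Secondary parameters

AUC uses the linear-up/log-down trapezoid; AUC to infinity adds
`C_last/λz` with `λz` from a log-linear regression over the last 3 points
(the 4-point imaging design leaves at most 3 terminal points).  MRT is
AUMC/AUC; Cmax/Tmax are read from a dense (2017-point, 0–7 d) simulation of
the fitted model, since 4 samples cannot locate a peak.  Cumulative AUC at
4 and 7 days is likewise computed on the fitted curve (a flag switches to
observed-point trapezoids).  `CL = dose/AUC_total` and `Vd` is the fitted
central volume; for blood-only elimination `CL = Vd·k_el` exactly, and the
7-day truncation of the reporting grid leaves a ~2% tail bias in the NCA
clearance, which the tests tolerate explicitly.  Reported T½ and MRT for
blood are curve-based (apparent terminal phase of the fitted curve over the
observation horizon); the eigenvalue/moment forms are kept as cross-checks
because they diverge when a sparse noisy fit drives `k_el` toward zero.
Organ MRT applies AUMC/AUC to the organ's own concentration curve — a
convention, since organ MRT is not otherwise defined here.  Units follow
the cohort-table conventions: h for T½/MRT, mL for volumes, mL/min for
clearance, µg·min·mL⁻¹ for AUC.

## Synthetic cohorts

The generator's defaults are the study conditions: 19 F1 / 13 F2 patients,
imaging at 240/1440/5760/10080 min, blood samples at 60 min plus the
imaging times, bolus 1000 µg (the labeling batch is 1.6 mg of antibody and
the infused fraction is not reported; 1 mg is the right order of magnitude
and the value is configurable), lognormal between-patient variability
with CV 0.30 (mean-preserving), proportional noise CV 0.10.
Fraction-specific mean rate constants and `Vd` are the published cohort
means; the unreported deep-exchange rates default to
`k15 = k51 = 1e-4 min⁻¹` and the unreported elimination rate to
`k_el = CL/Vd` from the blood-block means.  Organ masses derive from the
published blood-volume means and per-gram values (8.15 mL at 0.15 mL/g →
54.3 g vertebrae; 485 mL at 0.29 → 1672 g liver; 81.5 mL at 0.28 → 291 g
spleen), with CT volumes approximated at unit tissue density.  Organ totals
are composed as tissue amount + blood concentration × vascular volume —
the exact inverse of the subtraction stage — and a well-counter activity
layer applies the exact inverse of the mass conversion, so both early
pipeline stages are exercised end to end.  F2 draws fresh individual
parameters around the F2 means for the first 13 patient ids (the design is
partially paired, but the comparison is unpaired, so re-drawing is
inconsequential and simpler).

What the generator does **not** emulate: SPECT count statistics and
reconstruction artifacts, partial-volume effects, organ delineation error,
free-¹¹¹In in blood, and any tumor-volume dynamics between fractions.
Passing tests therefore demonstrate correctness of the analysis chain under
the stated statistical model, not robustness to imaging physics.

Note one internal tension of the published summary values that the
generator inherits: simulating from the tabulated rate constants does not
reproduce the tabulated organ Cmax/AUC or the 83.6 h blood half-life
(the implied terminal phase of the five-compartment mean parameter set is
slower).  The generator treats the rate constants and `Vd` as the ground
truth; derived quantities follow from the model, not from the table.

## Validation experiments

* **Parameter recovery (deterministic):** noise-free curves from the F1
  mean parameter set on a 40-point geometric 1 h–168 h grid, refit from
  neutral starts; every reported rate constant and `Vd` return to well
  under 1% relative error.  This is also what `scripts/acceptance.py`
  recomputes.
* **Selection, noise-free:** the 49-member catalogue ranks the generating
  topology first on the same data (exact-fit floor plus parsimony
  tie-break).
* **Selection, stochastic:** 50 replicate study cohorts (19 F1 + 13 F2,
  IIV 0.30, proportional noise 0.10, all five compartments sampled at the
  design times) are analysed with one model selected per cohort by summed
  AIC across patient fits, mirroring how a single structural model is
  established across patients and fractions in dosimetry practice.  Fits use the
  proportional-error objective (matched to the generator's noise) and one
  optimizer start per candidate for tractability.  Per-patient selection
  is near chance here — the spleen-efflux-to-blood twin differs from the
  truth by only ~0.4% relative RMS at the sparse design, far below the
  noise — so pooling across the cohort is what makes the experiment
  informative.
* **Type-I error:** 2000 null cohorts (19 vs 13 draws from one lognormal)
  give a Mann–Whitney rejection rate near the discrete-test value ≈0.045
  at α = 0.05.

## Known limitations

* The one-sample vascular-volume estimator is upward-biased under real
  kinetics (quantified above); a joint fit of vascular volume with the
  kinetic parameters would remove the bias but is out of scope.
* With 17–21 observations and 10 free parameters, noisy per-patient fits
  can drive `k_el` to its bound; curve-based summary statistics stay
  bounded, but terminal extrapolations from such fits should be read with
  care.
* The spleen efflux destination (blood vs liver) is at the edge of
  identifiability for this sampling design; only cohort-level evidence
  separates the two.
* Nonlinear (target-mediated) kinetics, time-varying rates, and absorbed
  radiation dose are out of scope.
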