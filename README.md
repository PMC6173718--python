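# ritpk

Individualized-vascular-compartment pharmacokinetics of radiolabeled
monoclonal antibodies.

## The problem

Radioimmunotherapy with ⁹⁰Y-ibritumomab tiuxetan (an anti-CD20 antibody)
is imaged with a ¹¹¹In-labeled surrogate: whole-body SPECT/CT at 4 h, 24 h,
96 h and 168 h after infusion quantifies the amount of antibody in delineated
organs (L2–L4 vertebrae, liver, spleen), and a 1 h blood sample anchors the
blood curve.  Two things make these data awkward for standard PK analysis:

1. **Counts, not concentrations.** A well counter reports activity; the
   antibody mass in a sample is recovered by decay correction and the
   specific activity of the label,
   `Am = (Ac/efficiency) / (exp(−ln2·t/T½)·MAc)`.
2. **Organs contain blood.** A delineated organ's signal mixes
   tissue-bound antibody with antibody still circulating in the organ's
   vessels.  Assuming a purely vascular distribution phase during the first
   hour, the intra-organ blood volume is estimated once per patient as
   `V_blood = organ amount(4 h) / blood concentration(1 h)` and the blood
   constituent `C_blood(t)·V_blood` is subtracted at every imaging time.

The tissue curves that remain are fitted with linear compartmental models
(first-order rate constants `k_ij`, min⁻¹) and candidate topologies are
ranked by the least-squares Akaike Information Criterion,
`AIC = n·ln(SSR/n) + 2p`.  The selected structure is a five-compartment
model: blood (x1, central, volume V_d) exchanging bidirectionally with
vertebrae (x2, k12/k21), liver (x3, k13/k31) and a deep compartment (x5,
everything unsampled including tumor), a one-way blood→spleen input (x4,
k14) with spleen efflux draining into the liver (k43), and first-order
elimination from blood (k_el).  Secondary parameters (Cmax, terminal T½,
MRT = AUMC/AUC, CL = dose/AUC, cumulative AUC at 4 and 7 days) are computed
from the fitted curves, and the two treatment fractions (F1: 19 patients,
F2: 13 patients) are compared per parameter with the two-sided
Mann–Whitney U test at α = 0.05.

Because the underlying trial data are not public, the package ships a
synthetic-cohort generator that emulates the full design (sampling times,
cohort sizes, fraction-specific mean parameters, lognormal between-patient
variability, proportional measurement noise) with the generating truth
stored next to every dataset, so the entire chain is testable end to end.

## Worked example

```python
from ritpk import RunConfig, run_pipeline

config = RunConfig(seed=1, out_dir="demo_run", n_patients_F1=5, n_patients_F2=4,
                   weighting="1/y2", vascular_volumes="truth")
run_pipeline(config)
```

This generates a small synthetic cohort, estimates the vascular volumes,
fits the five-compartment model per patient-fraction and writes
`obs.csv`, `activity.csv`, `partition.csv`, `fits.json`,
`pk_summaries.csv`, `comparison.csv` and `manifest.json` under `demo_run/`.
The partition table averages to blood volumes of 7.38 mL (vertebrae),
400.70 mL (liver) and 77.48 mL (spleen) for this seed — the scale expected
from vascularized-organ physiology.  The comparison table (excerpt):

```
                parameter   F1_mean    F1_sd   F2_mean    F2_sd    U  p_value  significant
              blood:Vd_mL  4643.338 1596.105  3303.274 1781.627 14.0    0.413        False
          blood:CL_mL_min     1.705    0.364     1.390    0.607 13.0    0.556        False
            x4:Cmax_ug_mL     0.687    0.235     0.402    0.180 18.0    0.063        False
   x4:AUCcum_7d_ug_min_mL  5918.877 1886.935  3352.249 1603.398 18.0    0.063        False
```

Spleen (x4) exposure trends lower at the second fraction — the direction
built into the fraction-specific generating means — while blood Vd does
not separate, mirroring the emulated study's pattern.  At full cohort size
(19 vs 13) the spleen rows reach significance.

A command-line interface mirrors each stage
(`ritpk synth-cohort | convert | partition | fit | select-model | pkparams |
compare | run`); see `ritpk --help`.

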