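# amtdr

Annual grassland mapping and rule-based disturbance-change analysis
from spectral–temporal indices on MODIS-like surface-reflectance time
series.

## The problem

Alpine grasslands change in ways a single vegetation index trend cannot
describe: a pixel can be disturbed yet recovering, disturbed and
degrading, or greening without meaningful disturbance pressure.  The
strategy implemented here — *annual mapping, then temporal disturbance
rules* — separates the two questions.  Each year is first mapped into
land-cover classes from engineered phenology features; the multi-year
sequence of two per-pixel indices is then tested for monotonic trend,
and a total decision table converts the two trend verdicts into one of
seven disturbance-change types per grassland pixel.

The package is aimed at remote-sensing and ecology researchers who want
this workflow as tested, reusable components driven end-to-end by a
seeded synthetic-scene generator, so every stage can be validated
without any satellite downloads.

## The indices and the model

For 8-day composite 7-band reflectance (46 epochs/year), QA-masked and
linearly interpolated to 365 days/year:

- **NIRv** = NDVI × NIR, with NDVI = (NIR − red)/(NIR + red).
- **Tasseled cap**: brightness *B*, greenness *G*, wetness *W* — fixed
  linear combinations of the 7 bands (MODIS coefficient set, swappable
  YAML).
- **Disturbance index**: with components z-scored against a vegetation
  reference set (*B*ᵣ = (*B* − *B*μ)/*B*σ, …),

  DI = *B*ᵣ − (*G*ᵣ + *W*ᵣ).

  Disturbance exposes bright soil and removes green, moist canopy, so
  all three shifts push DI up.
- **Greening abundance**: over the May 1–Sep 30 window of daily NIRv,
  GA = mean of the profile between the dates of the window minimum and
  maximum (order-agnostic, endpoints inclusive).

Per pixel-year the classifier consumes the 15-vector
{NIRv, DI, TC1, TC2, TC3} × {growing-season max, min, mean}: a small
fully connected MLP (2×64 ReLU, softmax, Adam, cross-entropy loss
`-x[c] + log Σⱼ exp x[j]`), trained on a stratified 80/20 split of
labelled points.  Interannual DI and GA series (17 years typical) get a
Theil–Sen slope (median of pairwise slopes) and a Mann–Kendall test
(statistic S, tie-corrected variance, continuity-corrected Z, two-sided
p).  The rule engine then classifies: DI not significant → stable;
DI significant and GA significantly rising → recovery (DI rising) or
greenness increase (DI falling); GA significantly falling →
degradation; GA non-significant → the corresponding *potential* type;
grassland that became water in the majority of the final 3 mapped years
→ turned-to-water, overriding everything.

## Worked example

The `analysis/` scripts run the whole study on a synthetic benchmark:

```bash
python analysis/01_simulate_scene.py    # 100x100, 17-year scene, 7 patches
python analysis/02_index_profiles.py    # class centroids in (GA, DI)
python analysis/03_run_pipeline.py      # full pipeline, writes results/pipeline_run/
python analysis/04_disturbance_recovery.py
python analysis/05_accuracy_and_areas.py
python analysis/06_driver_analysis.py
```

Script 04 prints, for the scene with one injected patch per change
type (noise sd 0.02, 5% cloud cover):

```
                       patch  pixels  agreement_pct
                    recovery     144          100.0
          potential_recovery     144          100.0
                 degradation     144          100.0
       potential_degradation     144          100.0
          greenness_increase     144          100.0
potential_greenness_increase     144          100.0
             turned_to_water     144          100.0

Stable-background disturbed rate: 4.08%
```

i.e. every injected disturbance regime is recovered at the pixel level,
while the undisturbed background is flagged "disturbed" at roughly the
Mann–Kendall false-positive rate (the exact null rejection rate of the
continuity-corrected test at α = 0.05 and n = 17 is ≈ 4.4%).

Script 05 prints the reference-site confusion statistics from the
published-style two-class counts (498/25 over 16/157): overall accuracy
94.11%, kappa 0.845, producer's accuracy 95.22%/90.75%, user's accuracy
96.89%/86.26%.

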