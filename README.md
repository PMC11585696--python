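# rafh — rim-area focal hyperautofluorescence analysis for geographic atrophy

Geographic atrophy (GA), the atrophic late stage of age-related macular
degeneration, appears on fundus autofluorescence (FAF) imaging as a dark
(hypoautofluorescent) lesion, often surrounded by a bright junctional zone.
**Rim-area focal hyperautofluorescence (RAFH)** quantifies that zone: the
fraction of the 450-µm band circumscribing the GA lesion occupied by
hyperautofluorescent pixels,

```
RAFH = area(hyperAF ∩ rim) / area(rim),       rim = {x ∉ GA : dist(x, GA) ≤ 450 µm}
```

a unitless ratio in [0, 1]. This package is for imaging researchers who want
a reproducible, tested implementation of the full RAFH analysis chain:

- **Measurement** — exact-Euclidean-distance rim band; hyperAF detection by a
  local +40 threshold (on the raw 0–255 scale) over a robust windowed-median
  background; manual add/remove grader edits; sub-pixel lesion area,
  perimeter, and focality.
- **Growth metrics** — per-eye GA growth as area rate `(A_last − A_first)/Δt`
  (mm²/yr), square-root rate `(√A_last − √A_first)/Δt` (mm/yr), and
  perimeter-adjusted rate `area rate / mean(P_first, P_last)` (mm/yr), plus
  baseline-area tertile stratification.
- **Grader agreement** — Bland–Altman limits of agreement, ICC(A,1) with
  F-based CI, strict out-of-limits flagging with a single consensus round,
  and grader averaging.
- **Association models** — Spearman correlations (overall and per tertile),
  baseline mixed models `RAFH ~ covariate + (1|participant)`, and the
  longitudinal model `RAFH ~ time (+ arm + time×arm)` with crossed
  participant and nested eye intercepts plus an eye-level random slope
  (REML via statsmodels, Wald-z inference).
- **Synthetic ground truth** — FAF-like images with planted lesions and
  known true RAFH, and hierarchical two-arm longitudinal cohorts, so every
  stage is validated against generator truth.

## Worked example

```python
from rafh import (ImageSimConfig, simulate_faf_image, make_rim_band,
                  detect_hyperaf, lesion_metrics)

cfg = ImageSimConfig(seed=3, target_rafh=0.15)          # 384x384 px, 10 um/px
image, ga_mask, true_hyper, true_rafh = simulate_faf_image(cfg)

metrics, rim = lesion_metrics(ga_mask, cfg.scale_um_per_px)
result = detect_hyperaf(image, ga_mask, rim)            # +40 local threshold
print(f"GA area      {metrics.ga_area_mm2:.3f} mm^2")
print(f"GA perimeter {metrics.ga_perimeter_mm:.3f} mm")
print(f"true RAFH    {true_rafh:.4f}")
print(f"measured     {result.rafh:.4f}")
```

prints

```
GA area      0.952 mm^2
GA perimeter 3.486 mm
true RAFH    0.1500
measured     0.1500
```

— a ~1 mm² lesion whose rim is 15% covered by planted speckle; the local
+40 threshold recovers the planted fraction exactly, because the speckle is
brighter than background + 40 and the windowed median is robust to it.

A whole cohort runs through one call:

```python
from rafh import CohortSimConfig, simulate_cohort, RunConfig, run_pipeline
cohort = simulate_cohort(CohortSimConfig(seed=7))
report = run_pipeline(RunConfig(), cohort=cohort.table)
print(report["longitudinal"]["rafh_slope_per_year"])   # ~0.02 /yr drift
```

The same flows are available on files from the shell:
`rafh measure|agree|growth|stats|simulate|run --help`.

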