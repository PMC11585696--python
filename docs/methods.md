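# Methods

This note documents the measurement model, the statistical models, the
synthetic-data generator that validates them, and the numerical choices made
where the design was genuinely open.

## Rim band and lesion morphometry

The junctional ("rim") zone is defined geometrically: a pixel belongs to the
rim when it is not part of the GA lesion and its center lies within 450 µm
(Euclidean, center-to-center) of the nearest lesion-pixel center. Distances
come from the exact Euclidean distance transform of the lesion complement
(`scipy.ndimage.distance_transform_edt`), so multifocal lesions
automatically yield the union of per-focus bands with overlap counted once.
The band is half-open, `0 < d ≤ 450 µm`, with the tie at exactly 450 µm
included. Holes enclosed by the lesion are rim whenever they are in range —
they satisfy the same geometric rule, and carving them out would make the
definition connectivity-dependent. A rim clipped by the image frame sets a
`touches_border` warning rather than erroring: whole-macula frames routinely
place lesions near the edge, and the measurement remains well defined on the
visible part.

Lesion area is pixel counting times the pixel area, `count × (scale/1000)²`
mm². Perimeter is the total length of sub-pixel marching-squares contours at
level 0.5, including inner (hole) boundaries. Contouring raw binary data
overestimates smooth boundaries by ~5% (staircase bias), so the mask is
pre-smoothed with a Gaussian of σ = 1 px before contouring; this brings both
a 1-mm square (−0.9%) and a 1-mm-radius disc (+0.5%) within 1% of their
analytic perimeters at 10 µm/px. Structures too thin to survive the
smoothing (≲2 px) fall back to unsmoothed contours rather than disappearing;
perimeters of such skeletal masks are reported with staircase bias, a known
limitation irrelevant at lesion scale. Foci are counted with 8-connectivity,
the standard convention for bright-blob lesion counting, matching how a
grader judges contiguity.

## Hyperautofluorescence detection

A rim pixel is hyperautofluorescent when its raw 8-bit intensity is at least
the local background plus an offset of 40 (inclusive comparison, no
normalization). The published threshold rule does not specify the background
reference surface, so it is defined here explicitly and configurably: the
**median** intensity of non-lesion pixels inside a square window of side
500 µm centered on the pixel, clipped at the image frame. The median is the
deliberate choice because it is robust to the bright speckle being detected
— a mean reference would rise with the signal and suppress detection in
heavily affected rims (a windowed median tolerates up to 50% contamination).
A `global` mode (single median over all rim pixels) is provided for
sensitivity analysis. Windows narrower than 3 px are rejected: a median over
one or two columns is noise.

Manual grader corrections are kept as separate add/remove masks and applied
as `((auto ∪ add) \ remove) ∩ rim`, so the automatic, reproducible output is
never overwritten. RAFH is the flagged-pixel count divided by the rim-pixel
count — a pure ratio, independent of the pixel scale.

## Growth metrics

All three growth rates use the first and last visits only (no regression
over intermediate visits): the area rate `(A_last − A_first)/Δt`, the
square-root rate `(√A_last − √A_first)/Δt` with the square root taken of
the **total** area summed over foci, and the perimeter-adjusted rate
`area rate / ((P_first + P_last)/2)`. The square-root transform removes the
first-order dependence of growth on baseline lesion size; the
perimeter-adjusted rate estimates the mean radial expansion speed of the
border (for a disc growing at radial speed *k* it converges to *k*, and the
square-root rate to √π·*k* — both verified against rasterized-disc
simulations in the test suite). Baseline-area tertiles are assigned by
stable ascending sort (ties broken by participant then eye), with the
remainder going to the lower tertiles, so 71 eyes split 24/24/23.

## Grader agreement

Bland–Altman uses the sample SD (n−1) of per-image differences and fixed
±1.96 limits (the conventional 95% limits of agreement, not t-based).
Reliability is ICC(A,1) — two-way random effects, absolute agreement,
single rater — computed from the two-way ANOVA mean squares with the
McGraw–Wong F-based confidence interval. Absolute agreement is the
appropriate variant for interchangeable graders whose raw values are
averaged downstream. Images whose difference falls **strictly** outside the
limits are flagged for consensus; the consensus round runs once (flag →
re-grade → recompute), never iterated. When no human re-grade is available
(pipeline runs on simulated data), the pair mean stands in for the joint
re-grade. Zero-variance input leaves the ICC undefined (NaN) rather than
returning a spurious 1.

## Association models

Spearman correlations use average ranks; two-sided p values come from the
t approximation for n > 10 and the exact permutation distribution for
n ≤ 10. Baseline models regress per-eye baseline RAFH (grader mean) on one
covariate at a time with a random intercept per participant to absorb
inter-eye correlation (REML, `statsmodels` MixedLM); covariates with
univariate p < 0.05 — and only those, no stepwise refinement — enter a
joint multivariable model of the same structure. The longitudinal model is

```
RAFH ~ time (+ arm + time×arm)          fixed
     + (1 | participant)                crossed participant intercept
     + (1 | eye:participant)            nested eye intercept
     + (time | eye:participant)         eye random slope, uncorrelated
```

fit by REML with Wald-z inference (CI = estimate ± 1.96·SE) throughout; a
profile-likelihood or Satterthwaite alternative would change p values only
in the third decimal at these sizes and is not portable across backends.
The eye slope and eye intercept are uncorrelated variance components by
construction. The treatment model restricts follow-up to 1.5 years (the
drug was stopped at 18 months); the pooled drift model uses 2.0 years; both
windows are configuration. The adherence sensitivity run excludes all eyes
of participants below 75% adherence (missing adherence passes the filter).
Non-convergence triggers an explicit fallback ladder — retry optimizer,
drop the eye slope, drop the eye intercept — with every step logged and the
final level recorded on the results object; at the default generator
conditions the full model converges in >99% of replicates.

## Synthetic-data generator

**Images.** A 384×384 frame at 10 µm/px with Gaussian background
(mean 100, SD 8), an irregular dark lesion (Fourier-perturbed ellipse,
interior ~25), and bright speckle discs (background +70, above the +40
threshold by construction) placed inside the analytic 450-µm rim until the
planted fraction equals the requested true RAFH within half a pixel (the
last disc is trimmed to the exact pixel budget). The generator returns the
planted masks, so detection is scored against known truth. These images
emulate the geometry and contrast of the measurement problem, **not** FAF
photorealism: no vessels, optic disc, illumination gradients, media
opacity, or inter-visit misalignment. Passing recovery tests therefore
demonstrates correctness of the measurement chain, not robustness to
real-world imaging artifacts.

**Cohorts.** 44 participants (two eyes with probability 0.61, giving ~71
eyes; 1:1 arm allocation balanced to within one), visits at 0, 0.5, 1.0,
1.5, 2.0 years with monotone dropout (8%/visit from the second follow-up
on; baseline and first follow-up always present, mirroring the ≥6-months
eligibility rule). Baseline areas are log-normal (median 5.5 mm², log-SD
0.8) truncated to an eligibility-like 0.25–35 mm²; √area grows linearly at
0.25 ± 0.12 mm/yr per eye; perimeter is `c·2√(πA)` with per-eye circularity
c ~ U(1, 2), keeping the area–perimeter coupling realistic for the
perimeter-adjusted metric. True RAFH is

```
RAFH(t) = 0.20 + 0.065·√A₀ + u_participant + u_eye
        + (0.020 + arm·δ + s_eye)·t + ε_visit
```

with SDs 0.05 / 0.04 / 0.015 / 0.02 and a null treatment effect δ = 0 by
default. The cross-sectional √area term uses the **baseline** area, so the
drift parameter 0.020/yr *is* the total marginal slope of RAFH over time —
the quantity the longitudinal model estimates; tying the term to the
current area would silently add the area-growth contribution
(≈ 0.065 × 0.25 ≈ 0.016/yr) on top of the nominal drift. The intercept 0.20
puts mean baseline RAFH near 0.33, within the range reported for
quantified junctional hyperautofluorescence, and keeps the truth far enough
from both bounds that grader-noise clipping is negligible. Two grader
readings add independent N(0, 0.044²) noise — the per-grader SD implied by
intergrader limits of agreement of half-width ≈ 0.122 (SD of differences
≈ 0.062, divided by √2) — and are clipped to [0, 1]; clips are counted and
a run with >1% clipped readings fails loudly, since silent truncation would
bias every downstream estimate. An optional per-tertile coupling
(0.8, 0.8, 0.0 mm/yr per RAFH unit) ties an eye's RAFH deviation to its
growth rate, making the size-dependent prognostic pattern (association in
small/medium lesions, none in large) a reachable regime rather than an
assumption. The generator does not model the marginal mean-difference
between graders (readings are exchangeable), missingness related to
disease severity, or measurement drift from camera repositioning between
visits.

All randomness flows through one `numpy.random.Generator` seeded from the
configuration: identical seeds give bit-identical tables and images.

## Problem sizes and tolerances

Validation sizes were chosen so each study is statistically decisive at
desk scale: exhaustive rim oracles on 100 random grids up to 100×100
(exact equality required); closed-form geometry within 2–3% of analytic
values at 5–10 µm/px; planted-RAFH recovery within 0.03 at defaults;
agreement formulas to 1e-10 against ANOVA oracles; 200 trial-sized
replicates for longitudinal slope recovery (mean within ±0.005 of truth)
and interaction type-I error (3–7% at α = 0.05); 100 cohorts for the
confounding ordering; and 200 cohorts of ~300 eyes for baseline-coefficient
bias (<10%). The acceptance script reruns the full chain on freshly
generated data and reports only quantities it computes at run time.

## Known limitations

- The background-reference surface of the original semiautomatic software
  is unpublished; the windowed median used here is an explicit, configurable
  stand-in, and absolute RAFH values may differ from that software even
  though the ratio definition is identical.
- Perimeters of structures thinner than ~2 px carry staircase bias (see
  above).
- Distances are planar; no correction for retinal curvature or axial
  length, and no fovea-centered zonal analysis.
- The longitudinal model assumes linear RAFH drift over the modeled window;
  sigmoidal natural-history dynamics are out of scope.
- Wald-z inference is mildly anticonservative at trial size (empirical
  type-I error ≈ 6% in the null-calibration study), which is inherent to
  the z approximation, not a defect of the fit.
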