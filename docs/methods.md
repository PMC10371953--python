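# Methods

This note documents the models, conventions and numerical choices behind
`polarrad`, in the order the pipeline runs.

## Synthetic polar-map cohorts

**What is emulated.** The analysis targets patients whose perfusion polar
maps are *visually normal* while global myocardial flow reserve (MFR) is
reduced (< 2). The premise is that diffuse flow impairment shows up as
subtly increased spatial heterogeneity of relative uptake. The generator
reproduces exactly that statistical structure and nothing else:

```
u(x) = base · (1 + G(x)) · (1 − g · r(x)) + ε(x)     inside the disc
```

* `G` — zero-mean Gaussian random field, built by convolving white noise
  with a Gaussian kernel (`sigma = correlation_length` pixels) and
  rescaling so its standard deviation over the mask equals the
  class-specific heterogeneity amplitude. Label 1 (reduced MFR) uses the
  larger amplitude.
* `g · r` — a plain radial (apex-to-base) linear trend of strength `g`
  on the normalized radius; real normal maps have structured perfusion
  gradients (apical thinning, sex differences) that are *not* modelled.
* `ε` — independent per-pixel Gaussian noise (`noise_floor` std).

Values are clipped at zero (settings that would zero out more than 10% of
masked pixels are rejected as visually abnormal) and rescaled so the
masked maximum is 100% of the dynamic range. The map is a deterministic
function of (spec, label, subject seed); per-subject seeds derive from the
cohort seed via `numpy.random.SeedSequence`.

**Defaults (the shipped `large_effect` preset).** 50 reduced-MFR + 50
preserved-MFR derivation subjects, 30 validation subjects with the same
class proportions; 64-pixel canvas (disc radius 30 px); base uptake 0.8 of
peak; heterogeneity amplitudes 0.15 (reduced) vs 0.03 (preserved);
correlation length 6 px; gradient strength 0.2; noise floor 0.02. Under
these conditions the standardized mean class difference of `GLRLM_GLNU`
at 16 bins is ≈ 3.7, comfortably above the calibration requirement of 1.0
that the test suite asserts. The `null` preset is identical except both
classes share amplitude 0.08, so no feature carries outcome information.

**What passing tests do not show.** The generator has no scanner physics,
no reconstruction artefacts, no 17-segment anatomy, no kinetic model
linking amplitude to MFR values. Pipeline power on the preset therefore
demonstrates *algorithmic* correctness and statistical calibration, not
clinical performance; the published patient-data operating points
(cutoff 948; 67%/74%/58% derivation accuracy/sensitivity/specificity) are
properties of an undeposited registry cohort and are deliberately not
reproduction targets.

## Image representation

Polar maps are 8-bit single-channel lossless PNGs with 256 gray levels.
Decoding maps byte `v` to uptake `v/255·100`; encoding rounds half-up
(`round(u/100·255)`, so uptake 50 encodes as byte 128). The region of
interest is the maximal centered disc of strictly positive pixels (or an
explicit sidecar mask); background is exactly 0 and excluded. After
masking, uptake is rescaled so the masked maximum is exactly 100. A valid
map needs at least 64 masked pixels. Encode/decode round-trips are exact
to within half a quantization step (100/255 per cent of peak).

## Discretization

Relative (min–max) resampling between the masked minimum and maximum:

```
level(x) = 1 + floor(n_bins · (u(x) − u_min) / (u_max − u_min))
```

with the maximum clamped into the top bin (half-open bins, closed at the
top) and constant regions mapping to level 1. This is the mode consistent
with peak-normalized relative images; absolute bounds can be passed
explicitly for fixed-bound discretization. The five standard depths are
8, 16, 32, 64 and 128 bins; other depths work but warn.

## The feature catalogue

95 named features per depth, enumerated in `polarrad.catalogue`
(`catalogue_frame()` is the machine-readable manifest with a formula per
entry). Composition:

* **24 3D-only** features (shape descriptors and volumetric texture
  aggregates) — recorded as NaN on 2D maps and removed by the
  applicability filter.
* **23 CONVENTIONAL** first-order statistics on raw uptake — identical
  across depths by construction.
* **48 depth-dependent** features: 16 DISCRETIZED/HISTO first-order
  statistics, 7 GLCM, 11 GLRLM, 3 NGLDM, 11 GLZLM.

Conventions worth noting:

* Kurtosis is raw (Pearson), not excess, in both first-order families.
  `Discretized_Kurtosis`/`Discretized_Skewness` are **bias-corrected
  sample estimators** over per-pixel level values, while
  `DISCRETIZED_HISTO_Kurtosis`/`Skewness` are **population moments of the
  normalized histogram**; with population moments throughout the two
  would be algebraically identical, so the finite-sample correction is
  what keeps them distinct catalogue entries.
* Entropies are carried in both log2 and log10.
* Texture matrices merge the four 2D directions (0°, 45°, 90°, 135°) into
  one count matrix *before* feature computation; per-direction averaging
  is a possible alternative that is not the default.
* GLRLM run percentage uses the merged-pixel budget:
  `RP = N_r / (n_pixels · 4)`.
* GLZLM zones are 8-connected components of equal level;
  `ZP = N_z / n_pixels`.
* NGLDM stores dependence counts `Q(i,k)`: masked pixels of level `i`
  with `k` of their in-mask 8-neighbours sharing the level. Coarseness,
  Contrast and Busyness are documented adaptations of the Amadasun–King
  statistics to this matrix (see formulas in the manifest); degenerate
  single-level regions return 0 for Contrast/Busyness, and GLCM
  correlation is defined as 0 when either marginal variance vanishes.
* Pixels are treated as isotropic and unitless (polar maps are abstract
  projections); no anisotropy resampling is applied.

All four matrix implementations are verified against naive brute-force
enumeration oracles on exhaustively enumerated small grids (every masked
grid with up to six cells over levels {0..3}) plus a seeded random sample
of 3×3–4×4 grids, and all features are invariant under 90° rotation.

## Selection cascade

Stage order and conventions (defaults in `SelectionConfig`):

1. **Applicability** — drop the 24 3D-only features.
2. **Depth invariance** — drop features whose columns are identical
   across all depths for every subject (exact equality; the 23
   CONVENTIONAL features on a conforming table).
3. **Near-zero variance** (threshold 0.0025) — sample variance (ddof 1)
   of min–max scaled columns; a raw-scale threshold would be meaningless
   across features spanning orders of magnitude (GLNU ~ 10³ vs kurtosis
   ~ 1). Exact constants drop at any threshold.
4. **Correlation pruning** (|ρ| ≥ 0.85) — greedy: repeatedly find the
   worst remaining pair and drop the member with the larger mean absolute
   correlation to everything else; ties keep the earlier catalogue-order
   column. NaN correlations (constant columns) count as 0.

Stages 3–4 run **within each depth's feature block**, so every depth
keeps its own survivor set — a pooled prune would mostly remove the same
feature's near-duplicate columns at adjacent depths and collapse the
per-depth structure the later screen needs.

5. **Boruta** — pooled across depths. Each iteration appends an
   independently permuted shadow copy of every candidate, fits a random
   forest (default 500 trees; importances are the forest's impurity-based
   importances — permutation importances would cost a scoring pass per
   column per iteration for little decision benefit at these sample
   sizes), and scores a hit when a real feature beats the best shadow.
   Hits are Binomial(t, ½) under the null; a two-sided binomial test at
   α = 0.05 with Bonferroni correction across all candidates confirms or
   rejects; undecided features after `max_iter` (default 100) are
   tentative and excluded by default. Heavy consumers (tests, the
   acceptance script) run 15–20 iterations with 75 trees, which is ample
   at the preset effect sizes.
6. **Univariate screen** — one logistic regression per surviving feature
   name at *every* depth (values from the post-invariance table), with
   standardized predictors and Wald p-values; Benjamini–Hochberg at
   q = 0.10 applied within each depth (pooled correction available).
   Perfect separation falls back to a Firth-style bias-reduced fit
   (Jeffreys-penalized Newton iterations) and is flagged.
7. **Depth choice** — the depth with the most significant predictors;
   ties break toward the coarser depth; none-significant-anywhere returns
   an explicit none marker.

Every stage writes its drops (with reason and statistic) into a
`SelectionReport` whose stage in/out counts must telescope; the report
serializes to deterministic text.

## Final model and evaluation

Forward stepwise logistic regression on the chosen depth's significant
features: likelihood-ratio entry test (p_enter 0.05) with a backward
removal check (p_remove 0.10); exact duplicates can never both enter
(the second adds zero likelihood). An empty model is an explicit flagged
outcome, not an error, except where a classifier is required.

The decision threshold is the Youden's *J* maximizer on the empirical ROC
(AUC by trapezoid ≡ Mann–Whitney; orientation auto-detected so AUC ≥ 0.5,
with the `≥`/`≤` decision direction recorded). Ties in *J* break toward
higher sensitivity. When exactly one feature is retained the cutoff is
reported on the raw feature scale (as a clinical cutoff would be);
otherwise on the linear-predictor scale — both the scale and direction
are stored in the classifier file.

Diagnostic metrics are derived from stored confusion counts
(accuracy, sensitivity, specificity, PPV, NPV as percentages; zero
denominators yield explicit undefined markers). Validation cohorts are
scored with frozen coefficients and cutoff only; subject-ID overlap with
the derivation cohort is an error.

## Determinism and problem sizes

Everything downstream of a config is a pure function of it: cohort seeds,
Boruta's generator and forest seeds, and all serializations are
deterministic, so `run-all` twice with one config produces byte-identical
report and classifier files (asserted in the test suite).

The shipped presets use 64-pixel maps and 50+50+30 subjects; a full
pipeline run takes ~10 s on one CPU, and the null-preset calibration
(20 full replicates) a few minutes. These sizes match the emulated study
design while keeping the whole suite quick to run.

## Known limitations

* The catalogue's exact 95-name composition (and the identity of the 24
  3D-only entries) is pinned by this package's manifest; extraction
  software in this field varies in naming and in bin-edge conventions, so
  absolute feature values are not comparable across toolkits.
* The univariate screen's Firth fallback reports Wald p-values from the
  penalized information matrix, a pragmatic (not exact) treatment of
  separation.
* The generator's radial gradient is a stand-in for real perfusion
  pattern statistics; nothing anatomical is modelled.
* Single held-out validation only — no cross-validation or bootstrap
  machinery is included.
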