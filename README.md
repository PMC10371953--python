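# polarrad

Radiomic texture analysis of myocardial PET polar maps for detecting
**diffusely impaired perfusion**.

## The problem

Myocardial perfusion imaging displays *relative* tracer uptake: the
left-ventricular polar map ("bullseye") is normalized to its own peak, so a
heart whose blood flow is *globally* reduced — balanced multi-vessel or
microvascular disease — can look perfectly normal. Quantitative PET exposes
such patients through the global myocardial flow reserve
(MFR = stress flow / rest flow; MFR < 2 is abnormal), but most clinical
scans never get absolute quantification. The hypothesis implemented here:
diffuse flow impairment leaves a statistical fingerprint — subtly more
*heterogeneous* relative uptake — that texture features can pick up from the
visually normal polar map alone.

`polarrad` provides the complete analysis as a tested, reusable library and
CLI:

1. **Polar-map I/O** — lossless 8-bit grayscale PNG (256 gray levels),
   circular whole-LV region of interest, peak normalization to 100%.
2. **Discretization** — min–max resampling of uptake to integer gray
   levels at five depths (8, 16, 32, 64, 128 bins):
   `level(x) = 1 + floor(n · (u(x) − u_min)/(u_max − u_min))`.
3. **Feature extraction** — a fixed 95-feature catalogue per depth
   (475 per subject): first-order statistics plus GLCM, GLRLM, NGLDM and
   GLZLM texture families. E.g. gray-level non-uniformity of the
   run-length matrix, `GLRLM_GLNU = Σᵢ (Σⱼ c(i,j))² / N_r`, is low for
   homogeneous and high for heterogeneous uptake patterns.
4. **Selection cascade** — applicability and depth-invariance pruning,
   near-zero-variance filter (var < 0.0025 on min–max scaled values),
   pairwise-correlation pruning (|ρ| ≥ 0.85), Boruta shadow-feature
   selection with random forests, univariate logistic screening with
   Benjamini–Hochberg control at a 10% FDR, and choice of the gray-level
   depth with the most significant predictors.
5. **Final model** — forward stepwise multivariate logistic regression,
   ROC analysis with Youden's *J* optimal cutoff, and diagnostic metrics
   (accuracy, sensitivity, specificity, PPV, NPV, AUC) on derivation and a
   strictly held-out validation cohort.

Because no patient images are distributed, the package ships a synthetic
cohort generator that emulates the study conditions: visually normal
circular maps whose spatially correlated uptake heterogeneity differs
between outcome classes, with a 50 + 50 derivation cohort and a 30-subject
validation cohort.

## Worked example

```python
import polarrad as pr

cfg = pr.preset_config("large_effect", seed=1,
                       boruta_max_iter=20, rf_n_trees=75)
result = pr.run_pipeline(cfg)
print("chosen depth:", result.report.chosen_gray_level)
print("significant:", result.report.significant_features)
print("model:", result.classifier.selected_features,
      "cutoff:", round(result.classifier.cutoff, 1),
      result.classifier.cutoff_direction)
print(result.validation_metrics.to_text())
```

prints (seed 1):

```
chosen depth: 8
significant: ['GLCM_Correlation', 'GLCM_Energy', 'GLRLM_GLNU', 'GLRLM_LRHGE',
 'GLRLM_LRLGE', 'GLZLM_GLNU', 'GLZLM_LZE', 'GLZLM_LZHGE', 'GLZLM_LZLGE',
 'GLZLM_SZE', 'NGLDM_Busyness']
model: ['GLRLM_LRLGE'] cutoff: 0.6 >=
tp=15 fp=0 tn=15 fn=0
accuracy=100.0%
sensitivity=100.0%
specificity=100.0%
ppv=100.0%
npv=100.0%
auc=1.000
```

Reading: on the shipped large-effect preset the cascade funnels 475
features down to a small significant set (including the zone-matrix
gray-level non-uniformity `GLZLM_GLNU`), the stepwise fit keeps a single
texture feature, and the frozen cutoff classifies all 30 held-out
validation subjects correctly — the synthetic effect is deliberately
strong. On the matched null preset (equal heterogeneity in both classes)
the same pipeline finds no significant predictor in essentially every
replicate, which is the intended false-discovery behaviour.

The same run from the shell:

```sh
polarrad run-all --preset large_effect --seed 1 --outdir results/run1
```

writes `features.csv`, `selection_report.txt`, `classifier.txt` and
`metrics.txt`. The stages are also available individually
(`polarrad simulate / extract / select / fit / evaluate`).

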