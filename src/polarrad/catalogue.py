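"""The radiomic feature catalogue.

The extraction computes 95 named features per gray-level depth. Of these,
24 apply only to three-dimensional volumes of interest (shape descriptors
and 3D texture aggregates) and are recorded as not-applicable on 2D polar
maps; of the remaining 71 two-dimensional features, the 23 first-order
CONVENTIONAL statistics are computed on the raw uptake values and are by
construction identical across gray-level depths, leaving 48 gray-level
dependent features: 16 DISCRETIZED/HISTO first-order statistics on the
level histogram, 7 GLCM, 11 GLRLM, 3 NGLDM and 11 GLZLM texture features.

``build_catalogue`` is the machine-readable manifest: each entry carries
the canonical name, family, applicability flags and a one-line formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FAMILIES = (
    "CONVENTIONAL",
    "DISCRETIZED",
    "HISTO",
    "SHAPE",
    "GLCM",
    "GLRLM",
    "NGLDM",
    "GLZLM",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalogue entry.

    ``requires_3d`` marks features applicable only to volumetric regions;
    ``gl_dependent`` is False for features whose value does not change with
    the discretization depth.
    """

    name: str
    family: str
    requires_3d: bool
    gl_dependent: bool
    formula: str


def _conv(name: str, formula: str) -> FeatureDescriptor:
    return FeatureDescriptor(f"CONVENTIONAL_{name}", "CONVENTIONAL", False, False, formula)


def _d(name: str, family: str, formula: str) -> FeatureDescriptor:
    return FeatureDescriptor(name, family, False, True, formula)


def _v3(name: str, family: str, formula: str) -> FeatureDescriptor:
    return FeatureDescriptor(name, family, True, True, formula)


#: 23 first-order statistics on raw uptake u (percent of peak), GL-invariant.
_CONVENTIONAL = [
    _conv("min", "min(u)"),
    _conv("max", "max(u)"),
    _conv("mean", "mean(u)"),
    _conv("std", "population std of u"),
    _conv("Variance", "population variance of u"),
    _conv("Q1", "25th percentile of u"),
    _conv("Q2", "median of u"),
    _conv("Q3", "75th percentile of u"),
    _conv("IQR", "Q3 - Q1"),
    _conv("Range", "max - min"),
    _conv("P10", "10th percentile of u"),
    _conv("P90", "90th percentile of u"),
    _conv("Skewness", "population skewness of u"),
    _conv("Kurtosis", "population Pearson (raw) kurtosis of u"),
    _conv("ExcessKurtosis", "population kurtosis - 3"),
    _conv("Energy", "sum(u^2)"),
    _conv("RMS", "sqrt(mean(u^2))"),
    _conv("MeanAbsDev", "mean |u - mean(u)|"),
    _conv("MedianAbsDev", "median |u - median(u)|"),
    _conv("RobustMeanAbsDev", "mean abs dev of u restricted to [P10, P90]"),
    _conv("CoeffVariation", "std / mean"),
    _conv("QuartileCoeffDispersion", "(Q3 - Q1) / (Q3 + Q1)"),
    _conv("Sum", "sum(u)"),
]

#: 11 first-order statistics on per-pixel discretized level values v in 1..n.
#: No Discretized_min entry: under relative min-max binning the minimum
#: level is 1 at every depth, which would make it depth-invariant.
_DISCRETIZED = [
    _d("Discretized_IQR", "DISCRETIZED", "Q3 - Q1 of v"),
    _d("Discretized_mean", "DISCRETIZED", "mean(v)"),
    _d("Discretized_max", "DISCRETIZED", "max(v)"),
    _d("Discretized_std", "DISCRETIZED", "sample std of v (ddof=1)"),
    _d("Discretized_Q1", "DISCRETIZED", "25th percentile of v"),
    _d("Discretized_Q2", "DISCRETIZED", "median of v"),
    _d("Discretized_Q3", "DISCRETIZED", "75th percentile of v"),
    _d("Discretized_Range", "DISCRETIZED", "max(v) - min(v)"),
    _d("Discretized_Peak", "DISCRETIZED", "mode level (smallest on ties)"),
    _d("Discretized_Skewness", "DISCRETIZED", "bias-corrected sample skewness of v"),
    _d("Discretized_Kurtosis", "DISCRETIZED", "bias-corrected sample Pearson kurtosis of v"),
]

#: 5 statistics on the normalized level histogram p_i.
_HISTO = [
    _d("DISCRETIZED_HISTO_Skewness", "HISTO", "population skewness of histogram"),
    _d("DISCRETIZED_HISTO_Kurtosis", "HISTO", "population Pearson kurtosis of histogram"),
    _d("DISCRETIZED_HISTO_Entropy_log2", "HISTO", "-sum p_i log2 p_i"),
    _d("DISCRETIZED_HISTO_Entropy_log10", "HISTO", "-sum p_i log10 p_i"),
    _d("DISCRETIZED_HISTO_Energy", "HISTO", "sum p_i^2"),
]

_GLCM = [
    _d("GLCM_Homogeneity", "GLCM", "sum p(i,j)/(1+|i-j|)"),
    _d("GLCM_Energy", "GLCM", "sum p(i,j)^2"),
    _d("GLCM_Contrast", "GLCM", "sum p(i,j)(i-j)^2"),
    _d("GLCM_Correlation", "GLCM", "sum (i-mu_i)(j-mu_j)p(i,j)/(sigma_i sigma_j)"),
    _d("GLCM_Entropy_log2", "GLCM", "-sum p(i,j) log2 p(i,j)"),
    _d("GLCM_Entropy_log10", "GLCM", "-sum p(i,j) log10 p(i,j)"),
    _d("GLCM_Dissimilarity", "GLCM", "sum p(i,j)|i-j|"),
]

_GLRLM = [
    _d("GLRLM_SRE", "GLRLM", "sum c(i,j)/j^2 / Nr"),
    _d("GLRLM_LRE", "GLRLM", "sum c(i,j) j^2 / Nr"),
    _d("GLRLM_LGRE", "GLRLM", "sum c(i,j)/i^2 / Nr"),
    _d("GLRLM_HGRE", "GLRLM", "sum c(i,j) i^2 / Nr"),
    _d("GLRLM_SRLGE", "GLRLM", "sum c(i,j)/(i^2 j^2) / Nr"),
    _d("GLRLM_SRHGE", "GLRLM", "sum c(i,j) i^2/j^2 / Nr"),
    _d("GLRLM_LRLGE", "GLRLM", "sum c(i,j) j^2/i^2 / Nr"),
    _d("GLRLM_LRHGE", "GLRLM", "sum c(i,j) i^2 j^2 / Nr"),
    _d("GLRLM_GLNU", "GLRLM", "sum_i (sum_j c(i,j))^2 / Nr"),
    _d("GLRLM_RLNU", "GLRLM", "sum_j (sum_i c(i,j))^2 / Nr"),
    _d("GLRLM_RP", "GLRLM", "Nr / (n_pixels * n_directions)"),
]

_NGLDM = [
    _d("NGLDM_Coarseness", "NGLDM", "sum k p(i,k) / 8 (mean matching-neighbour fraction)"),
    _d("NGLDM_Contrast", "NGLDM", "sum_{i,j} p_i p_j (i-j)^2 / (Ng(Ng-1))"),
    _d("NGLDM_Busyness", "NGLDM", "sum_i p_i (1-match_i) / sum_{i!=j} |i p_i - j p_j|"),
]

_GLZLM = [
    _d("GLZLM_SZE", "GLZLM", "sum c(i,s)/s^2 / Nz"),
    _d("GLZLM_LZE", "GLZLM", "sum c(i,s) s^2 / Nz"),
    _d("GLZLM_LGZE", "GLZLM", "sum c(i,s)/i^2 / Nz"),
    _d("GLZLM_HGZE", "GLZLM", "sum c(i,s) i^2 / Nz"),
    _d("GLZLM_SZLGE", "GLZLM", "sum c(i,s)/(i^2 s^2) / Nz"),
    _d("GLZLM_SZHGE", "GLZLM", "sum c(i,s) i^2/s^2 / Nz"),
    _d("GLZLM_LZLGE", "GLZLM", "sum c(i,s) s^2/i^2 / Nz"),
    _d("GLZLM_LZHGE", "GLZLM", "sum c(i,s) i^2 s^2 / Nz"),
    _d("GLZLM_GLNU", "GLZLM", "sum_i (sum_s c(i,s))^2 / Nz"),
    _d("GLZLM_ZLNU", "GLZLM", "sum_s (sum_i c(i,s))^2 / Nz"),
    _d("GLZLM_ZP", "GLZLM", "Nz / n_pixels"),
]

#: 24 features applicable only to three-dimensional volumes of interest:
#: shape descriptors plus 3D texture aggregates (13-direction GLCM,
#: 26-neighbour NGLDM, volumetric zone statistics). Recorded as
#: not-applicable on 2D polar maps and removed by the applicability filter.
_THREE_D_ONLY = [
    FeatureDescriptor("SHAPE_Volume_mL", "SHAPE", True, False, "ROI volume, mL"),
    FeatureDescriptor("SHAPE_Volume_vx", "SHAPE", True, False, "ROI volume, voxels"),
    FeatureDescriptor("SHAPE_Surface_mm2", "SHAPE", True, False, "mesh surface area"),
    FeatureDescriptor("SHAPE_Sphericity", "SHAPE", True, False, "pi^(1/3)(6V)^(2/3)/A"),
    FeatureDescriptor("SHAPE_Compacity", "SHAPE", True, False, "V / (sqrt(pi) A^(3/2))"),
    FeatureDescriptor("SHAPE_Elongation", "SHAPE", True, False, "sqrt(lambda2/lambda1)"),
    FeatureDescriptor("SHAPE_Flatness", "SHAPE", True, False, "sqrt(lambda3/lambda1)"),
    FeatureDescriptor("SHAPE_MajorAxisLength", "SHAPE", True, False, "4 sqrt(lambda1)"),
    FeatureDescriptor("SHAPE_MinorAxisLength", "SHAPE", True, False, "4 sqrt(lambda2)"),
    FeatureDescriptor("SHAPE_LeastAxisLength", "SHAPE", True, False, "4 sqrt(lambda3)"),
    _v3("GLCM_Homogeneity_3D", "GLCM", "3D 13-direction homogeneity"),
    _v3("GLCM_Energy_3D", "GLCM", "3D 13-direction energy"),
    _v3("GLCM_Contrast_3D", "GLCM", "3D 13-direction contrast"),
    _v3("GLCM_Correlation_3D", "GLCM", "3D 13-direction correlation"),
    _v3("GLCM_Entropy_log2_3D", "GLCM", "3D 13-direction entropy, log2"),
    _v3("GLCM_Entropy_log10_3D", "GLCM", "3D 13-direction entropy, log10"),
    _v3("GLCM_Dissimilarity_3D", "GLCM", "3D 13-direction dissimilarity"),
    _v3("NGLDM_Coarseness_3D", "NGLDM", "26-neighbour coarseness"),
    _v3("NGLDM_Contrast_3D", "NGLDM", "26-neighbour contrast"),
    _v3("NGLDM_Busyness_3D", "NGLDM", "26-neighbour busyness"),
    _v3("GLZLM_SZE_3D", "GLZLM", "volumetric small-zone emphasis"),
    _v3("GLZLM_LZE_3D", "GLZLM", "volumetric large-zone emphasis"),
    _v3("GLZLM_GLNU_3D", "GLZLM", "volumetric gray-level non-uniformity"),
    _v3("GLZLM_ZLNU_3D", "GLZLM", "volumetric zone-length non-uniformity"),
]

_CATALOGUE: list[FeatureDescriptor] = (
    _CONVENTIONAL + _DISCRETIZED + _HISTO + _GLCM + _GLRLM + _NGLDM + _GLZLM + _THREE_D_ONLY
)


def build_catalogue() -> list[FeatureDescriptor]:
    """Return the fixed 95-feature catalogue."""
    return list(_CATALOGUE)


def catalogue_frame() -> pd.DataFrame:
    """The catalogue manifest as a DataFrame (name, family, flags, formula)."""
    return pd.DataFrame(
        [
            {
                "name": d.name,
                "family": d.family,
                "requires_3d": d.requires_3d,
                "gl_dependent": d.gl_dependent,
                "formula": d.formula,
            }
            for d in _CATALOGUE
        ]
    )


def two_d_feature_names() -> list[str]:
    """Names of the 71 features computable on 2D polar maps."""
    return [d.name for d in _CATALOGUE if not d.requires_3d]


def gl_dependent_feature_names() -> list[str]:
    """Names of the 48 2D features whose value depends on the bin depth."""
    return [d.name for d in _CATALOGUE if not d.requires_3d and d.gl_dependent]


def _check() -> None:
    names = [d.name for d in _CATALOGUE]
    assert len(names) == len(set(names)) == 95, "catalogue must have 95 unique names"
    assert sum(d.requires_3d for d in _CATALOGUE) == 24
    two_d = [d for d in _CATALOGUE if not d.requires_3d]
    assert len(two_d) == 71
    assert sum(not d.gl_dependent for d in two_d) == 23
    assert all(d.family in FAMILIES for d in _CATALOGUE)


_check()
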