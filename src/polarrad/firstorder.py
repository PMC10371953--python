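"""First-order intensity statistics.

Two families:

CONVENTIONAL
    Computed on the raw relative-uptake values (percent of peak) inside
    the region of interest; independent of the discretization depth.
DISCRETIZED / HISTO
    Computed on the integer gray levels. The DISCRETIZED statistics are
    sample estimators over the per-pixel level values (bias-corrected
    skewness/kurtosis); the HISTO statistics are population moments of the
    normalized level histogram. The two kurtosis entries therefore differ
    by finite-sample correction factors. Kurtosis is raw (Pearson), not
    excess, in both families unless the name says otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .discretize import DiscretizedMap
from .io import PolarMap


def conventional_features(pmap: PolarMap) -> dict[str, float]:
    """The 23 gray-level-independent statistics on raw uptake."""
    u = pmap.masked_values.astype(float)
    if u.size == 0:
        raise ValueError("empty mask")
    mean = float(u.mean())
    std = float(u.std())  # population
    q1, q2, q3 = (float(q) for q in np.percentile(u, [25, 50, 75]))
    p10, p90 = (float(q) for q in np.percentile(u, [10, 90]))
    if std > 0:
        skew = float(((u - mean) ** 3).mean() / std**3)
        kurt = float(((u - mean) ** 4).mean() / std**4)
    else:
        skew, kurt = 0.0, 0.0
    robust = u[(u >= p10) & (u <= p90)]
    robust_mad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return {
        "CONVENTIONAL_min": float(u.min()),
        "CONVENTIONAL_max": float(u.max()),
        "CONVENTIONAL_mean": mean,
        "CONVENTIONAL_std": std,
        "CONVENTIONAL_Variance": std**2,
        "CONVENTIONAL_Q1": q1,
        "CONVENTIONAL_Q2": q2,
        "CONVENTIONAL_Q3": q3,
        "CONVENTIONAL_IQR": q3 - q1,
        "CONVENTIONAL_Range": float(u.max() - u.min()),
        "CONVENTIONAL_P10": p10,
        "CONVENTIONAL_P90": p90,
        "CONVENTIONAL_Skewness": skew,
        "CONVENTIONAL_Kurtosis": kurt,
        "CONVENTIONAL_ExcessKurtosis": kurt - 3.0 if std > 0 else 0.0,
        "CONVENTIONAL_Energy": float((u**2).sum()),
        "CONVENTIONAL_RMS": float(np.sqrt((u**2).mean())),
        "CONVENTIONAL_MeanAbsDev": float(np.abs(u - mean).mean()),
        "CONVENTIONAL_MedianAbsDev": float(np.median(np.abs(u - q2))),
        "CONVENTIONAL_RobustMeanAbsDev": robust_mad,
        "CONVENTIONAL_CoeffVariation": std / mean if mean != 0 else 0.0,
        "CONVENTIONAL_QuartileCoeffDispersion": (q3 - q1) / (q3 + q1) if (q3 + q1) != 0 else 0.0,
        "CONVENTIONAL_Sum": float(u.sum()),
    }


def discretized_features(dmap: DiscretizedMap) -> dict[str, float]:
    """The 16 gray-level-dependent first-order statistics."""
    v = dmap.levels[dmap.mask].astype(float)
    if v.size == 0:
        raise ValueError("empty mask")
    q1, q2, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    constant = v.max() == v.min()
    if constant or v.size < 3:
        d_skew, d_kurt = 0.0, 0.0
    else:
        d_skew = float(stats.skew(v, bias=False))
        d_kurt = float(stats.kurtosis(v, fisher=False, bias=False))
    hist = np.bincount(dmap.levels[dmap.mask], minlength=dmap.n_bins + 1)[1:]
    p = hist / hist.sum()
    lev = np.arange(1, dmap.n_bins + 1, dtype=float)
    mu = float((lev * p).sum())
    var = float(((lev - mu) ** 2 * p).sum())
    if var > 0:
        h_skew = float(((lev - mu) ** 3 * p).sum() / var**1.5)
        h_kurt = float(((lev - mu) ** 4 * p).sum() / var**2)
    else:
        h_skew, h_kurt = 0.0, 0.0
    pos = p[p > 0]
    # mode level; smallest level on ties
    peak = float(np.argmax(hist) + 1)
    return {
        "Discretized_IQR": q3 - q1,
        "Discretized_mean": float(v.mean()),
        "Discretized_max": float(v.max()),
        "Discretized_std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "Discretized_Q1": q1,
        "Discretized_Q2": q2,
        "Discretized_Q3": q3,
        "Discretized_Range": float(v.max() - v.min()),
        "Discretized_Peak": peak,
        "Discretized_Skewness": d_skew,
        "Discretized_Kurtosis": d_kurt,
        "DISCRETIZED_HISTO_Skewness": h_skew,
        "DISCRETIZED_HISTO_Kurtosis": h_kurt,
        "DISCRETIZED_HISTO_Entropy_log2": float(-(pos * np.log2(pos)).sum()),
        "DISCRETIZED_HISTO_Entropy_log10": float(-(pos * np.log10(pos)).sum()),
        "DISCRETIZED_HISTO_Energy": float((p**2).sum()),
    }
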