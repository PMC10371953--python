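"""Feature extraction: polar maps -> subjects x (gray level, feature) table.

Columns are named ``GL{depth}_{feature}`` (e.g. ``GL16_GLRLM_GLNU``).
Features flagged 3D-only in the catalogue are recorded as NaN
(not-applicable markers); CONVENTIONAL features are computed once on the
raw uptake and replicated across depths, so their columns are identical at
every depth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import build_catalogue
from .discretize import STANDARD_BIN_DEPTHS, discretize
from .firstorder import conventional_features, discretized_features
from .io import PolarMap
from .synthetic import SubjectRecord
from .texture import (
    compute_glcm,
    compute_glrlm,
    compute_glzlm,
    compute_ngldm,
    glcm_features,
    glrlm_features,
    glzlm_features,
    ngldm_features,
)


def column_name(gl: int, feature: str) -> str:
    return f"GL{gl}_{feature}"


def split_column(col: str) -> tuple[int, str]:
    """Parse ``GL16_GLRLM_GLNU`` -> (16, 'GLRLM_GLNU')."""
    head, feature = col.split("_", 1)
    if not head.startswith("GL"):
        raise ValueError(f"malformed feature column {col!r}")
    return int(head[2:]), feature


def extract_features(
    pmap: PolarMap,
    bin_depths: tuple[int, ...] = STANDARD_BIN_DEPTHS,
) -> pd.Series:
    """All catalogue features for one map at every requested depth."""
    if not bin_depths:
        raise ValueError("bin_depths must be nonempty")
    catalogue = build_catalogue()
    conv = conventional_features(pmap)
    values: dict[str, float] = {}
    for depth in bin_depths:
        dmap = discretize(pmap, depth)
        per_gl: dict[str, float] = dict(conv)
        per_gl.update(discretized_features(dmap))
        per_gl.update(glcm_features(compute_glcm(dmap)))
        per_gl.update(glrlm_features(compute_glrlm(dmap)))
        per_gl.update(ngldm_features(compute_ngldm(dmap)))
        per_gl.update(glzlm_features(compute_glzlm(dmap)))
        for desc in catalogue:
            values[column_name(depth, desc.name)] = (
                np.nan if desc.requires_3d else per_gl[desc.name]
            )
    return pd.Series(values)


@dataclass
class CohortFeatures:
    """Feature table plus outcome labels and cohort roles, index-aligned."""

    features: pd.DataFrame
    labels: pd.Series
    roles: pd.Series

    @property
    def derivation(self) -> tuple[pd.DataFrame, pd.Series]:
        keep = self.roles == "derivation"
        return self.features.loc[keep], self.labels.loc[keep]

    @property
    def validation(self) -> tuple[pd.DataFrame, pd.Series]:
        keep = self.roles == "validation"
        return self.features.loc[keep], self.labels.loc[keep]


def extract_cohort(
    records: list[SubjectRecord],
    bin_depths: tuple[int, ...] = STANDARD_BIN_DEPTHS,
) -> CohortFeatures:
    """Extract the full feature table for a cohort of subject records."""
    rows = {}
    labels = {}
    roles = {}
    for rec in records:
        rows[rec.subject_id] = extract_features(rec.polar_map, bin_depths)
        labels[rec.subject_id] = rec.label
        roles[rec.subject_id] = rec.cohort_role
    features = pd.DataFrame.from_dict(rows, orient="index")
    return CohortFeatures(
        features=features,
        labels=pd.Series(labels, name="label").loc[features.index],
        roles=pd.Series(roles, name="cohort_role").loc[features.index],
    )


def save_cohort_features(cf: CohortFeatures, path: str) -> None:
    """Write features + labels + roles as one delimited text file."""
    out = cf.features.copy()
    out.insert(0, "cohort_role", cf.roles)
    out.insert(0, "label", cf.labels)
    out.to_csv(path, index_label="subject_id")


def load_cohort_features(path: str) -> CohortFeatures:
    df = pd.read_csv(path, index_col="subject_id")
    labels = df.pop("label").astype(int)
    roles = df.pop("cohort_role").astype(str)
    return CohortFeatures(features=df, labels=labels, roles=roles)
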