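"""Final model: stepwise logistic fit, ROC cutoff, diagnostic metrics.

The classifier is a forward stepwise multivariate logistic regression on
the chosen gray level's significant features (likelihood-ratio entry test
at p_enter, removal check at p_remove), followed by an ROC-derived optimal
cutoff (Youden's J). When a single feature survives, the cutoff is
reported on the raw feature scale; otherwise on the model-score scale.
Validation subjects are scored with frozen coefficients and cutoff — no
refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve


class ModelError(ValueError):
    """Raised for degenerate model inputs (empty model, cohort overlap...)."""


# ---------------------------------------------------------------------------
# stepwise logistic regression


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


class StepwiseLogisticRegression(BaseEstimator, ClassifierMixin):
    """Forward stepwise logistic regression with likelihood-ratio tests.

    Parameters
    ----------
    p_enter : float
        Entry threshold for the likelihood-ratio p-value of adding a
        candidate (default 0.05).
    p_remove : float
        Removal threshold re-checked after each entry (default 0.10).

    Fitted attributes
    -----------------
    selected_features_ : ordered list of retained column names.
    coef_, intercept_ : maximum-likelihood coefficients on the raw scale.
    empty_model_ : True when no candidate met the entry criterion.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def _lr_pvalue(self, y, X_small, X_big) -> float:
        try:
            ll0 = _fit_logit(y, X_small).llf if X_small is not None else _null_llf(y)
            res = _fit_logit(y, X_big)
            # perfect separation leaves the fit formally non-converged but
            # with a well-defined (near-zero) log-likelihood; only reject
            # fits whose likelihood is not finite
            if not np.isfinite(res.llf) or not np.all(np.isfinite(res.params)):
                return 1.0
            lr = 2.0 * (res.llf - ll0)
        except Exception:
            return 1.0
        if lr <= 0:
            return 1.0
        return float(stats.chi2.sf(lr, df=1))

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ModelError("both outcome classes required")
        candidates = list(X.columns)
        selected: list[str] = []
        while True:
            changed = False
            # forward step
            best_p, best_c = None, None
            base = sm.add_constant(X[selected].to_numpy(), has_constant="add") if selected else None
            for c in candidates:
                if c in selected:
                    continue
                cols = selected + [c]
                X_big = sm.add_constant(X[cols].to_numpy(), has_constant="add")
                p = self._lr_pvalue(y, base, X_big)
                if best_p is None or p < best_p:
                    best_p, best_c = p, c
            if best_c is not None and best_p < self.p_enter:
                selected.append(best_c)
                changed = True
                # backward check on previously entered terms
                for c in list(selected[:-1]):
                    rest = [s for s in selected if s != c]
                    X_small = sm.add_constant(X[rest].to_numpy(), has_constant="add")
                    X_big = sm.add_constant(X[selected].to_numpy(), has_constant="add")
                    p_rm = self._lr_pvalue(y, X_small, X_big)
                    if p_rm > self.p_remove:
                        selected.remove(c)
            if not changed:
                break
        self.selected_features_ = selected
        self.empty_model_ = not selected
        self.separation_flag_ = False
        if selected:
            design = sm.add_constant(X[selected].to_numpy(), has_constant="add")
            try:
                res = _fit_logit(y, design)
                params = np.asarray(res.params, dtype=float)
                if not np.all(np.isfinite(params)):
                    raise ValueError("non-finite ML coefficients")
                self.result_ = res
            except Exception:
                # separated data: Firth bias-reduced fit keeps coefficients
                # finite; flag it for the report
                from .stats import firth_logistic

                params, _ = firth_logistic(design, y)
                self.separation_flag_ = True
            self.intercept_ = float(params[0])
            self.coef_ = np.asarray(params[1:], dtype=float)
        else:
            self.intercept_ = float(np.log(y.mean() / (1 - y.mean())))
            self.coef_ = np.zeros(0)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if self.empty_model_:
            raise ModelError("empty model: no feature met the entry criterion")
        return self.intercept_ + X[self.selected_features_].to_numpy(dtype=float) @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        s = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def stepwise_logistic(
    table: pd.DataFrame,
    labels,
    candidate_features: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseLogisticRegression:
    if not candidate_features:
        raise ModelError("candidate feature list is empty")
    return StepwiseLogisticRegression(p_enter=p_enter, p_remove=p_remove).fit(
        table[candidate_features], labels
    )


# ---------------------------------------------------------------------------
# ROC and cutoff


@dataclass
class RocResult:
    """Empirical ROC curve with orientation.

    ``direction`` is ">=" when high scores indicate the positive class and
    "<=" when low scores do (orientation chosen so AUC >= 0.5); thresholds
    are on the original score scale, and a prediction is positive when
    ``score direction threshold`` holds.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    direction: str


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all distinct thresholds; trapezoid AUC equals the
    Mann-Whitney statistic; orientation auto-detected."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ModelError("ROC requires at least one subject in each class")
    auc_raw = float(roc_auc_score(y, scores))
    if auc_raw >= 0.5:
        direction = ">="
        fpr, tpr, thr = _sk_roc_curve(y, scores)
    else:
        direction = "<="
        fpr, tpr, thr = _sk_roc_curve(y, -scores)
        thr = -thr
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=max(auc_raw, 1 - auc_raw), direction=direction)


def optimal_cutoff(roc: RocResult) -> tuple[float, float]:
    """Youden's J maximizer; ties break toward higher sensitivity.

    Returns (threshold, J). With all scores equal, J = 0 and the degenerate
    threshold is returned.
    """
    j = roc.tpr - roc.fpr
    best_j = j.max()
    # among maximizers pick the highest sensitivity
    idx = np.flatnonzero(j == best_j)
    best = idx[np.argmax(roc.tpr[idx])]
    thr = float(roc.thresholds[best])
    if not np.isfinite(thr):
        finite = roc.thresholds[np.isfinite(roc.thresholds)]
        thr = float(finite[0]) if finite.size else 0.0
    return thr, float(best_j)


# ---------------------------------------------------------------------------
# diagnostic metrics


@dataclass
class DiagnosticMetrics:
    """Confusion counts plus the derived percentages.

    Percentages are None when the denominator is zero (undefined, not a
    number). ``auc`` is a fraction in [0, 1] when available.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    @property
    def accuracy(self) -> float | None:
        return self._pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    def to_text(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.1f}%"

        lines = [
            f"tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn}",
            f"accuracy={fmt(self.accuracy)}",
            f"sensitivity={fmt(self.sensitivity)}",
            f"specificity={fmt(self.specificity)}",
            f"ppv={fmt(self.ppv)}",
            f"npv={fmt(self.npv)}",
        ]
        if self.auc is not None:
            lines.append(f"auc={self.auc:.3f}")
        return "\n".join(lines) + "\n"


def diagnostic_metrics(predictions, labels, auc: float | None = None) -> DiagnosticMetrics:
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if pred.size == 0 or pred.shape != y.shape:
        raise ModelError("predictions and labels must be equal-length and nonempty")
    return DiagnosticMetrics(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# final fitted classifier


@dataclass
class FittedClassifier:
    """Frozen final model: chosen depth, features, coefficients, cutoff."""

    gray_level: int
    selected_features: list[str]  # base feature names
    coefficients: dict[str, float]  # feature -> weight, plus "intercept"
    cutoff: float
    cutoff_direction: str  # ">=" or "<=" predicts reduced MFR
    cutoff_scale: str  # "feature" | "score"
    youden_j: float
    derivation_auc: float
    derivation_subjects: list[str] = dc_field(default_factory=list)

    def columns(self) -> list[str]:
        return [f"GL{self.gray_level}_{f}" for f in self.selected_features]

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Decision score per subject (raw feature value in single-feature
        models, linear predictor otherwise)."""
        cols = self.columns()
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ModelError(f"features missing from table: {missing}")
        if not self.selected_features:
            raise ModelError("empty model cannot score subjects")
        if self.cutoff_scale == "feature":
            return table[cols[0]].to_numpy(dtype=float)
        s = np.full(len(table), self.coefficients["intercept"], dtype=float)
        for f, c in zip(self.selected_features, cols):
            s += self.coefficients[f] * table[c].to_numpy(dtype=float)
        return s

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        s = self.score(table)
        return (s >= self.cutoff).astype(int) if self.cutoff_direction == ">=" else (
            s <= self.cutoff
        ).astype(int)

    def to_text(self, provenance: dict | None = None) -> str:
        lines = ["# fitted classifier"]
        for key, val in (provenance or {}).items():
            lines.append(f"provenance\t{key}\t{val}")
        lines.append(f"gray_level\t{self.gray_level}")
        lines.append("features\t" + ",".join(self.selected_features))
        for name in ["intercept"] + self.selected_features:
            lines.append(f"coef\t{name}\t{self.coefficients[name]:.10g}")
        lines.append(f"cutoff\t{self.cutoff:.10g}")
        lines.append(f"cutoff_direction\t{self.cutoff_direction}")
        lines.append(f"cutoff_scale\t{self.cutoff_scale}")
        lines.append(f"youden_j\t{self.youden_j:.10g}")
        lines.append(f"derivation_auc\t{self.derivation_auc:.10g}")
        return "\n".join(lines) + "\n"


def fit_final_model(
    table: pd.DataFrame,
    labels,
    gray_level: int,
    significant_features: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> FittedClassifier:
    """Stepwise fit on the chosen depth's significant features, then the
    ROC-optimal Youden cutoff (raw feature scale for one-feature models)."""
    if not significant_features:
        raise ModelError("no significant features to fit")
    cols = [f"GL{gray_level}_{f}" for f in significant_features]
    model = stepwise_logistic(table, labels, cols, p_enter, p_remove)
    if model.empty_model_:
        raise ModelError("stepwise selection retained no feature (empty model)")
    kept = [c.split("_", 1)[1] for c in model.selected_features_]
    coeffs = {"intercept": model.intercept_}
    for name, w in zip(kept, model.coef_):
        coeffs[name] = float(w)
    if len(kept) == 1:
        scores = table[model.selected_features_[0]].to_numpy(dtype=float)
        scale = "feature"
    else:
        scores = model.decision_function(table)
        scale = "score"
    roc = roc_curve(scores, labels)
    cutoff, j = optimal_cutoff(roc)
    return FittedClassifier(
        gray_level=gray_level,
        selected_features=kept,
        coefficients=coeffs,
        cutoff=cutoff,
        cutoff_direction=roc.direction,
        cutoff_scale=scale,
        youden_j=j,
        derivation_auc=roc.auc,
        derivation_subjects=list(table.index.astype(str)),
    )


def apply_to_validation(
    classifier: FittedClassifier,
    validation_table: pd.DataFrame,
    validation_labels,
) -> DiagnosticMetrics:
    """Score a held-out cohort with frozen coefficients and cutoff."""
    overlap = set(validation_table.index.astype(str)) & set(classifier.derivation_subjects)
    if overlap:
        raise ModelError(f"validation overlaps derivation cohort: {sorted(overlap)[:5]}")
    scores = classifier.score(validation_table)
    y = np.asarray(validation_labels)
    auc = None
    if len(np.unique(y)) == 2:
        raw = float(roc_auc_score(y, scores))
        auc = raw if classifier.cutoff_direction == ">=" else 1 - raw
    pred = classifier.predict(validation_table)
    return diagnostic_metrics(pred, y, auc=auc)
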