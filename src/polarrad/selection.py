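"""The feature-selection cascade.

Outcome-independent stages
    1. applicability: drop the 24 features applicable only to 3D volumes;
    2. gray-level invariance: drop features identical across all depths
       for every subject (the 23 CONVENTIONAL statistics on a conforming
       catalogue);
    3. near-zero variance: drop columns whose sample variance on min-max
       scaled values falls below 0.0025;
    4. correlation pruning: greedily drop one member of every pair with
       absolute Pearson correlation >= 0.85.

Outcome-dependent stages
    5. Boruta: iterative random-forest comparison of each feature against
       the maximum importance of permuted "shadow" copies, with a
       two-sided binomial decision test (Bonferroni across features);
    6. univariate screen: one logistic regression per surviving feature at
       each gray-level depth, Benjamini-Hochberg corrected within depth at
       a 10% false discovery rate;
    7. gray-level choice: the depth with the most significant predictors.

Each stage is a scikit-learn style transformer over the feature DataFrame
(fit/transform, parameters via ``get_params``), and the classic function
names are thin wrappers. Every stage records what it dropped and why into
a :class:`SelectionReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .catalogue import build_catalogue
from .extract import split_column
from .stats import logistic_wald


@dataclass(frozen=True)
class SelectionConfig:
    """Cascade thresholds. Printed defaults: variance < 0.0025 (on min-max
    scaled values), |rho| >= 0.85, FDR q = 0.10."""

    variance_threshold: float = 0.0025
    correlation_threshold: float = 0.85
    fdr_q: float = 0.10
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    rf_n_trees: int = 500
    seed: int = 0
    boruta_keep_tentative: bool = False
    pooled_bh: bool = False  # BH pooled across depths instead of within

    def __post_init__(self) -> None:
        if not (0 <= self.variance_threshold):
            raise ValueError("variance_threshold must be non-negative")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must lie in (0, 1]")
        if not (0 < self.fdr_q < 1) or not (0 < self.boruta_alpha < 1):
            raise ValueError("fdr_q and boruta_alpha must lie in (0, 1)")
        if self.boruta_max_iter < 1 or self.rf_n_trees < 1:
            raise ValueError("boruta_max_iter and rf_n_trees must be positive")


@dataclass
class StageRecord:
    """Audit record of one cascade stage."""

    stage: str
    n_in: int
    n_out: int
    dropped: list[tuple[str, str, float]] = dc_field(default_factory=list)
    # (column, reason, statistic); statistic is NaN where not applicable


@dataclass
class SelectionReport:
    """Audit trail of the whole cascade."""

    stages: list[StageRecord] = dc_field(default_factory=list)
    screen: pd.DataFrame | None = None
    chosen_gray_level: int | None = None
    significant_features: list[str] = dc_field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and self.stages[-1].n_out != record.n_in:
            raise ValueError(
                f"stage {record.stage}: features-in ({record.n_in}) does not "
                f"match previous features-out ({self.stages[-1].n_out})"
            )
        if len(record.dropped) != record.n_in - record.n_out:
            raise ValueError(f"stage {record.stage}: drop count mismatch")
        self.stages.append(record)

    def to_text(self) -> str:
        lines = ["# selection report"]
        for st in self.stages:
            lines.append(f"## stage {st.stage}: in={st.n_in} out={st.n_out}")
            for col, reason, stat in st.dropped:
                stat_s = "" if np.isnan(stat) else f" stat={stat:.6g}"
                lines.append(f"drop\t{col}\t{reason}{stat_s}")
        if self.screen is not None:
            lines.append("## univariate screen")
            lines.append("gl\tfeature\tcoef\tp_raw\tp_adj\tsignificant\tflag")
            for _, r in self.screen.iterrows():
                lines.append(
                    f"{r.gl}\t{r.feature}\t{r.coef:.6g}\t{r.p_raw:.6g}\t"
                    f"{r.p_adj:.6g}\t{int(r.significant)}\t{r.flag}"
                )
        lines.append(f"## chosen gray level: {self.chosen_gray_level}")
        lines.append("## significant features: " + ", ".join(self.significant_features))
        return "\n".join(lines) + "\n"


def _record(report: SelectionReport | None, record: StageRecord) -> None:
    if report is not None:
        report.add(record)


class ApplicabilityFilter(BaseEstimator, TransformerMixin):
    """Drop catalogue features flagged as applicable only to 3D volumes."""

    def fit(self, X: pd.DataFrame, y=None):
        three_d = {d.name for d in build_catalogue() if d.requires_3d}
        self.dropped_ = [c for c in X.columns if split_column(c)[1] in three_d]
        self.kept_ = [c for c in X.columns if c not in set(self.dropped_)]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


class GLInvariantFilter(BaseEstimator, TransformerMixin):
    """Drop features identical across all gray levels for every subject."""

    def fit(self, X: pd.DataFrame, y=None):
        parsed = [split_column(c) for c in X.columns]
        gls = sorted({gl for gl, _ in parsed})
        if len(gls) < 2:
            raise ValueError("gray-level invariance needs at least two depths")
        by_feature: dict[str, list[str]] = {}
        for col, (gl, name) in zip(X.columns, parsed):
            by_feature.setdefault(name, []).append(col)
        invariant = []
        for name, cols in by_feature.items():
            if len(cols) < 2:
                continue
            ref = X[cols[0]].to_numpy()
            if all(np.array_equal(X[c].to_numpy(), ref) for c in cols[1:]):
                invariant.append(name)
        inv = set(invariant)
        self.invariant_features_ = sorted(inv)
        self.dropped_ = [c for c in X.columns if split_column(c)[1] in inv]
        self.kept_ = [c for c in X.columns if split_column(c)[1] not in inv]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Drop near-zero-variance columns.

    Variances are computed on per-column min-max scaled values; a raw-scale
    threshold would be meaningless across features whose magnitudes differ
    by orders.
    """

    def __init__(self, threshold: float = 0.0025):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        self.variances_ = {}
        self.dropped_ = []
        self.kept_ = []
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            rng = v.max() - v.min()
            var = float(((v - v.min()) / rng).var(ddof=1)) if rng > 0 else 0.0
            self.variances_[col] = var
            # "zero or near-zero": exact constants drop at any threshold
            low = var == 0.0 or var < self.threshold
            (self.dropped_ if low else self.kept_).append(col)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy pruning of feature pairs with |Pearson rho| >= threshold.

    While any pair exceeds the threshold, the member of the worst pair with
    the larger mean absolute correlation to the remaining features is
    dropped; ties break toward keeping the earlier (catalogue-order)
    column. Deterministic given the table.
    """

    def __init__(self, threshold: float = 0.85):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        corr = X.corr().abs().fillna(0.0)
        np.fill_diagonal(corr.values, 0.0)
        cols = list(X.columns)
        dropped: list[tuple[str, str, float]] = []
        while True:
            sub = corr.loc[cols, cols]
            max_val = float(sub.values.max()) if len(cols) > 1 else 0.0
            if max_val < self.threshold:
                break
            ai, bi = np.unravel_index(np.argmax(sub.values), sub.shape)
            a, b = cols[ai], cols[bi]
            mean_a = float(sub.loc[a].mean())
            mean_b = float(sub.loc[b].mean())
            if mean_a > mean_b:
                victim, partner = a, b
            elif mean_b > mean_a:
                victim, partner = b, a
            else:  # tie: drop the later column in table (catalogue) order
                victim, partner = (b, a) if cols.index(a) < cols.index(b) else (a, b)
            dropped.append((victim, f"|rho|>=thr with {partner}", max_val))
            cols.remove(victim)
        self.kept_ = cols
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


class BorutaSelector(BaseEstimator, TransformerMixin):
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends an independently permuted copy of every
    candidate column, fits a random forest, and scores each real feature a
    "hit" when its importance exceeds the maximum shadow importance. Hits
    follow Binomial(t, 1/2) under the null; a two-sided binomial test at
    ``alpha`` with Bonferroni correction across candidates confirms or
    rejects features as iterations accumulate. Rejected features (and
    their shadows) leave the forest; features undecided after ``max_iter``
    are tentative. Fully seeded.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_iter: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
        keep_tentative: bool = False,
    ):
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.alpha = alpha
        self.seed = seed
        self.keep_tentative = keep_tentative

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("Boruta requires both outcome classes")
        rng = np.random.default_rng(self.seed)
        cols = list(X.columns)
        m0 = len(cols)
        hits = {c: 0 for c in cols}
        trials = {c: 0 for c in cols}
        confirmed: list[str] = []
        rejected: list[str] = []
        active = list(cols)
        values = X.to_numpy(dtype=float)
        col_index = {c: k for k, c in enumerate(cols)}
        for it in range(1, self.max_iter + 1):
            if not active:
                break
            real = values[:, [col_index[c] for c in active]]
            shadows = real.copy()
            for k in range(shadows.shape[1]):
                rng.shuffle(shadows[:, k])
            design = np.hstack([real, shadows])
            forest = RandomForestClassifier(
                n_estimators=self.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(design, y)
            imp = forest.feature_importances_
            shadow_max = imp[len(active):].max()
            for k, c in enumerate(active):
                trials[c] += 1
                if imp[k] > shadow_max:
                    hits[c] += 1
            # two-sided binomial decision, Bonferroni across all candidates
            thr = self.alpha / (2 * m0)
            for c in list(active):
                t, h = trials[c], hits[c]
                if stats.binom.sf(h - 1, t, 0.5) < thr:
                    confirmed.append(c)
                    active.remove(c)
                elif stats.binom.cdf(h, t, 0.5) < thr:
                    rejected.append(c)
                    active.remove(c)
        self.confirmed_ = [c for c in cols if c in set(confirmed)]
        self.rejected_ = [c for c in cols if c in set(rejected)]
        self.tentative_ = [c for c in cols if c in set(active)]
        self.hits_ = hits
        self.trials_ = trials
        keep = set(self.confirmed_) | (set(self.tentative_) if self.keep_tentative else set())
        self.kept_ = [c for c in cols if c in keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


# ---------------------------------------------------------------------------
# function surface

def filter_applicability(
    table: pd.DataFrame, report: SelectionReport | None = None
) -> pd.DataFrame:
    f = ApplicabilityFilter().fit(table)
    _record(report, StageRecord(
        "applicability", table.shape[1], len(f.kept_),
        [(c, "3D-only feature", float("nan")) for c in f.dropped_],
    ))
    return f.transform(table)


def filter_gl_invariant(
    table: pd.DataFrame, report: SelectionReport | None = None
) -> pd.DataFrame:
    f = GLInvariantFilter().fit(table)
    _record(report, StageRecord(
        "gl-invariance", table.shape[1], len(f.kept_),
        [(c, "identical across gray levels", float("nan")) for c in f.dropped_],
    ))
    return f.transform(table)


def filter_low_variance(
    table: pd.DataFrame,
    threshold: float = 0.0025,
    report: SelectionReport | None = None,
) -> pd.DataFrame:
    f = VarianceFilter(threshold=threshold).fit(table)
    _record(report, StageRecord(
        "low-variance", table.shape[1], len(f.kept_),
        [(c, "near-zero variance", f.variances_[c]) for c in f.dropped_],
    ))
    return f.transform(table)


def filter_correlated(
    table: pd.DataFrame,
    threshold: float = 0.85,
    report: SelectionReport | None = None,
) -> pd.DataFrame:
    f = CorrelationFilter(threshold=threshold).fit(table)
    _record(report, StageRecord(
        "correlation", table.shape[1], len(f.kept_),
        [(c, reason, stat) for c, reason, stat in f.dropped_],
    ))
    return f.transform(table)


def boruta_select(
    table: pd.DataFrame,
    labels,
    config: SelectionConfig,
    report: SelectionReport | None = None,
) -> BorutaSelector:
    sel = BorutaSelector(
        n_trees=config.rf_n_trees,
        max_iter=config.boruta_max_iter,
        alpha=config.boruta_alpha,
        seed=config.seed,
        keep_tentative=config.boruta_keep_tentative,
    ).fit(table, labels)
    dropped = [
        (c, "Boruta rejected", float(sel.hits_[c])) for c in sel.rejected_
    ] + ([] if config.boruta_keep_tentative else [
        (c, "Boruta tentative", float(sel.hits_[c])) for c in sel.tentative_
    ])
    _record(report, StageRecord(
        "boruta", table.shape[1], len(sel.kept_), dropped,
    ))
    return sel


def benjamini_hochberg(p_values, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control; returns (adjusted p-values, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def univariate_screen(
    table: pd.DataFrame,
    labels,
    q: float = 0.10,
    pooled_bh: bool = False,
) -> pd.DataFrame:
    """Single-predictor logistic regression per (gray level, feature).

    Predictors are standardized before fitting; Wald p-values are BH
    corrected within each gray level (or pooled when requested). Perfect
    separation falls back to a Firth-style penalized fit and is flagged.
    """
    y = np.asarray(labels)
    rows = []
    for col in table.columns:
        gl, feature = split_column(col)
        x = table[col].to_numpy(dtype=float)
        coef, p, flag = logistic_wald(x, y)
        rows.append({"gl": gl, "feature": feature, "coef": coef, "p_raw": p, "flag": flag})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    out["significant"] = False
    if pooled_bh:
        groups = [out.index]
    else:
        groups = [out.index[out.gl == gl] for gl in sorted(out.gl.unique())]
    for idx in groups:
        if len(idx) == 0:
            continue
        p_adj, sig = benjamini_hochberg(out.loc[idx, "p_raw"].to_numpy(), q)
        out.loc[idx, "p_adj"] = p_adj
        out.loc[idx, "significant"] = sig
    return out[["gl", "feature", "coef", "p_raw", "p_adj", "significant", "flag"]]


def select_gray_level(screen: pd.DataFrame) -> tuple[int | None, list[str]]:
    """Depth with the most significant predictors; ties go to the coarser
    depth; (None, []) when nothing is significant anywhere."""
    counts = screen.groupby("gl")["significant"].sum()
    if counts.max() == 0:
        return None, []
    best = int(counts[counts == counts.max()].index.min())
    feats = screen[(screen.gl == best) & screen.significant]["feature"].tolist()
    return best, feats


def run_selection(
    table: pd.DataFrame,
    labels,
    config: SelectionConfig,
) -> tuple[SelectionReport, pd.DataFrame]:
    """Run the full cascade; returns the report and the post-Boruta table.

    The outcome-independent variance and correlation filters run within
    each gray level's feature block (each depth keeps its own survivor
    set), Boruta then sees the pooled survivors of all depths, and the
    univariate screen tests each Boruta-surviving feature name at every
    gray level, pulling values from the post-invariance table.
    """
    report = SelectionReport()
    t = filter_applicability(table, report)
    t_gl = filter_gl_invariant(t, report)
    gls_all = sorted({split_column(c)[0] for c in t_gl.columns})

    var_record = StageRecord("low-variance", t_gl.shape[1], 0, [])
    corr_record = StageRecord("correlation", 0, 0, [])
    kept_cols: list[str] = []
    for gl in gls_all:
        block = t_gl[[c for c in t_gl.columns if split_column(c)[0] == gl]]
        vf = VarianceFilter(threshold=config.variance_threshold).fit(block)
        var_record.dropped += [
            (c, "near-zero variance", vf.variances_[c]) for c in vf.dropped_
        ]
        cf = CorrelationFilter(threshold=config.correlation_threshold).fit(
            vf.transform(block)
        )
        corr_record.dropped += list(cf.dropped_)
        kept_cols += cf.kept_
    var_record.n_out = var_record.n_in - len(var_record.dropped)
    corr_record.n_in = var_record.n_out
    corr_record.n_out = corr_record.n_in - len(corr_record.dropped)
    report.add(var_record)
    report.add(corr_record)
    t3 = t_gl[[c for c in t_gl.columns if c in set(kept_cols)]]

    sel = boruta_select(t3, labels, config, report)
    survivors = sel.transform(t3)
    survivor_names = sorted({split_column(c)[1] for c in survivors.columns})
    gls = sorted({split_column(c)[0] for c in t_gl.columns})
    screen_cols = [
        f"GL{gl}_{name}" for gl in gls for name in survivor_names
        if f"GL{gl}_{name}" in t_gl.columns
    ]
    if screen_cols:
        screen = univariate_screen(t_gl[screen_cols], labels, config.fdr_q, config.pooled_bh)
    else:
        screen = pd.DataFrame(
            columns=["gl", "feature", "coef", "p_raw", "p_adj", "significant", "flag"]
        )
    report.screen = screen
    gl, feats = select_gray_level(screen) if len(screen) else (None, [])
    report.chosen_gray_level = gl
    report.significant_features = feats
    return report, survivors
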