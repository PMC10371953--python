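import numpy as np
import pandas as pd
import pytest

from polarrad.selection import (
    BorutaSelector,
    SelectionConfig,
    SelectionReport,
    StageRecord,
    benjamini_hochberg,
    filter_applicability,
    filter_correlated,
    filter_gl_invariant,
    filter_low_variance,
    select_gray_level,
    univariate_screen,
)


def _table(columns: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestApplicabilityFilter:
    def test_full_catalogue_table_drops_to_71_per_gl(self):
        from polarrad.catalogue import build_catalogue

        rng = np.random.default_rng(0)
        cols = {
            f"GL{gl}_{d.name}": rng.normal(size=10)
            for gl in (8, 16)
            for d in build_catalogue()
        }
        out = filter_applicability(_table(cols))
        assert out.shape[1] == 2 * 71

    def test_idempotent_and_empty(self):
        rng = np.random.default_rng(0)
        t = _table({"GL8_GLRLM_GLNU": rng.normal(size=5)})
        assert filter_applicability(filter_applicability(t)).shape[1] == 1
        empty = pd.DataFrame(index=range(5))
        assert filter_applicability(empty).shape[1] == 0


class TestGLInvariantFilter:
    def test_identical_across_gls_removed(self):
        v = np.arange(6.0)
        t = _table({
            "GL8_CONVENTIONAL_mean": v,
            "GL16_CONVENTIONAL_mean": v.copy(),
            "GL8_GLRLM_GLNU": v * 2,
            "GL16_GLRLM_GLNU": v * 3,
        })
        out = filter_gl_invariant(t)
        assert list(out.columns) == ["GL8_GLRLM_GLNU", "GL16_GLRLM_GLNU"]

    def test_difference_at_single_subject_retains_feature(self):
        v = np.arange(6.0)
        w = v.copy()
        w[3] += 1e-9
        t = _table({"GL8_X_f": v, "GL16_X_f": w})
        assert filter_gl_invariant(t).shape[1] == 2

    def test_single_gl_table_rejected(self):
        t = _table({"GL8_X_f": np.arange(4.0)})
        with pytest.raises(ValueError):
            filter_gl_invariant(t)


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        t = _table({"GL8_A_f": np.full(10, 3.0), "GL8_B_f": np.arange(10.0)})
        assert list(filter_low_variance(t).columns) == ["GL8_B_f"]

    def test_alternating_binary_column_retained(self):
        v = np.tile([0.0, 1.0], 10)
        t = _table({"GL8_A_f": v})
        out = filter_low_variance(t, threshold=0.0025)
        assert out.shape[1] == 1  # scaled variance ~0.25 >= 0.0025

    def test_zero_threshold_drops_only_exact_constants(self):
        v = np.arange(10.0)
        t = _table({"GL8_A_f": v, "GL8_B_f": np.full(10, 1.0)})
        out = filter_low_variance(t, threshold=0.0)
        assert list(out.columns) == ["GL8_A_f"]


class TestCorrelationFilter:
    def test_identical_columns_drop_exactly_one(self):
        v = np.arange(10.0)
        t = _table({"GL8_A_f": v, "GL8_B_f": v.copy()})
        out = filter_correlated(t)
        assert out.shape[1] == 1

    def test_three_mutually_perfect_columns_keep_one(self):
        v = np.arange(10.0)
        t = _table({"GL8_A_f": v, "GL8_B_f": 2 * v, "GL8_C_f": -v})
        out = filter_correlated(t)
        assert out.shape[1] == 1

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(0)
        t = _table({f"GL8_F{i}_f": rng.normal(size=200) for i in range(5)})
        out = filter_correlated(t, threshold=0.85)
        assert out.shape[1] == 5


class TestBenjaminiHochberg:
    def test_worked_step_up_example(self):
        """p = (.001, .02, .04, .2) at q = .10: thresholds .025/.05/.075/.10
        flag exactly the first three."""
        p_adj, sig = benjamini_hochberg([0.001, 0.02, 0.04, 0.2], q=0.10)
        assert sig.tolist() == [True, True, True, False]
        assert (np.diff(np.sort(p_adj)) >= -1e-15).all()

    def test_all_ones_none_significant(self):
        _, sig = benjamini_hochberg(np.ones(5), q=0.10)
        assert not sig.any()

    def test_single_p_at_boundary(self):
        _, sig = benjamini_hochberg([0.09], q=0.10)
        assert sig.all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([], 0.1)
        with pytest.raises(ValueError):
            benjamini_hochberg([1.2], 0.1)


class TestBoruta:
    @staticmethod
    def _noise_table(rng, n, p, prefix="GL16_F"):
        return pd.DataFrame(
            {f"{prefix}{i}_f": rng.normal(size=n) for i in range(p)}
        )

    def test_separating_feature_confirmed_noise_not(self):
        rng = np.random.default_rng(1)
        n = 200
        y = np.repeat([0, 1], n // 2)
        t = self._noise_table(rng, n, 10)
        t["GL16_Signal_f"] = y + rng.normal(scale=0.05, size=n)
        sel = BorutaSelector(n_trees=50, max_iter=20, seed=3).fit(t, y)
        assert "GL16_Signal_f" in sel.confirmed_
        assert not [c for c in sel.confirmed_ if c != "GL16_Signal_f"]

    def test_pure_noise_rarely_confirms(self):
        confirmed = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            y = np.repeat([0, 1], 30)
            t = self._noise_table(rng, 60, 10)
            sel = BorutaSelector(n_trees=30, max_iter=12, seed=rep).fit(t, y)
            confirmed += bool(sel.confirmed_)
        assert confirmed <= 2  # no confirmed features in >= 18 of 20 replicates

    def test_label_shuffle_destroys_confirmation(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.repeat([0, 1], n // 2)
        t = self._noise_table(rng, n, 5)
        t["GL16_Signal_f"] = y + rng.normal(scale=0.05, size=n)
        y_shuffled = rng.permutation(y)
        sel = BorutaSelector(n_trees=50, max_iter=20, seed=3).fit(t, y_shuffled)
        assert "GL16_Signal_f" not in sel.confirmed_

    def test_single_class_labels_rejected(self):
        t = self._noise_table(np.random.default_rng(0), 20, 3)
        with pytest.raises(ValueError):
            BorutaSelector().fit(t, np.zeros(20))


class TestUnivariateScreen:
    def test_constant_feature_non_significant(self):
        y = np.repeat([0, 1], 10)
        t = _table({"GL16_A_f": np.full(20, 2.0)})
        out = univariate_screen(t, y)
        row = out.iloc[0]
        assert row.coef == 0.0 and not row.significant and row.flag == "constant"

    def test_feature_equal_to_label_flags_separation(self):
        y = np.repeat([0, 1], 15)
        t = _table({"GL16_A_f": y.astype(float)})
        out = univariate_screen(t, y)
        assert out.iloc[0].flag == "separation"
        assert out.iloc[0].significant

    def test_strong_feature_significant_after_bh(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 40)
        t = _table({
            "GL16_Signal_f": y + rng.normal(scale=0.3, size=80),
            "GL16_Noise_f": rng.normal(size=80),
            "GL8_Noise2_f": rng.normal(size=80),
        })
        out = univariate_screen(t, y, q=0.10)
        sig = out[out.significant]
        assert ("Signal_f" in set(sig.feature)) and ("Noise_f" not in set(sig.feature))


class TestSelectGrayLevel:
    @staticmethod
    def _screen(counts: dict[int, int]) -> pd.DataFrame:
        rows = []
        for gl, k in counts.items():
            for i in range(5):
                rows.append({
                    "gl": gl, "feature": f"F{i}", "coef": 1.0,
                    "p_raw": 0.01, "p_adj": 0.01, "significant": i < k, "flag": "",
                })
        return pd.DataFrame(rows)

    def test_highest_count_wins(self):
        gl, feats = select_gray_level(self._screen({8: 0, 16: 2, 32: 1, 64: 0, 128: 0}))
        assert gl == 16 and len(feats) == 2

    def test_all_zero_selects_none(self):
        gl, feats = select_gray_level(self._screen({8: 0, 16: 0}))
        assert gl is None and feats == []

    def test_tie_broken_toward_coarser_depth(self):
        gl, _ = select_gray_level(self._screen({16: 2, 32: 2}))
        assert gl == 16


class TestSelectionReport:
    def test_stage_composition_enforced(self):
        rep = SelectionReport()
        rep.add(StageRecord("a", 10, 8, [("x", "r", 0.0), ("y", "r", 0.0)]))
        with pytest.raises(ValueError):
            rep.add(StageRecord("b", 9, 9, []))

    def test_drop_count_must_match(self):
        rep = SelectionReport()
        with pytest.raises(ValueError):
            rep.add(StageRecord("a", 10, 8, [("x", "r", 0.0)]))


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(correlation_threshold=1.5)
    with pytest.raises(ValueError):
        SelectionConfig(fdr_q=0.0)
    cfg = SelectionConfig()
    assert cfg.variance_threshold == 0.0025
    assert cfg.correlation_threshold == 0.85
    assert cfg.fdr_q == 0.10
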