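import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from crispr3d import (
    CVConfig,
    DensityEfficiencyModel,
    correlate,
    importance,
    paired_signed_rank,
    partial_correlation,
    quintile_contrast,
    repeated_cv,
)
from crispr3d.errors import DegenerateInputError, InputError, ParameterError


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_monotone_map_has_perfect_spearman(self):
        x = np.array([-3.0, -1.0, 0.5, 2.0, 4.0])
        r, _ = correlate(x, x**3, method="spearman")
        assert r == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(hand, rel=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_no_controls_equals_plain_correlation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert partial_correlation(x, y) == pytest.approx(correlate(x, y)[0])

    def test_common_cause_is_removed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=1000)
        x = z + rng.normal(size=1000)
        y = z + rng.normal(size=1000)
        assert abs(correlate(x, y)[0]) > 0.3  # confounded
        assert abs(partial_correlation(x, y, controls=[z])) < 0.1

    def test_spearman_variant_removes_monotone_confounder(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=800)
        x = np.exp(z) + 0.5 * rng.normal(size=800)
        y = z**3 + 20 * rng.normal(size=800)
        assert abs(partial_correlation(x, y, controls=[z], method="spearman")) < 0.1

    def test_controlling_x_for_itself_is_degenerate(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, y, controls=[x])

    def test_rank_deficient_controls_rejected(self):
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=30), rng.normal(size=30), rng.normal(size=30)
        with pytest.raises(DegenerateInputError, match="rank"):
            partial_correlation(x, y, controls=[z, 2 * z])


class TestQuintileContrast:
    def test_identical_groups_are_null(self):
        eff = np.linspace(0, 1, 40)
        feature = np.ones(40) * 3.0
        stat, p, direction = quintile_contrast(feature, eff)
        assert direction == 0
        assert p > 0.9

    def test_planted_direction_recovered(self, planted_fm, planted):
        name = planted["planted_feature"]
        stat, p, direction = quintile_contrast(
            planted_fm[name], planted_fm["efficiency"]
        )
        # Distance-type feature: high-efficiency sites sit in sparse regions
        assert direction == 1
        assert p < 0.05

    def test_null_pvalues_roughly_uniform_under_permutation(self):
        rng = np.random.default_rng(6)
        feature = rng.normal(size=100)
        pvals = []
        for _ in range(200):
            eff = rng.permutation(np.linspace(0, 1, 100))
            pvals.append(quintile_contrast(feature, eff)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_small_groups_rejected(self):
        with pytest.raises(InputError):
            quintile_contrast(np.arange(10.0), np.arange(10.0), q=0.2)


class TestPairedSignedRank:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            p = paired_signed_rank(np.ones(10), np.ones(10))
        assert p == 1.0

    def test_systematic_shift_is_overwhelming(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 0.5, size=1000)
        p = paired_signed_rank(base + 0.05, base)
        assert p < 1e-6

    def test_eight_pair_toy_matches_exact_enumeration(self):
        a = np.array([0.31, 0.28, 0.40, 0.25, 0.33, 0.37, 0.22, 0.30])
        b = np.array([0.30, 0.30, 0.35, 0.26, 0.30, 0.31, 0.24, 0.25])
        p = paired_signed_rank(a, b)
        # exact null distribution of W+ over all 2^8 sign assignments
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=8)
        ]
        ws = np.array(ws)
        mu = ws.mean()
        p_exact = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)


def _toy_regression(n=200, n_noise=10, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = pd.DataFrame({"informative": x})
    for k in range(n_noise):
        X[f"noise{k}"] = rng.normal(size=n)
    y = x + 0.5 * rng.normal(size=n)
    return X, y


def _fit_lasso(X, y, seed=0):
    pipe = Pipeline([("scale", StandardScaler()), ("lasso", Lasso(alpha=0.05))])
    return pipe.fit(X, y)


class TestImportance:
    def test_leaky_feature_dominates_permutation(self):
        X, y = _toy_regression(seed=8)
        X = X.copy()
        X["leak"] = y
        fit = _fit_lasso(X, y)
        imp = importance(fit, X, y, "permutation", rng=np.random.default_rng(0))
        assert imp.idxmax() == "leak"

    def test_noise_feature_importance_near_zero(self):
        # response independent of every feature; held-out permutation drops
        # should be centred on zero
        from sklearn.linear_model import Ridge

        drops = []
        for it in range(100):
            rng = np.random.default_rng(1000 + it)
            X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
            y = rng.normal(size=200)
            fit = Pipeline(
                [("scale", StandardScaler()), ("m", Ridge(alpha=1.0))]
            ).fit(X.iloc[:100], y[:100])
            imp = importance(
                fit, X.iloc[100:], y[100:], "permutation", rng=np.random.default_rng(it)
            )
            drops.append(imp["a"])
        drops = np.array(drops)
        assert abs(drops.mean()) < 2 * drops.std(ddof=1) / np.sqrt(len(drops))

    def test_informative_feature_selected_consistently(self):
        hits = 0
        for it in range(100):
            X, y = _toy_regression(n=500, n_noise=10, seed=500 + it)
            fit = _fit_lasso(X, y)
            sel = importance(fit, X, y, "selection")
            hits += int(sel["informative"] == 1)
        assert hits > 90

    def test_gain_on_lasso_rejected(self):
        X, y = _toy_regression(seed=9)
        fit = _fit_lasso(X, y)
        with pytest.raises(ParameterError):
            importance(fit, X, y, "gain")

    def test_duplicated_feature_splits_permutation_importance(self):
        # collinear copies shield each other: documented, not hidden
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        y = x + 0.3 * rng.normal(size=400)
        noise = rng.normal(size=400)
        solo = pd.DataFrame({"x": x, "noise": noise})
        dup = pd.DataFrame({"x": x, "x_copy": x, "noise": noise})

        def fit(X):
            return Pipeline(
                [("scale", StandardScaler()), ("m", Ridge(alpha=1.0))]
            ).fit(X, y)

        imp_solo = importance(fit(solo), solo, y, "permutation", np.random.default_rng(1))
        imp_dup = importance(fit(dup), dup, y, "permutation", np.random.default_rng(1))
        assert imp_dup["x"] < imp_solo["x"]
        assert imp_dup["x_copy"] < imp_solo["x"]


class TestRepeatedCV:
    def _small_fm(self, n=120, seed=11, signal=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{k}" for k in range(6)])
        dens = rng.normal(size=n)
        X["density3d"] = dens
        y = 0.5 * X["f0"] + (0.8 * dens if signal else 0.0) + 0.5 * rng.normal(size=n)
        X["efficiency"] = (y - y.min()) / (y.max() - y.min())
        return X

    def test_evaluation_count_and_paired_folds(self):
        fm = self._small_fm()
        rep = repeated_cv(fm, CVConfig(k=5, repeats=4, seed=0), "density3d")
        assert rep.n_evaluations == 20
        # one fold hash per paired evaluation; k distinct hashes per repeat
        assert rep.frame.groupby("repeat")["fold_hash"].nunique().eq(5).all()

    def test_report_is_deterministic(self):
        fm = self._small_fm()
        r1 = repeated_cv(fm, CVConfig(k=3, repeats=2, seed=4), "density3d")
        r2 = repeated_cv(fm, CVConfig(k=3, repeats=2, seed=4), "density3d")
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_informative_3d_column_improves_fit(self):
        fm = self._small_fm(signal=True)
        rep = repeated_cv(fm, CVConfig(k=5, repeats=6, seed=1), "density3d")
        assert rep.mean_r2_with > rep.mean_r2_without
        assert rep.signed_rank_p < 0.01

    def test_missing_3d_column_rejected(self):
        fm = self._small_fm()
        with pytest.raises(ParameterError):
            repeated_cv(fm, CVConfig(repeats=1), "nope")

    def test_screen_keeps_requested_feature_count(self):
        fm = self._small_fm()
        rep = repeated_cv(
            fm,
            CVConfig(k=3, repeats=1, seed=2, feature_screen=3, screen_scope="global"),
            "density3d",
        )
        assert rep.n_evaluations == 3
        # a global screen fixes the candidate set: screened cols + the 3D col
        assert (rep.selection_counts > 0).sum() <= 4

    def test_gbt_model_runs_and_reports_gain(self):
        fm = self._small_fm()
        rep = repeated_cv(
            fm,
            CVConfig(k=3, repeats=1, model="gbt", seed=3, importance_modes=("gain",)),
            "density3d",
        )
        assert "gain" in rep.importance_ranks
        assert rep.selection_counts is None


class TestModelResults:
    def test_full_and_partial_correlation_agree_on_planted_data(self, planted_fm, planted):
        name = planted["planted_feature"]
        dens = planted_fm[name].to_numpy()
        eff = planted_fm["efficiency"].to_numpy()
        gc = planted_fm["freq_G"].to_numpy() + planted_fm["freq_C"].to_numpy()
        full = correlate(dens, eff)[0]
        partial = partial_correlation(dens, eff, controls=[gc])
        assert np.sign(full) == np.sign(partial)
        assert abs(partial - full) / abs(full) < 0.5

    def test_summary_reports_planted_association(self, planted_fm, planted):
        model = DensityEfficiencyModel(planted_fm, planted["planted_feature"])
        res = model.fit(CVConfig(k=5, repeats=2, seed=13, feature_screen=30))
        text = res.summary()
        assert "Pearson r" in text and "Signed-rank" in text
        assert res.pearson[0] > 0  # Distance-type feature, planted direction
        assert res.cv_report.n_evaluations == 10
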