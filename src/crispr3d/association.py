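"""Association statistics and paired repeated cross-validation.

This module quantifies what a 3D density feature adds to the classic
CRISPR-efficiency predictors along the same axes a practitioner would use:

* plain and partial correlations (Pearson / Spearman) of features with
  measured efficiency — partial correlation residualizes both variables on
  the controls, isolating information the controls do not carry;
* a top-vs-bottom efficiency-quintile contrast of a feature (two-sided
  Wilcoxon rank-sum), giving a direction for the density-efficiency link;
* repeated k-fold cross-validation (default 5-fold x 200 repeats = 1000
  paired evaluations) of a learner trained twice per fold on identical
  splits — with and without the single 3D column — compared by Wilcoxon's
  signed-rank test on the paired test correlations, plus feature-importance
  bookkeeping (lasso selection counts, permutation importance, tree gain).

The statsmodels-style surface is :class:`DensityEfficiencyModel` /
:class:`DensityEfficiencyResults`: build the model from an assembled
feature matrix, call ``fit()``, read ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateInputError, InputError, ParameterError

__all__ = [
    "correlate",
    "partial_correlation",
    "quintile_contrast",
    "paired_signed_rank",
    "importance",
    "CVConfig",
    "CVReport",
    "repeated_cv",
    "DensityEfficiencyModel",
    "DensityEfficiencyResults",
]


# ---------------------------------------------------------------- statistics


def _as_finite(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p between two value vectors."""
    x, y = _as_finite(x, "x"), _as_finite(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise InputError("correlate needs two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), controls])
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateInputError(
            f"control matrix is rank-deficient (rank {rank} < {design.shape[1]} columns)"
        )
    return v - design @ coef


def partial_correlation(x, y, controls=(), method: str = "pearson") -> float:
    """Correlation of x and y after projecting both on [1, controls].

    ``controls`` is a sequence of vectors (or a 2D array, columns =
    controls); empty controls reduce to the plain correlation.  For
    ``"spearman"`` every vector is rank-transformed first, giving the
    rank-based partial correlation used when controlling for expression.
    """
    x, y = _as_finite(x, "x"), _as_finite(y, "y")
    c = np.asarray(controls, dtype=float)
    if c.size == 0:
        return correlate(x, y, method=method)[0]
    if c.ndim == 1:
        c = c[:, None]
    elif c.shape[0] != len(x) and c.shape[1] == len(x):
        c = c.T  # accept a list of control vectors
    if c.shape[0] != len(x) or len(x) != len(y):
        raise InputError("x, y and controls must share their length")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
        c = np.column_stack([stats.rankdata(col) for col in c.T])
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    rx, ry = _residualize(x, c), _residualize(y, c)
    # relative floor: residuals that are pure rounding noise count as zero
    if rx.std() <= 1e-8 * max(x.std(), 1e-300) or ry.std() <= 1e-8 * max(y.std(), 1e-300):
        raise DegenerateInputError(
            "zero residual variance: a variable is explained exactly by the controls"
        )
    return float(stats.pearsonr(rx, ry)[0])


def quintile_contrast(
    feature, efficiency, q: float = 0.2
) -> tuple[float, float, int]:
    """Two-sided Wilcoxon rank-sum of a feature between top-q and bottom-q
    efficiency sites.

    Returns (statistic, p, direction) with direction the sign of
    mean(feature | top) - mean(feature | bottom).
    """
    f, e = _as_finite(feature, "feature"), _as_finite(efficiency, "efficiency")
    if len(f) != len(e) or len(f) < 10:
        raise InputError("quintile contrast needs equal-length vectors with n >= 10")
    if not 0 < q <= 0.5:
        raise ParameterError(f"q must lie in (0, 0.5], got {q}")
    n_grp = int(np.floor(len(e) * q))
    if n_grp < 3:
        raise InputError(f"fewer than 3 sites per {q:.0%} group")
    order = np.argsort(e, kind="stable")
    bottom, top = f[order[:n_grp]], f[order[-n_grp:]]
    stat, p = stats.ranksums(top, bottom)
    return float(stat), float(p), int(np.sign(top.mean() - bottom.mean()))


def paired_signed_rank(r_with, r_without) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-iteration correlations."""
    a, b = _as_finite(r_with, "r_with"), _as_finite(r_without, "r_without")
    if len(a) != len(b) or len(a) < 6:
        raise InputError("signed-rank test needs equal-length vectors with n >= 6")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; signed-rank test degenerate")
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


# ------------------------------------------------------------ cross-validation


@dataclass(frozen=True)
class CVConfig:
    """Repeated-CV protocol knobs.

    k x repeats folds in total (default 5 x 200 = 1000 paired evaluations).
    ``model`` is "lasso" (z-scored features, lambda by inner 5-fold CV) or
    "gbt" (gradient-boosted trees with the fixed hyperparameters below).
    ``feature_screen`` keeps only the top-N classic features by |Pearson r|
    with efficiency; by default the screen is recomputed inside each
    training fold (``screen_scope="fold"``); ``"global"`` reproduces a
    single pre-CV screen.  ``importance_modes`` selects which rankings to
    record per iteration ("selection"/"permutation" for lasso,
    "permutation"/"gain" for gbt).
    """

    k: int = 5
    repeats: int = 200
    model: str = "lasso"
    seed: int = 0
    feature_screen: int | None = None
    screen_scope: str = "fold"
    importance_modes: tuple[str, ...] = ()
    lasso_n_alphas: int = 30
    lasso_inner_cv: int = 5
    gbt_n_estimators: int = 100
    gbt_max_depth: int = 4
    gbt_learning_rate: float = 0.1
    gbt_subsample: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "importance_modes", tuple(self.importance_modes))
        if self.k < 2:
            raise ParameterError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ParameterError(f"repeats must be >= 1, got {self.repeats}")
        if self.model not in ("lasso", "gbt"):
            raise ParameterError(f"model must be 'lasso' or 'gbt', got {self.model!r}")
        if self.screen_scope not in ("fold", "global"):
            raise ParameterError("screen_scope must be 'fold' or 'global'")
        bad = set(self.importance_modes) - {"selection", "permutation", "gain"}
        if bad:
            raise ParameterError(f"unknown importance modes {sorted(bad)}")
        if self.model == "lasso" and "gain" in self.importance_modes:
            raise ParameterError("gain importance is only defined for the gbt model")


def _make_learner(cfg: CVConfig, seed: int):
    if cfg.model == "lasso":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lasso",
                    LassoCV(
                        alphas=cfg.lasso_n_alphas,
                        cv=cfg.lasso_inner_cv,
                        random_state=seed,
                        max_iter=5000,
                    ),
                ),
            ]
        )
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=cfg.gbt_n_estimators,
        max_depth=cfg.gbt_max_depth,
        learning_rate=cfg.gbt_learning_rate,
        subsample=cfg.gbt_subsample,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )


def _safe_pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    # a degenerate (constant) prediction carries no linear signal
    if np.std(pred) == 0 or np.std(truth) == 0:
        return 0.0
    return float(stats.pearsonr(pred, truth)[0])


def _nonzero_coefs(fitted) -> np.ndarray:
    return fitted.named_steps["lasso"].coef_ != 0


def importance(fitted, X_test: pd.DataFrame, y_test, mode: str, rng=None) -> pd.Series:
    """Per-feature importance of one fitted model on one held-out fold.

    "selection"    1 where the lasso kept a nonzero coefficient;
    "permutation"  drop in test r^2 after shuffling each column once;
    "gain"         total split gain per feature from the tree booster.
    """
    y_test = _as_finite(y_test, "y_test")
    if mode == "selection":
        if not isinstance(fitted, Pipeline):
            raise ParameterError("selection importance is only defined for the lasso model")
        return pd.Series(_nonzero_coefs(fitted).astype(int), index=X_test.columns)
    if mode == "permutation":
        rng = rng or np.random.default_rng(0)
        base_pred = np.asarray(fitted.predict(X_test), dtype=float)
        base_r2 = _safe_pearson(base_pred, y_test) ** 2
        out = {}
        for col in X_test.columns:
            Xp = X_test.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            r2 = _safe_pearson(np.asarray(fitted.predict(Xp), dtype=float), y_test) ** 2
            out[col] = base_r2 - r2
        return pd.Series(out)
    if mode == "gain":
        if isinstance(fitted, Pipeline):
            raise ParameterError("gain importance is only defined for the gbt model")
        booster = fitted.get_booster()
        gain = booster.get_score(importance_type="gain")
        names = list(X_test.columns)
        # boosters name features f0, f1, ... in column order
        return pd.Series({c: gain.get(f"f{i}", 0.0) for i, c in enumerate(names)})
    raise ParameterError(f"unknown importance mode {mode!r}")


@dataclass
class CVReport:
    """Outcome of one paired repeated-CV run.

    ``frame`` has one row per fold evaluation (k x repeats rows): the paired
    test Pearson correlations and RMSEs plus a hash of the test indices that
    certifies both models saw the same split.  ``selection_counts`` counts
    lasso nonzero selections of every feature in the with-3D model;
    ``importance_ranks`` maps each requested mode to the features' average
    rank (1 = most important) across iterations.
    """

    config: CVConfig
    with_3d_column: str
    frame: pd.DataFrame
    selection_counts: pd.Series | None = None
    importance_ranks: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def n_evaluations(self) -> int:
        return len(self.frame)

    @property
    def signed_rank_p(self) -> float:
        return paired_signed_rank(self.frame["r_with"], self.frame["r_without"])

    @property
    def mean_r2_with(self) -> float:
        return float((self.frame["r_with"] ** 2).mean())

    @property
    def mean_r2_without(self) -> float:
        return float((self.frame["r_without"] ** 2).mean())

    @property
    def relative_r2_change(self) -> float:
        """(mean r2_with - mean r2_without) / mean r2_without."""
        base = self.mean_r2_without
        return float("nan") if base == 0 else (self.mean_r2_with - base) / base

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary_dict(self) -> dict:
        try:
            p = self.signed_rank_p
        except InputError:  # fewer than 6 paired evaluations
            p = None
        return {
            "model": self.config.model,
            "k": self.config.k,
            "repeats": self.config.repeats,
            "n_evaluations": self.n_evaluations,
            "with_3d_column": self.with_3d_column,
            "mean_r_with": float(self.frame["r_with"].mean()),
            "mean_r_without": float(self.frame["r_without"].mean()),
            "mean_rmse_with": float(self.frame["rmse_with"].mean()),
            "mean_rmse_without": float(self.frame["rmse_without"].mean()),
            "mean_r2_with": self.mean_r2_with,
            "mean_r2_without": self.mean_r2_without,
            "relative_r2_change": self.relative_r2_change,
            "signed_rank_p": p,
            "seed": self.config.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def _fold_hash(test_idx: np.ndarray) -> str:
    return hashlib.sha1(np.sort(test_idx).astype(np.int64).tobytes()).hexdigest()[:12]


def _screen_columns(X: pd.DataFrame, y: np.ndarray, keep: int, exclude: str) -> list[str]:
    cand = [c for c in X.columns if c != exclude]
    M = X[cand].to_numpy(dtype=float)
    Mc = M - M.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Mc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    scores = dict(zip(cand, np.abs(r)))
    ranked = sorted(cand, key=lambda c: (-scores[c], c))
    return ranked[:keep]


def repeated_cv(fm: pd.DataFrame, cfg: CVConfig, with_3d_column: str) -> CVReport:
    """Paired with/without-3D repeated k-fold cross-validation.

    ``fm`` is an assembled feature matrix whose last column is the
    ``efficiency`` response and which contains ``with_3d_column``.  Within
    each fold the learner is trained twice on identical train/test splits —
    once on the classic columns, once with the single 3D column added — and
    the held-out Pearson correlation and RMSE are recorded for both.
    """
    if with_3d_column not in fm.columns:
        raise ParameterError(f"feature matrix lacks the 3D column {with_3d_column!r}")
    if "efficiency" not in fm.columns:
        raise InputError("feature matrix must carry an 'efficiency' response column")
    y_all = _as_finite(fm["efficiency"].to_numpy(), "efficiency")
    X_all = fm.drop(columns=["efficiency"])
    if not np.all(np.isfinite(X_all.to_numpy(dtype=float))):
        raise InputError("feature matrix contains non-finite values")
    if len(fm) < 5 * cfg.k:
        raise InputError(f"need at least {5 * cfg.k} sites for {cfg.k}-fold CV")

    global_keep: list[str] | None = None
    if cfg.feature_screen is not None and cfg.screen_scope == "global":
        global_keep = _screen_columns(X_all, y_all, cfg.feature_screen, with_3d_column)

    rows = []
    sel_counts = pd.Series(0, index=X_all.columns, dtype=int)
    rank_sums: dict[str, pd.Series] = {m: None for m in cfg.importance_modes}
    rank_counts: dict[str, pd.Series] = {m: None for m in cfg.importance_modes}
    for rep in range(cfg.repeats):
        rep_seed = cfg.seed * 100003 + rep
        splitter = KFold(n_splits=cfg.k, shuffle=True, random_state=rep_seed % (2**31))
        for fold, (tr, te) in enumerate(splitter.split(X_all)):
            if cfg.feature_screen is None:
                keep = [c for c in X_all.columns if c != with_3d_column]
            elif global_keep is not None:
                keep = global_keep
            else:
                keep = _screen_columns(
                    X_all.iloc[tr], y_all[tr], cfg.feature_screen, with_3d_column
                )
            cols_without = keep
            cols_with = keep + [with_3d_column]
            it_seed = (rep_seed * 1009 + fold) % (2**31)
            row = {
                "repeat": rep,
                "fold": fold,
                "fold_hash": _fold_hash(te),
                "n_test": len(te),
            }
            fit_with = None
            for tag, cols in (("without", cols_without), ("with", cols_with)):
                Xtr, Xte = X_all.iloc[tr][cols], X_all.iloc[te][cols]
                learner = _make_learner(cfg, it_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    learner.fit(Xtr, y_all[tr])
                pred = np.asarray(learner.predict(Xte), dtype=float)
                row[f"r_{tag}"] = _safe_pearson(pred, y_all[te])
                row[f"rmse_{tag}"] = float(np.sqrt(np.mean((pred - y_all[te]) ** 2)))
                if tag == "with":
                    fit_with = learner
            rows.append(row)
            if cfg.model == "lasso":
                nz = _nonzero_coefs(fit_with)
                sel_counts.loc[cols_with] += nz.astype(int)
            if cfg.importance_modes:
                Xte_with = X_all.iloc[te][cols_with]
                rng = np.random.default_rng(it_seed)
                for mode in cfg.importance_modes:
                    imp = importance(fit_with, Xte_with, y_all[te], mode, rng=rng)
                    ranks = imp.rank(ascending=False, method="average")
                    ones = pd.Series(1, index=ranks.index)
                    if rank_sums[mode] is None:
                        rank_sums[mode], rank_counts[mode] = ranks, ones
                    else:
                        rank_sums[mode] = rank_sums[mode].add(ranks, fill_value=0)
                        rank_counts[mode] = rank_counts[mode].add(ones, fill_value=0)

    report = CVReport(
        config=cfg,
        with_3d_column=with_3d_column,
        frame=pd.DataFrame(rows),
        selection_counts=sel_counts if cfg.model == "lasso" else None,
        # average rank over the iterations in which a feature was in play
        importance_ranks={
            m: (s / rank_counts[m]).sort_values()
            for m, s in rank_sums.items()
            if s is not None
        },
    )
    return report


# ----------------------------------------------------------- model / results


class DensityEfficiencyModel:
    """Association model between a 3D density feature and CRISPR efficiency.

    Parameters
    ----------
    features : DataFrame
        Assembled site-by-feature matrix (classic features, optional
        epigenetic columns, exactly one 3D density column, and an
        ``efficiency`` response), e.g. from :func:`crispr3d.targets.assemble`.
    density_feature : str
        Name of the 3D column under evaluation.
    """

    def __init__(self, features: pd.DataFrame, density_feature: str):
        if density_feature not in features.columns:
            raise ParameterError(f"features lack the density column {density_feature!r}")
        if "efficiency" not in features.columns:
            raise InputError("features must carry an 'efficiency' column")
        if len(features) < 10:
            raise InputError("need at least 10 sites")
        self.features = features
        self.density_feature = density_feature

    @classmethod
    def from_sites(
        cls, sites, bin_features, density_feature: str, tracks=None, window: int = 500
    ) -> "DensityEfficiencyModel":
        from .targets import assemble

        fm = assemble(
            sites, bin_features, include_3d=density_feature, tracks=tracks, window=window
        )
        return cls(fm, density_feature)

    def fit(
        self, config: CVConfig = CVConfig(), quintile: float = 0.2, run_cv: bool = True
    ) -> "DensityEfficiencyResults":
        dens = self.features[self.density_feature].to_numpy(dtype=float)
        eff = self.features["efficiency"].to_numpy(dtype=float)
        pear = correlate(dens, eff, "pearson")
        spear = correlate(dens, eff, "spearman")
        contrast = quintile_contrast(dens, eff, q=quintile)
        gc = self.features["freq_G"].to_numpy() + self.features["freq_C"].to_numpy()
        partial_gc = partial_correlation(dens, eff, controls=[gc])
        cv = repeated_cv(self.features, config, self.density_feature) if run_cv else None
        return DensityEfficiencyResults(
            model=self,
            pearson=pear,
            spearman=spear,
            partial_vs_gc=partial_gc,
            quintile=contrast,
            quintile_q=quintile,
            cv_report=cv,
        )


@dataclass
class DensityEfficiencyResults:
    """Fitted association results; ``summary()`` renders the headline table."""

    model: DensityEfficiencyModel
    pearson: tuple[float, float]
    spearman: tuple[float, float]
    partial_vs_gc: float
    quintile: tuple[float, float, int]
    quintile_q: float
    cv_report: CVReport | None

    def summary(self) -> str:
        m = self.model
        lines = [
            "Density-efficiency association".center(60),
            "=" * 60,
            f"{'Sites':<34}{len(m.features):>26}",
            f"{'Density feature':<34}{m.density_feature:>26}",
            f"{'Pearson r (p)':<34}{self.pearson[0]:>14.4f} ({self.pearson[1]:.2e})",
            f"{'Spearman rho (p)':<34}{self.spearman[0]:>14.4f} ({self.spearman[1]:.2e})",
            f"{'Partial r | GC':<34}{self.partial_vs_gc:>26.4f}",
        ]
        stat, p, direction = self.quintile
        arrow = {1: "higher", -1: "lower", 0: "equal"}[direction]
        lines += [
            f"Top vs bottom {self.quintile_q:.0%} efficiency: feature {arrow} in top "
            f"(rank-sum p = {p:.2e})",
        ]
        if self.cv_report is not None:
            s = self.cv_report.summary_dict()
            lines += [
                "-" * 60,
                f"{'CV protocol':<34}{s['repeats']}x{s['k']}-fold, {s['model']:>10}",
                f"{'Paired evaluations':<34}{s['n_evaluations']:>26}",
                f"{'Mean test r with / without 3D':<34}"
                f"{s['mean_r_with']:>12.4f} /{s['mean_r_without']:>10.4f}",
                f"{'Mean RMSE with / without 3D':<34}"
                f"{s['mean_rmse_with']:>12.4f} /{s['mean_rmse_without']:>10.4f}",
                f"{'Relative r2 change':<34}{s['relative_r2_change']:>25.1%}",
                f"{'Signed-rank p (r with vs without)':<34}"
                + (f"{s['signed_rank_p']:>26.2e}" if s["signed_rank_p"] is not None
                   else f"{'n/a':>26}"),
            ]
        lines.append("=" * 60)
        return "\n".join(lines)
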