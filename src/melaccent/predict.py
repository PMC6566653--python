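"""Regression models of perceived accent and their cross-validated evaluation.

Two models predict the per-note mean rating from the feature matrix: ordinary
multiple linear regression (MLR) on standardized predictors, reported with
standardized betas, semipartial correlations and t-test p-values; and
epsilon-SVR with an RBF kernel, with C and gamma chosen by grid search.
Model quality is the squared Pearson correlation R² between observed and
predicted ratings, estimated by k-fold cross-validation averaged over random
repetitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "PredictError",
    "RegressionResult",
    "SvrConfig",
    "CvResult",
    "r_squared",
    "accent_misplacement_r2",
    "fit_mlr",
    "fit_svr",
    "grid_search_svr",
    "cross_validate",
]


class PredictError(ValueError):
    pass


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted values
    (the explained-variance measure used for model comparison)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 3:
        raise PredictError("r_squared needs two equal-length vectors of length >= 3")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise PredictError("r_squared undefined for a constant vector")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def variance_ratio_r2(y, yhat) -> float:
    """1 - SSE/SStot; can be negative for out-of-fold predictions worse than
    the mean.  Used for the per-rater reports."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise PredictError("variance-ratio R2 undefined for constant y")
    return 1.0 - float(((y - yhat) ** 2).sum()) / sstot


def accent_misplacement_r2(n_notes: int, n_accents: int, n_misplaced: int) -> float:
    """R² between a binary accent pattern and the same pattern with some
    accents moved to previously unaccented notes.

    Quantifies how strongly single misplaced accents depress the squared
    correlation: for a 70-note melody with 15 accents, moving one accent
    drops R² from 1 to about 0.84 — a 16% loss for one wrong note.
    """
    if not (0 <= n_misplaced <= n_accents <= n_notes):
        raise PredictError("need 0 <= n_misplaced <= n_accents <= n_notes")
    if n_accents + n_misplaced > n_notes:
        raise PredictError("not enough unaccented notes to receive the moved accents")
    truth = np.zeros(n_notes)
    truth[:n_accents] = 1
    pred = truth.copy()
    pred[:n_misplaced] = 0
    pred[n_accents:n_accents + n_misplaced] = 1
    return r_squared(truth, pred)


@dataclass
class RegressionResult:
    """OLS fit summary on standardized predictors and response."""

    feature_names: list[str]
    beta: np.ndarray            # standardized coefficients
    sr: np.ndarray              # semipartial correlations (sign of beta)
    p_values: np.ndarray        # two-sided t-test p-values
    intercept: float
    r2: float                   # training R^2
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "sr": self.sr, "p": self.p_values},
            index=self.feature_names,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.feature_names,
                "beta": self.beta.tolist(),
                "sr": self.sr.tolist(),
                "p": self.p_values.tolist(),
                "intercept": self.intercept,
                "r2": self.r2,
                "n": self.n,
            },
            indent=1,
        )


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def fit_mlr(X: pd.DataFrame | np.ndarray, y) -> RegressionResult:
    """OLS on z-scored predictors and response.

    The standardized coefficients are the betas; each feature's semipartial
    correlation sr satisfies sr² = R²(full) − R²(without that feature) and is
    computed from its t statistic; p-values are two-sided with
    df = n − p − 1.  Exactly collinear columns raise, naming the offenders.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if len(yv) != n:
        raise PredictError("X and y row counts differ")
    if n <= p + 1:
        raise PredictError(f"need n > p + 1 (n={n}, p={p})")
    if np.std(yv) == 0:
        raise PredictError("constant response")
    Z = _standardize(Xv)
    zy = _standardize(yv.reshape(-1, 1)).ravel()
    design = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # name the columns involved in exact collinearity
        bad = []
        seen: list[int] = []
        for j in range(p):
            cols = seen + [j]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n)] + [Z[:, c] for c in cols])) < len(cols) + 1:
                bad.append(names[j])
            else:
                seen.append(j)
        raise PredictError(f"collinear feature columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(design, zy, rcond=None)
    yhat = design @ coef
    resid = zy - yhat
    df_res = n - p - 1
    sse = float(resid @ resid)
    r2_train = 1.0 - sse / float(((zy - zy.mean()) ** 2).sum())
    sigma2 = sse / df_res
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = coef / se
    p_two = 2 * stats.t.sf(np.abs(t[1:]), df_res)
    # sr_i = t_i * sqrt((1 - R^2) / df_res)
    sr = t[1:] * math.sqrt(max(0.0, 1.0 - r2_train) / df_res)
    return RegressionResult(
        feature_names=names,
        beta=coef[1:],
        sr=sr,
        p_values=p_two,
        intercept=float(coef[0]),
        r2=r2_train,
        n=n,
    )


def mlr_predictor(X: pd.DataFrame | np.ndarray, y):
    """Fit OLS (with intercept, on raw scales) and return a predict callable."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(Xv)), Xv])
    coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)

    def predict(Xnew):
        Xn = np.asarray(Xnew, dtype=float)
        return np.column_stack([np.ones(len(Xn)), Xn]) @ coef

    return predict


@dataclass
class SvrConfig:
    """epsilon-SVR hyperparameters and the C/gamma search grid.

    Defaults follow common RBF-SVR practice: coarse powers of 4 over
    C in 2^-5..2^15 and gamma in 2^-15..2^3, epsilon 0.1, predictors
    z-scored before the kernel.
    """

    c_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 4))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 4))
    epsilon: float = 0.1
    standardize: bool = True
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise PredictError("SVR grids must be non-empty")
        if self.epsilon <= 0:
            raise PredictError("epsilon must be > 0")


def _make_svr(c: float, gamma: float, config: SvrConfig):
    svr = SVR(kernel="rbf", C=c, gamma=gamma, epsilon=config.epsilon)
    if config.standardize:
        return Pipeline([("scale", StandardScaler()), ("svr", svr)])
    return svr


def grid_search_svr(X, y, config: SvrConfig, seed: int = 0) -> tuple[float, float]:
    """Choose (C, gamma) minimizing inner-CV mean squared error."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    kf = KFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    best = (math.inf, config.c_grid[0], config.gamma_grid[0])
    for c in config.c_grid:
        for g in config.gamma_grid:
            sse = 0.0
            for tr, te in splits:
                model = _make_svr(c, g, config)
                model.fit(Xv[tr], yv[tr])
                err = yv[te] - model.predict(Xv[te])
                sse += float(err @ err)
            if sse < best[0]:
                best = (sse, c, g)
    return best[1], best[2]


def fit_svr(X, y, config: SvrConfig | None = None, seed: int = 0):
    """epsilon-SVR with RBF kernel; C and gamma from an inner grid search.
    Returns a fitted model exposing ``predict``."""
    config = config or SvrConfig()
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(np.unique(yv)) == 1:
        raise PredictError("constant response")
    c, g = grid_search_svr(Xv, yv, config, seed=seed)
    model = _make_svr(c, g, config)
    model.fit(Xv, yv)
    return model


@dataclass
class CvResult:
    """Repeated k-fold cross-validation summary."""

    method: str
    k: int
    reps: int
    seed: int
    per_rep_r2: list[float]
    oof_predictions: np.ndarray  # reps x n out-of-fold predictions
    r2_convention: str = "squared_correlation"
    svr_params: tuple[float, float] | None = None

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_rep_r2))

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "k": self.k,
                "reps": self.reps,
                "seed": self.seed,
                "per_rep_r2": self.per_rep_r2,
                "mean_r2": self.mean_r2,
                "r2_convention": self.r2_convention,
                "svr_params": list(self.svr_params) if self.svr_params else None,
            },
            indent=1,
        )


def cross_validate(
    X,
    y,
    method: str = "mlr",
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    svr_config: SvrConfig | None = None,
    r2_convention: str = "squared_correlation",
) -> CvResult:
    """Repeated k-fold CV: per repetition, a fresh random partition of the
    notes; out-of-fold predictions pooled over all notes give one R² per
    repetition, and the mean over repetitions is the reported score.

    For SVR, (C, gamma) are grid-searched once on the full data and reused
    across folds, keeping the repeated 10x10 protocol tractable.
    Fully reproducible from ``seed``.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 2 * k:
        raise PredictError(f"need n >= 2k for {k}-fold CV (n={n})")
    if method not in ("mlr", "svr"):
        raise PredictError(f"unknown method {method!r}")

    svr_params = None
    if method == "svr":
        cfg = svr_config or SvrConfig()
        svr_params = grid_search_svr(Xv, yv, cfg, seed=seed)
        one_point = SvrConfig(
            c_grid=(svr_params[0],), gamma_grid=(svr_params[1],),
            epsilon=cfg.epsilon, standardize=cfg.standardize,
            inner_folds=cfg.inner_folds,
        )

    score = r_squared if r2_convention == "squared_correlation" else variance_ratio_r2
    rng = np.random.default_rng(seed)
    per_rep: list[float] = []
    oof_all = np.empty((reps, n))
    for rep in range(reps):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        oof = np.empty(n)
        for tr, te in kf.split(Xv):
            if method == "mlr":
                predict = mlr_predictor(Xv[tr], yv[tr])
            else:
                model = _make_svr(svr_params[0], svr_params[1], one_point)
                model.fit(Xv[tr], yv[tr])
                predict = model.predict
            oof[te] = predict(Xv[te])
        per_rep.append(score(yv, oof))
        oof_all[rep] = oof
    return CvResult(
        method=method,
        k=k,
        reps=reps,
        seed=seed,
        per_rep_r2=per_rep,
        oof_predictions=oof_all,
        r2_convention=r2_convention,
        svr_params=svr_params,
    )
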