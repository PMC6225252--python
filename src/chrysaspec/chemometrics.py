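"""Sample-set splitting and the two regression engines (PLS, LS-SVM).

Both regressors are scikit-learn style estimators that select their
hyperparameters by cross-validation on the calibration set:

* :class:`PLSRegressor` — partial least squares on mean-centered
  spectra; the number of latent variables (LVs) is chosen to minimise
  the cross-validated RMSE (leave-one-out by default).
* :class:`LSSVMRegressor` — least-squares support vector machine with
  an RBF kernel ``K(xi, xj) = exp(-||xi - xj||^2 / sigma2)``.  Training
  solves the single KKT linear system

      [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y],

  and prediction is ``yhat(x) = sum_i alpha_i K(x, x_i) + b``.  The
  (gamma, sigma2) pair is picked by a two-stage grid search (coarse
  log-spaced grid, then a finer grid around the coarse optimum).
  Leave-one-out residuals come from the closed form
  ``r_i = alpha_i / (A^{-1})_{ii}`` on the inverse KKT matrix, making
  LOO essentially free per grid point.

The calibration/prediction split follows the content-rank rule: sort
samples by reference value; in each consecutive triple, the first and
third go to calibration and the middle one to prediction; leftovers go
to calibration.  279 samples therefore split 186 / 93.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SpectralDataset",
    "rank_split",
    "PLSRegressor",
    "LSSVMRegressor",
    "fit_pls",
    "fit_lssvm",
    "predict",
    "save_model",
    "load_model",
]

CALIBRATION = "calibration"
PREDICTION = "prediction"


@dataclass
class SpectralDataset:
    """Preprocessed mean spectra paired with reference chemistry."""

    X: np.ndarray              # (n_samples, n_bands)
    y: np.ndarray              # (n_samples,) % w/w
    set_labels: np.ndarray     # "calibration" / "prediction"
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        self.set_labels = np.asarray(self.set_labels)
        if len(self.X) != len(self.y) or len(self.y) != len(self.set_labels):
            raise ValueError("X, y and set_labels must align")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing values are not allowed")

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.set_labels == label
        return self.X[m], self.y[m]

    @property
    def calibration(self):
        return self.subset(CALIBRATION)

    @property
    def prediction(self):
        return self.subset(PREDICTION)


def rank_split(y) -> np.ndarray:
    """Content-ranked calibration/prediction split.

    Samples are sorted ascending by ``y`` (stable, so ties keep their
    original order); within each consecutive triple of ranks the first
    and third samples go to the calibration set and the second to the
    prediction set; any leftover (n mod 3) samples go to calibration.
    Returns an array of "calibration"/"prediction" labels aligned with
    ``y``; always |calibration| = 2*floor(n/3) + n mod 3.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("rank_split needs at least 3 samples")
    order = np.argsort(y, kind="stable")
    labels = np.full(n, CALIBRATION, dtype=object)
    for t in range(n // 3):
        labels[order[3 * t + 1]] = PREDICTION
    return labels.astype(str)


def _cv_folds(cv, n: int):
    if cv in (None, "loo"):
        return list(LeaveOneOut().split(np.empty(n)))
    k = int(cv)
    if not 2 <= k <= n:
        raise ValueError("k-fold cv requires 2 <= k <= n")
    return list(KFold(n_splits=k, shuffle=False).split(np.empty(n)))


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _r2(y, yhat) -> float:
    """Internal diagnostic R^2; NaN on degenerate (constant/single) y."""
    y = np.asarray(y, float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or np.isnan(yhat).any():
        return float("nan")
    return 1.0 - float(np.sum((y - np.asarray(yhat)) ** 2)) / ss_tot


def _pls_coef_path(pls: PLSRegression, max_k: int):
    """Cumulative regression coefficients for 1..max_k latent variables.

    NIPALS deflation makes the fitted regression additive per
    component, so coefficients for k LVs are built from the first k
    columns of the rotations and response loadings of one max_k fit.
    Returns (coefs[k-1] of shape (p,), intercepts[k-1]).
    """
    W = pls.x_rotations_            # (p, max_k)
    Q = pls.y_loadings_             # (1, max_k)
    x_mean = pls._x_mean
    # sklearn's intercept_ is the response mean (X is centered inside
    # its predict); the path below folds the centering into intercepts.
    y_mean = float(np.atleast_1d(pls.intercept_)[0])
    coefs, intercepts = [], []
    for k in range(1, max_k + 1):
        b = (W[:, :k] @ Q[:, :k].T).reshape(-1)
        coefs.append(b)
        intercepts.append(float(y_mean - x_mean @ b))
    return np.array(coefs), np.array(intercepts)


class PLSRegressor(RegressorMixin, BaseEstimator):
    """PLS regression with cross-validated latent-variable selection.

    Spectra are mean-centered (no per-band autoscaling, the usual
    chemometric convention for reflectance spectra).  All candidate LV
    counts 1..max_lvs are scored in one pass per CV fold via the
    cumulative-coefficient path, and the count minimising RMSECV wins
    (smallest count on ties).

    Parameters
    ----------
    max_lvs : upper bound on latent variables (clipped to the data rank
        and fold size; a warning is raised if clipping bites).
    cv : "loo" (default) or an integer k for k-fold.

    Attributes
    ----------
    n_lvs_ : selected number of latent variables.
    rmsec_, r2c_ : calibration-set diagnostics.
    rmsecv_, r2cv_ : cross-validation diagnostics at the selected count.
    cv_rmse_per_lv_ : RMSECV for each candidate count.
    """

    def __init__(self, max_lvs: int = 20, cv="loo"):
        self.max_lvs = max_lvs
        self.cv = cv

    def _fit_base(self, X, y, k):
        m = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X, y)
        return m

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        folds = _cv_folds(self.cv, n)
        min_train = min(len(tr) for tr, _ in folds)
        rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
        max_k = min(self.max_lvs, p, min_train - 1, rank)
        if max_k < 1:
            raise ValueError("not enough samples/rank for even one LV")
        if max_k < self.max_lvs:
            warnings.warn(
                f"max_lvs reduced from {self.max_lvs} to {max_k} "
                "(limited by data rank or fold size)", UserWarning)

        press = np.zeros(max_k)
        cv_pred = np.zeros((max_k, n))
        for tr, te in folds:
            m = self._fit_base(X[tr], y[tr], max_k)
            coefs, icpts = _pls_coef_path(m, max_k)
            pred = X[te] @ coefs.T + icpts  # (n_te, max_k)
            cv_pred[:, te] = pred.T
            press += ((pred - y[te, None]) ** 2).sum(axis=0)
        rmsecv = np.sqrt(press / n)
        best = int(np.argmin(rmsecv))  # first minimum -> smallest count

        self.n_lvs_ = best + 1
        self.cv_rmse_per_lv_ = rmsecv
        self.rmsecv_ = float(rmsecv[best])
        self.r2cv_ = _r2(y, cv_pred[best])
        self.model_ = self._fit_base(X, y, self.n_lvs_)
        yc = self.model_.predict(X).ravel()
        self.rmsec_ = _rmse(y, yc)
        self.r2c_ = _r2(y, yc)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} bands, model was trained with "
                f"{self.n_features_in_}")
        return self.model_.predict(X).ravel()


def _rbf_kernel(sqdist: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-sqdist / sigma2)


def _solve_lssvm_system(K: np.ndarray, y: np.ndarray, gamma: float):
    """Solve the LS-SVM KKT system; returns (b, alpha, loo_residuals).

    The leave-one-out residual of sample i is ``alpha_i / (A^{-1})_{ii}``
    where A is the KKT matrix — the classical closed form that avoids n
    refits.
    """
    n = y.size
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular LS-SVM system at gamma={gamma}") from exc
    sol = A_inv @ np.concatenate(([0.0], y))
    b, alpha = float(sol[0]), sol[1:]
    # undefined for n = 1 (nothing to leave out): NaN, not a crash
    with np.errstate(divide="ignore", invalid="ignore"):
        loo_resid = alpha / np.diag(A_inv)[1:]
    return b, alpha, loo_resid


class LSSVMRegressor(RegressorMixin, BaseEstimator):
    """LS-SVM regression with RBF kernel and two-stage grid search.

    When ``gamma`` and ``sigma2`` are given, the model is fitted
    directly.  Otherwise a coarse log-spaced grid (gamma 1e0..1e7,
    sigma2 1e0..1e5, 10 x 10 by default) is scored by cross-validated
    RMSE, then a 5 x 5 refinement spanning one coarse step around the
    optimum is scored, and the overall best pair is refitted on all
    calibration data.  With LOO (the default) the residuals come from
    the closed-form inverse-KKT identity; with k-fold each fold is
    refitted.

    Attributes: ``gamma_``, ``sigma2_``, ``alpha_``, ``b_``,
    ``rmsec_``, ``r2c_``, ``rmsecv_``, ``r2cv_``, ``cv_results_``.
    """

    def __init__(self, gamma: float | None = None,
                 sigma2: float | None = None,
                 gamma_grid=None, sigma2_grid=None,
                 refine: bool = True, cv="loo"):
        self.gamma = gamma
        self.sigma2 = sigma2
        self.gamma_grid = gamma_grid
        self.sigma2_grid = sigma2_grid
        self.refine = refine
        self.cv = cv

    # -- internal scoring -------------------------------------------------
    def _loo_score(self, sqdist, y, gamma, sigma2):
        K = _rbf_kernel(sqdist, sigma2)
        _, _, resid = _solve_lssvm_system(K, y, gamma)
        return float(np.sqrt(np.mean(resid ** 2))), y - resid

    def _kfold_score(self, X, y, gamma, sigma2, folds):
        pred = np.empty_like(y)
        for tr, te in folds:
            sq = cdist(X[tr], X[tr], "sqeuclidean")
            K = _rbf_kernel(sq, sigma2)
            b, alpha, _ = _solve_lssvm_system(K, y[tr], gamma)
            K_te = _rbf_kernel(cdist(X[te], X[tr], "sqeuclidean"), sigma2)
            pred[te] = K_te @ alpha + b
        return _rmse(y, pred), pred

    def _score_grid(self, X, y, sqdist, pairs, folds):
        rows = []
        for gamma, sigma2 in pairs:
            if gamma <= 0 or sigma2 <= 0:
                raise ValueError("grid candidates must be positive")
            if folds is None:
                rmsecv, cv_pred = self._loo_score(sqdist, y, gamma, sigma2)
            else:
                rmsecv, cv_pred = self._kfold_score(X, y, gamma, sigma2, folds)
            rows.append({"gamma": gamma, "sigma2": sigma2,
                         "rmsecv": rmsecv, "_pred": cv_pred})
        return rows

    @staticmethod
    def _refine_grid(center: float, log_step: float, n: int = 5) -> np.ndarray:
        lo = np.log10(center) - log_step
        return np.logspace(lo, lo + 2 * log_step, n)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n = len(y)
        folds = None if self.cv in (None, "loo") else _cv_folds(self.cv, n)
        sqdist = cdist(X, X, "sqeuclidean")

        if self.gamma is not None and self.sigma2 is not None:
            rows = self._score_grid(X, y, sqdist,
                                    [(float(self.gamma), float(self.sigma2))],
                                    folds)
        else:
            g_grid = (np.asarray(self.gamma_grid, float)
                      if self.gamma_grid is not None
                      else np.logspace(0, 7, 10))
            s_grid = (np.asarray(self.sigma2_grid, float)
                      if self.sigma2_grid is not None
                      else np.logspace(0, 5, 10))
            pairs = [(g, s) for g in g_grid for s in s_grid]
            rows = self._score_grid(X, y, sqdist, pairs, folds)
            if self.refine:
                best = min(rows, key=lambda r: r["rmsecv"])
                g_step = np.diff(np.log10(g_grid)).mean() if len(g_grid) > 1 else 0.5
                s_step = np.diff(np.log10(s_grid)).mean() if len(s_grid) > 1 else 0.5
                pairs = [(g, s)
                         for g in self._refine_grid(best["gamma"], g_step)
                         for s in self._refine_grid(best["sigma2"], s_step)]
                rows += self._score_grid(X, y, sqdist, pairs, folds)

        best = min(rows, key=lambda r: r["rmsecv"])  # stable: first minimum
        self.gamma_ = float(best["gamma"])
        self.sigma2_ = float(best["sigma2"])
        self.rmsecv_ = float(best["rmsecv"])
        self.r2cv_ = _r2(y, best["_pred"])
        self.cv_results_ = pd.DataFrame(
            [{k: v for k, v in r.items() if not k.startswith("_")}
             for r in rows])

        K = _rbf_kernel(sqdist, self.sigma2_)
        self.b_, self.alpha_, _ = _solve_lssvm_system(K, y, self.gamma_)
        self.X_fit_ = X
        yc = K @ self.alpha_ + self.b_
        self.rmsec_ = _rmse(y, yc)
        self.r2c_ = _r2(y, yc)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} bands, model was trained with "
                f"{self.n_features_in_}")
        K = _rbf_kernel(cdist(X, self.X_fit_, "sqeuclidean"), self.sigma2_)
        return K @ self.alpha_ + self.b_


# -- thin functional wrappers ---------------------------------------------

def fit_pls(X, y, max_lvs: int = 20, cv="loo") -> PLSRegressor:
    return PLSRegressor(max_lvs=max_lvs, cv=cv).fit(X, y)


def fit_lssvm(X, y, gamma_grid=None, sigma2_grid=None,
              cv="loo", refine: bool = True) -> LSSVMRegressor:
    return LSSVMRegressor(gamma_grid=gamma_grid, sigma2_grid=sigma2_grid,
                          cv=cv, refine=refine).fit(X, y)


def predict(model, X_new) -> np.ndarray:
    return model.predict(X_new)


# -- model serialization (documented JSON container) ----------------------

def save_model(model, path: str) -> str:
    """Serialize a fitted PLS or LS-SVM model to a JSON container."""
    if isinstance(model, PLSRegressor):
        coef = model.model_.coef_.reshape(-1)
        # fold sklearn's internal X-centering into a plain intercept
        intercept = (float(np.atleast_1d(model.model_.intercept_)[0])
                     - float(model.model_._x_mean @ coef))
        payload = {
            "family": "pls",
            "n_lvs": model.n_lvs_,
            "coef": coef.tolist(),
            "intercept": intercept,
            "diagnostics": {"rmsec": model.rmsec_, "r2c": model.r2c_,
                            "rmsecv": model.rmsecv_, "r2cv": model.r2cv_},
        }
    elif isinstance(model, LSSVMRegressor):
        payload = {
            "family": "lssvm",
            "gamma": model.gamma_,
            "sigma2": model.sigma2_,
            "alpha": model.alpha_.tolist(),
            "b": model.b_,
            "X_fit": model.X_fit_.tolist(),
            "diagnostics": {"rmsec": model.rmsec_, "r2c": model.r2c_,
                            "rmsecv": model.rmsecv_, "r2cv": model.r2cv_},
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


class _LinearPredictor:
    """Deserialized PLS model reduced to its linear predictor."""

    def __init__(self, coef, intercept, diagnostics):
        self.coef = np.asarray(coef, float)
        self.intercept = float(intercept)
        self.diagnostics = diagnostics

    def predict(self, X):
        return np.asarray(X, float) @ self.coef + self.intercept


def load_model(path: str):
    """Load a model saved by :func:`save_model`.

    PLS models come back as a bare linear predictor; LS-SVM models are
    reconstructed as fitted :class:`LSSVMRegressor` instances.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if payload["family"] == "pls":
        return _LinearPredictor(payload["coef"], payload["intercept"],
                                payload["diagnostics"])
    m = LSSVMRegressor(gamma=payload["gamma"], sigma2=payload["sigma2"])
    m.gamma_ = payload["gamma"]
    m.sigma2_ = payload["sigma2"]
    m.alpha_ = np.asarray(payload["alpha"], float)
    m.b_ = float(payload["b"])
    m.X_fit_ = np.asarray(payload["X_fit"], float)
    m.n_features_in_ = m.X_fit_.shape[1]
    for k, v in payload["diagnostics"].items():
        setattr(m, k + "_", v)
    return m
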