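"""Orthogonal projections to latent structures (O-PLS / O-PLS-DA).

O-PLS regresses a single response on a high-dimensional block (NMR
spectra or peak-cluster integrals) after removing response-orthogonal
variation: each orthogonal component captures systematic X-variation
uncorrelated with y, and a single predictive component is then fitted on
the deflated block. Model quality is summarised by R²Y on the training
data and the cross-validated goodness-of-prediction Q²_Ŷ
(1 − PRESS/TSS on held-out predictions, sevenfold by default), whose
empirical significance comes from response-permutation testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold, StratifiedKFold

from .stats import adjust_pvalues

__all__ = [
    "OPLS",
    "PermutationResult",
    "fit_oplsda",
    "cross_validate_q2",
    "permutation_test",
    "mwas_coefficients",
]


def _as_matrix(X):
    """Accept ndarray, DataFrame, FeatureTable or SpectraMatrix."""
    if hasattr(X, "values") and hasattr(X, "metadata"):  # FeatureTable
        return X.values.to_numpy(dtype=float)
    if hasattr(X, "intensities"):  # SpectraMatrix
        return np.asarray(X.intensities, dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _encode_y(y):
    """Continuous y passes through; two-level y becomes −1/+1."""
    y = np.asarray(y)
    if y.dtype.kind in "OUSb" or np.unique(y).size == 2:
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("non-numeric y must have exactly two levels")
        return np.where(y == classes[1], 1.0, -1.0), classes
    return y.astype(float), None


class OPLS(RegressorMixin, BaseEstimator):
    """O-PLS(-DA) with one predictive and ``n_orth`` orthogonal components.

    Parameters
    ----------
    n_orth : int
        Number of response-orthogonal components removed before the
        predictive component.
    scale : {"uv", "center"}
        ``"uv"`` mean-centres and unit-variance scales each column
        (recommended for feature tables); ``"center"`` mean-centres only
        (recommended for full-resolution spectra).

    Attributes
    ----------
    predictive_weights_, predictive_loadings_, predictive_scores_ : ndarray
    orthogonal_weights_, orthogonal_loadings_, orthogonal_scores_ : ndarray
        One column per extracted orthogonal component.
    coef_ : ndarray
        Regression coefficients on the original (unscaled) X columns,
        applied after orthogonal filtering.
    r2y_ : float
        Fraction of response variance explained on the training data.
    """

    def __init__(self, n_orth: int = 1, scale: str = "uv"):
        self.n_orth = n_orth
        self.scale = scale

    def fit(self, X, y):
        X = _as_matrix(X)
        y, self.classes_ = _encode_y(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X rows must match length of y")
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if np.ptp(y) == 0:
            raise ValueError("y is constant")
        if self.scale not in ("uv", "center"):
            raise ValueError("scale must be 'uv' or 'center'")

        self.x_means_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.x_scales_ = (
            np.where(sd > 0, sd, 1.0) if self.scale == "uv" else np.ones(X.shape[1])
        )
        self.y_mean_ = float(y.mean())
        E = (X - self.x_means_) / self.x_scales_
        yc = y - self.y_mean_

        w_os, t_os, p_os = [], [], []
        max_rank = min(E.shape) - 1
        for i in range(self.n_orth):
            w = E.T @ yc
            w_norm = np.linalg.norm(w)
            if w_norm < 1e-12 or len(w_os) >= max_rank:
                warnings.warn(
                    f"orthogonal components truncated at {len(w_os)} (rank exhausted)"
                )
                break
            w /= w_norm
            t = E @ w
            p = E.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-10 * np.linalg.norm(p):
                warnings.warn(
                    f"orthogonal components truncated at {len(w_os)} "
                    "(no response-orthogonal variation left)"
                )
                break
            w_o /= norm
            t_o = E @ w_o
            p_o = E.T @ t_o / (t_o @ t_o)
            E = E - np.outer(t_o, p_o)
            w_os.append(w_o)
            t_os.append(t_o)
            p_os.append(p_o)

        self.orthogonal_weights_ = np.column_stack(w_os) if w_os else np.empty((X.shape[1], 0))
        self.orthogonal_scores_ = np.column_stack(t_os) if t_os else np.empty((X.shape[0], 0))
        self.orthogonal_loadings_ = np.column_stack(p_os) if p_os else np.empty((X.shape[1], 0))

        w = E.T @ yc
        w /= np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q = yc @ t / (t @ t)
        self.predictive_weights_ = w
        self.predictive_scores_ = t
        self.predictive_loadings_ = p
        b_scaled = w * q
        self.coef_ = b_scaled / self.x_scales_
        yhat = t * q + self.y_mean_
        tss = float(yc @ yc)
        self.r2y_ = 1.0 - float(np.sum((y - yhat) ** 2)) / tss
        return self

    def _deflate(self, E):
        for i in range(self.orthogonal_weights_.shape[1]):
            t_o = E @ self.orthogonal_weights_[:, i]
            E = E - np.outer(t_o, self.orthogonal_loadings_[:, i])
        return E

    def predict(self, X):
        X = _as_matrix(X)
        E = self._deflate((X - self.x_means_) / self.x_scales_)
        return E @ (self.coef_ * self.x_scales_) + self.y_mean_

    def transform(self, X):
        """Predictive score t and orthogonal scores for new observations."""
        X = _as_matrix(X)
        E0 = (X - self.x_means_) / self.x_scales_
        t_orth = E0 @ self.orthogonal_weights_
        E = self._deflate(E0)
        t = E @ self.predictive_weights_
        return np.column_stack([t, t_orth]) if t_orth.size else t[:, None]


def fit_oplsda(X, y, n_orth: int = 1, scale: str = "uv") -> OPLS:
    """Fit an O-PLS(-DA) model (binary y is encoded −1/+1 internally)."""
    return OPLS(n_orth=n_orth, scale=scale).fit(X, y)


def _folds(y, n_folds, seed):
    if np.unique(y).size == 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros_like(y), y))
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros_like(y)))


def cross_validate_q2(
    X,
    y,
    n_orth: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    scale: str = "uv",
    return_predictions: bool = False,
):
    """Sevenfold cross-validated Q²_Ŷ = 1 − PRESS/TSS.

    Folds are stratified when y is binary; TSS uses the overall response
    mean. With ``return_predictions=True`` also returns the held-out
    prediction vector from which Q² is computed.
    """
    X = _as_matrix(X)
    y_enc, _ = _encode_y(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    yhat = np.empty_like(y_enc, dtype=float)
    for train, test in _folds(y_enc, n_folds, seed):
        model = OPLS(n_orth=n_orth, scale=scale).fit(X[train], y_enc[train])
        yhat[test] = model.predict(X[test])
    press = float(np.sum((y_enc - yhat) ** 2))
    tss = float(np.sum((y_enc - y_enc.mean()) ** 2))
    q2 = 1.0 - press / tss
    return (q2, yhat) if return_predictions else q2


@dataclass
class PermutationResult:
    """Observed Q² against its response-permutation null."""

    observed_q2: float
    null_q2: np.ndarray
    p_empirical: float

    def __post_init__(self):
        if not 0.0 < self.p_empirical <= 1.0:
            raise ValueError("p_empirical must be in (0, 1]")


def permutation_test(
    X,
    y,
    n_orth: int = 1,
    n_perm: int = 10_000,
    n_folds: int = 7,
    seed: int = 0,
    scale: str = "uv",
) -> PermutationResult:
    """Empirical significance of Q² by random response permutation.

    The full cross-validated Q² is recomputed for ``n_perm`` permutations
    of y; p = (#{null ≥ observed} + 1)/(n_perm + 1), never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _as_matrix(X)
    y_enc, _ = _encode_y(y)
    rng = np.random.default_rng(seed)
    observed = cross_validate_q2(X, y_enc, n_orth, n_folds, seed=seed, scale=scale)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y_enc)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        null[b] = cross_validate_q2(X, y_perm, n_orth, n_folds, seed=fold_seed, scale=scale)
    p = (int(np.sum(null >= observed)) + 1) / (n_perm + 1)
    return PermutationResult(observed_q2=observed, null_q2=null, p_empirical=p)


def mwas_coefficients(
    features,
    y,
    method: str = "pearson",
    fdr_method: str = "bh",
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-cluster association statistics for a Manhattan pseudo-spectrum.

    For every peak cluster: the covariance of the cluster integral with
    y (the circle size of the pseudo-spectrum), the Pearson or Spearman
    correlation with its test p-value, a q-value from ``fdr_method``,
    the association sign, and the significance mask at
    ``p ≤ p_threshold`` (clusters above it are the grey circles).
    Zero-variance clusters are returned flagged with undefined
    statistics.
    """
    if hasattr(features, "values") and hasattr(features, "metadata"):
        table = features.values
        apex = features.metadata["apex_ppm"]
    else:
        table = pd.DataFrame(features)
        apex = pd.Series(np.nan, index=table.columns)
    y = np.asarray(y, dtype=float)
    if len(table) != y.size:
        raise ValueError("feature rows must match length of y")

    rows = []
    for cid in table.columns:
        x = table[cid].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                dict(cluster_id=cid, apex_ppm=float(apex[cid]), covariance_with_y=np.nan,
                     correlation_with_y=np.nan, p_value=np.nan, sign=0, flagged=True)
            )
            continue
        if method == "pearson":
            r, p = sps.pearsonr(x, y)
        elif method == "spearman":
            r, p = sps.spearmanr(x, y)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        cov = float(np.cov(x, y, ddof=0)[0, 1])
        rows.append(
            dict(cluster_id=cid, apex_ppm=float(apex[cid]), covariance_with_y=cov,
                 correlation_with_y=float(r),
                 p_value=max(float(p), np.finfo(float).tiny),
                 sign=int(np.sign(cov)), flagged=False)
        )
    out = pd.DataFrame(rows)
    ok = ~out["flagged"]
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = adjust_pvalues(out.loc[ok, "p_value"].to_numpy(), method=fdr_method)
    out["q_value"] = q
    out["significant"] = ok & (out["p_value"] <= p_threshold)
    return out
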