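"""Cohort stratification and attribution statistics.

Implements the statistical toolbox of the cohort analysis: consensus
choice of k for k-means (elbow + silhouette + gap statistic by majority
vote), k-means stratification with 25 random restarts, probabilistic PCA
tolerant of missing values, forward stepwise rank-transformed regression
scored by AIC, partial Spearman correlations, Storey-q and
Benjamini-Hochberg FDR, normality-gated group comparisons with Tukey or
joint-rank Dunn post hocs, ROUT-style robust outlier screening, glucose
tolerance test summaries, and the two-way adjusted-attribution pattern
(does a correlate survive adjustment for its partner variable?).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PcaResult",
    "StepwiseResult",
    "CorrelationResult",
    "IpgttResult",
    "GroupComparisonReport",
    "AttributionReport",
    "ProbabilisticPCA",
    "choose_k_consensus",
    "kmeans_stratify",
    "stratify_high_low",
    "ppca_scores",
    "stepwise_rank_regression",
    "partial_spearman",
    "adjust_pvalues",
    "dunn_posthoc",
    "group_compare",
    "rout_outliers",
    "ipgtt_summary",
    "adjusted_attribution",
]


# ---------------------------------------------------------------------------
# multiple testing


def adjust_pvalues(p, method: str = "storey_q") -> np.ndarray:
    """FDR-adjust p-values, preserving input order.

    ``storey_q`` estimates the null fraction π₀ with the λ-grid smoother
    (cubic fit of π₀(λ) over λ = 0.05…0.95, evaluated at the largest λ)
    and returns q_i = min_{j≥i} π₀·m·p₍ⱼ₎/j; ``bh`` is the standard
    Benjamini-Hochberg step-up (π₀ = 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey_q":
        raise ValueError("method must be 'storey_q' or 'bh'")
    m = p.size
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if m < 20 or np.all(pi0_l == 0):
        pi0 = 1.0  # too few tests for a stable smoother
    else:
        coeffs = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
        pi0 = min(max(pi0, pi0_l[-1] if pi0 <= 0 else pi0), 1.0)
        if pi0 <= 0:
            pi0 = 1.0
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """A (partial) Spearman correlation with its t-test p-value."""

    rho: float
    p_value: float
    adjusted_for: list = field(default_factory=list)
    n_effective: int = 0
    q_value: float | None = None
    flagged: bool = False  # undefined (constant or collinear input)


def _complete_rows(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a if a.ndim == 1 else a).all(axis=-1) if a.ndim > 1 else np.isfinite(a)
    return mask


def partial_spearman(x, y, covariates=None) -> CorrelationResult:
    """Spearman correlation of x and y adjusted for covariates.

    x and y are rank-transformed (average ranks for ties), residualised
    on the rank-transformed covariates by least squares, and the Pearson
    correlation of the residuals is tested on n − #covariates − 2
    degrees of freedom. Without covariates this reduces to the plain
    Spearman coefficient. Rows with missing values in any involved
    variable are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.size, 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        Z = covariates.to_numpy(dtype=float)
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] == x.size and Z.shape[1] != x.size:
            pass
        elif Z.shape[1] == x.size:
            Z = Z.T
        names = [f"z{i}" for i in range(Z.shape[1])]
    mask = np.isfinite(x) & np.isfinite(y)
    if Z.shape[1]:
        mask &= np.isfinite(Z).all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        warnings.warn(f"partial_spearman: dropped {n_dropped} incomplete rows")
    x, y, Z = x[mask], y[mask], Z[mask]
    n, k = x.size, Z.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > #covariates + 3 (n={n}, k={k})")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(np.nan, np.nan, names, n, flagged=True)
    design = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(k)])
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    if ex.std() < 1e-10 * rx.std() or ey.std() < 1e-10 * ry.std():
        return CorrelationResult(np.nan, np.nan, names, n, flagged=True)
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - k - 2
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(rho, max(p, np.finfo(float).tiny), names, n)


# ---------------------------------------------------------------------------
# clustering / stratification


def _wss(X, k, seed, n_init=10):
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return float(km.inertia_)


def choose_k_consensus(
    X,
    k_candidates,
    methods=("elbow", "silhouette", "gap"),
    seed: int = 0,
    n_ref: int = 50,
    return_votes: bool = False,
):
    """Consensus number of clusters by elbow + silhouette + gap majority vote.

    elbow: k maximising the second difference of the within-cluster sum
    of squares; silhouette: k maximising the mean silhouette width; gap:
    Tibshirani's statistic against ``n_ref`` uniform bounding-box
    references with the one-standard-error rule. Ties in the vote break
    toward the smaller k.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate input: all rows identical")
    ks = sorted(set(int(k) for k in k_candidates))
    if ks[0] < 2 or ks[-1] >= X.shape[0]:
        raise ValueError("k_candidates must lie in [2, n_subjects - 1]")
    rng = np.random.default_rng(seed)
    ks_ext = list(range(max(1, ks[0] - 1), ks[-1] + 2))
    wss = {k: _wss(X, k, seed) for k in ks_ext}

    votes = {}
    if "elbow" in methods:
        second_diff = {
            k: wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in ks if k - 1 >= 1
        }
        votes["elbow"] = min(second_diff, key=lambda k: (-second_diff[k], k))
    if "silhouette" in methods:
        sil = {}
        for k in ks:
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
            sil[k] = silhouette_score(X, labels) if len(set(labels)) > 1 else -1.0
        votes["silhouette"] = min(sil, key=lambda k: (-sil[k], k))
    if "gap" in methods:
        lo, hi = X.min(axis=0), X.max(axis=0)
        log_wref = {k: np.empty(n_ref) for k in ks_ext}
        for b in range(n_ref):
            ref = rng.uniform(lo, hi, size=X.shape)
            ref_seed = int(rng.integers(0, 2**31 - 1))
            for k in ks_ext:
                log_wref[k][b] = np.log(_wss(ref, k, ref_seed, n_init=3))
        gap = {k: log_wref[k].mean() - np.log(wss[k]) for k in ks_ext}
        s = {k: log_wref[k].std(ddof=0) * np.sqrt(1 + 1 / n_ref) for k in ks_ext}
        chosen = ks[-1]
        for k in ks:
            if gap[k] >= gap[k + 1] - s[k + 1]:
                chosen = k
                break
        votes["gap"] = chosen

    best = majority_vote(votes.values())
    return (best, votes) if return_votes else best


def majority_vote(ks) -> int:
    """Most frequent k; ties break toward the smaller k."""
    counts: dict[int, int] = {}
    for k in ks:
        counts[k] = counts.get(k, 0) + 1
    return min(counts, key=lambda k: (-counts[k], k))


def kmeans_stratify(X, k: int, n_restarts: int = 25, seed: int = 0):
    """K-means with the best of ``n_restarts`` random starts.

    Returns ``(labels, centers, inertia)``; deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of observations")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_restarts, random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def stratify_high_low(values, seed: int = 0) -> pd.Series:
    """Two-cluster k-means split of one variable, labelled high/low.

    The cluster with the larger center is ``"high"`` — the convention
    used to dichotomise hippurate excretion and the first dietary
    principal component.
    """
    values = pd.Series(values)
    labels, centers, _ = kmeans_stratify(values.to_numpy(dtype=float), 2, seed=seed)
    high = int(np.argmax(centers[:, 0]))
    return pd.Series(np.where(labels == high, "high", "low"), index=values.index)


# ---------------------------------------------------------------------------
# probabilistic PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # orthonormal columns, ordered by variance
    variance_explained: np.ndarray  # fractions, non-increasing
    mean: np.ndarray
    sigma2: float
    n_iter: int


class ProbabilisticPCA:
    """Probabilistic PCA tolerant of missing values.

    On complete data the maximum-likelihood solution is closed-form
    (eigendecomposition of the covariance with the residual variance σ²
    equal to the mean discarded eigenvalue), so scores and loadings
    coincide with classical PCA up to sign. With missing entries the
    model is fitted by EM, treating the missing coordinates as latent.

    Parameters
    ----------
    n_components : int
    max_missing : float
        Maximum tolerated per-column missingness (default 20 %).
    """

    def __init__(self, n_components: int = 2, max_iter: int = 1000, tol: float = 1e-6,
                 max_missing: float = 0.2, standardize: bool = True):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.max_missing = max_missing
        self.standardize = standardize

    def fit_transform(self, X) -> PcaResult:
        if isinstance(X, pd.DataFrame):
            cols, index = list(X.columns), X.index
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            cols = [f"v{j}" for j in range(X.shape[1])]
            index = pd.RangeIndex(X.shape[0])
        n, p = X.shape
        q = self.n_components
        if q >= p:
            raise ValueError("n_components must be < number of variables")
        miss = np.isnan(X)
        frac = miss.mean(axis=0)
        if np.any(frac >= 1.0):
            bad = [cols[j] for j in np.flatnonzero(frac >= 1.0)]
            raise ValueError("fully missing column(s): " + ", ".join(bad))
        if np.any(frac > self.max_missing):
            bad = [cols[j] for j in np.flatnonzero(frac > self.max_missing)]
            raise ValueError(
                f"column(s) exceed max_missing={self.max_missing:.0%}: " + ", ".join(bad)
            )
        col_mean = np.nanmean(X, axis=0)
        if self.standardize:
            col_sd = np.nanstd(X, axis=0)
            col_sd[col_sd == 0] = 1.0
        else:
            col_sd = np.ones(p)
        Xs = (X - col_mean) / col_sd

        if not miss.any():
            W, mu, sigma2, n_iter = self._closed_form(Xs, q)
        else:
            W, mu, sigma2, n_iter = self._em(Xs, miss, q)

        # rotate W to ordered orthonormal axes
        U, svals, _ = np.linalg.svd(W, full_matrices=False)
        load = U[:, :q]
        if miss.any():
            scores = self._posterior_scores(Xs, miss, W, mu, sigma2) @ _rotation(W, U[:, :q])
        else:
            scores = (Xs - mu) @ load
        comp_var = svals[:q] ** 2 + sigma2
        # variance explained relative to total model variance
        total = comp_var.sum() + sigma2 * (p - q)
        var_expl = comp_var / total
        names = [f"PC{i + 1}" for i in range(q)]
        return PcaResult(
            scores=pd.DataFrame(scores, index=index, columns=names),
            loadings=pd.DataFrame(load, index=cols, columns=names),
            variance_explained=var_expl,
            mean=col_mean,
            sigma2=float(sigma2),
            n_iter=n_iter,
        )

    @staticmethod
    def _closed_form(Xs, q):
        n, p = Xs.shape
        mu = Xs.mean(axis=0)
        Xc = Xs - mu
        cov = Xc.T @ Xc / n
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        sigma2 = float(np.mean(evals[q:])) if q < p else 0.0
        W = evecs[:, :q] * np.sqrt(np.maximum(evals[:q] - sigma2, 0.0))
        return W, mu, sigma2, 0

    def _em(self, Xs, miss, q):
        n, p = Xs.shape
        Xfill = np.where(miss, 0.0, Xs)  # columns are already ~zero-mean
        W, mu, sigma2, _ = self._closed_form(Xfill, q)
        sigma2 = max(sigma2, 1e-6)
        for it in range(1, self.max_iter + 1):
            W_old, mu_old, s_old = W.copy(), mu.copy(), sigma2
            Ez = np.zeros((n, q))
            Ezz = np.zeros((n, q, q))
            Xhat = Xs.copy()
            for i in range(n):
                o = ~miss[i]
                Wo = W[o]
                M = Wo.T @ Wo + sigma2 * np.eye(q)
                Minv = np.linalg.inv(M)
                Ez[i] = Minv @ Wo.T @ (Xs[i, o] - mu[o])
                Ezz[i] = sigma2 * Minv + np.outer(Ez[i], Ez[i])
                Xhat[i, miss[i]] = mu[miss[i]] + W[miss[i]] @ Ez[i]
            mu = (Xhat - Ez @ W.T).mean(axis=0)
            A = Ezz.sum(axis=0)
            B = (Xhat - mu).T @ Ez
            W = B @ np.linalg.inv(A)
            resid = 0.0
            for i in range(n):
                o = ~miss[i]
                d = Xs[i, o] - mu[o] - W[o] @ Ez[i]
                resid += d @ d + sigma2 * np.trace(W[o] @ np.linalg.inv(
                    W[o].T @ W[o] + s_old * np.eye(q)) @ W[o].T)
            sigma2 = max(resid / (~miss).sum(), 1e-10)
            delta = (
                np.abs(W - W_old).max() + np.abs(mu - mu_old).max() + abs(sigma2 - s_old)
            )
            if delta < self.tol:
                return W, mu, sigma2, it
        warnings.warn("probabilistic PCA EM did not converge")
        return W, mu, sigma2, self.max_iter

    @staticmethod
    def _posterior_scores(Xs, miss, W, mu, sigma2):
        n, q = Xs.shape[0], W.shape[1]
        Ez = np.zeros((n, q))
        for i in range(n):
            o = ~miss[i]
            Wo = W[o]
            M = Wo.T @ Wo + sigma2 * np.eye(q)
            Ez[i] = np.linalg.solve(M, Wo.T @ (Xs[i, o] - mu[o]))
        return Ez


def _rotation(W, U):
    """Rotation from the EM factor basis to the ordered orthonormal basis."""
    # scores in factor basis z relate to axis projections via W = U S V':
    # x ~ W z, so U'x ~ S V' z
    _, S, Vt = np.linalg.svd(W, full_matrices=False)
    return (np.diag(S) @ Vt).T


def ppca_scores(X, n_components: int = 2, max_iter: int = 1000, tol: float = 1e-6,
                max_missing: float = 0.2, standardize: bool = True) -> PcaResult:
    """Probabilistic PCA scores/loadings for a table with missing values."""
    return ProbabilisticPCA(
        n_components, max_iter, tol, max_missing, standardize
    ).fit_transform(X)


# ---------------------------------------------------------------------------
# stepwise rank regression


@dataclass
class StepwiseResult:
    """Forward stepwise selection trace on rank-transformed data."""

    selected: list
    aic_path: list  # AIC after each accepted step (intercept-only first)
    incremental_pct: list  # added explained variance per accepted variable, %
    coefficients: dict  # final-model coefficients (rank scale)
    coef_signs: dict
    p_values: dict  # final-model t-test p per selected variable
    r2: float
    n_used: int
    notes: list = field(default_factory=list)


def _aic(rss, n, k_params):
    return n * np.log(2 * np.pi * rss / n) + n + 2 * k_params


def stepwise_rank_regression(
    y, candidates: pd.DataFrame, direction: str = "forward", criterion: str = "aic"
) -> StepwiseResult:
    """Greedy forward selection on rank-transformed variables, scored by AIC.

    The response and all continuous candidates are rank-transformed
    (average ranks); binary candidates pass through. Selection stops when
    no remaining candidate lowers the AIC; near-collinear candidates
    (R² > 0.999 with the selected set) are skipped with a note. The
    per-variable incremental explained variance is the Fig-style bar
    decomposition: the gain in R² (×100) when the variable entered.
    """
    if direction != "forward" or criterion != "aic":
        raise ValueError("only forward selection with AIC is implemented")
    y = pd.Series(y).astype(float)
    candidates = candidates.copy()
    keep = y.notna() & candidates.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    notes = []
    if n_dropped:
        notes.append(f"dropped {n_dropped} incomplete rows (complete-case)")
    y = y[keep]
    candidates = candidates.loc[keep]
    n = len(y)
    ry = sps.rankdata(y)

    def prep(col: pd.Series) -> np.ndarray:
        vals = col.to_numpy(dtype=float)
        if np.unique(vals).size <= 2:
            return vals  # binary/categorical passes through
        return sps.rankdata(vals)

    Xcand = {name: prep(candidates[name]) for name in candidates.columns}
    tss = float(((ry - ry.mean()) ** 2).sum())
    selected: list[str] = []
    design = np.ones((n, 1))
    rss = tss
    aic_path = [_aic(rss, n, 2)]  # intercept + variance
    incremental = []

    while True:
        best = None
        for name, col in Xcand.items():
            if name in selected:
                continue
            # collinearity screen against the current design
            coef, res, *_ = np.linalg.lstsq(design, col, rcond=None)
            col_tss = float(((col - col.mean()) ** 2).sum())
            col_rss = float(((col - design @ coef) ** 2).sum())
            if col_tss > 0 and 1 - col_rss / col_tss > 0.999:
                if f"skipped collinear candidate {name}" not in notes:
                    notes.append(f"skipped collinear candidate {name}")
                continue
            trial = np.column_stack([design, col])
            coef, *_ = np.linalg.lstsq(trial, ry, rcond=None)
            trial_rss = float(((ry - trial @ coef) ** 2).sum())
            trial_aic = _aic(max(trial_rss, 1e-12), n, trial.shape[1] + 1)
            if best is None or trial_aic < best[1]:
                best = (name, trial_aic, trial, trial_rss)
        if best is None or best[1] >= aic_path[-1]:
            break
        name, aic, design, new_rss = best
        selected.append(name)
        incremental.append(100.0 * (rss - new_rss) / tss)
        rss = new_rss
        aic_path.append(aic)

    coef, *_ = np.linalg.lstsq(design, ry, rcond=None)
    resid = ry - design @ coef
    dof = n - design.shape[1]
    s2 = float(resid @ resid) / max(dof, 1)
    cov = s2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    coefs, signs, pvals = {}, {}, {}
    for j, name in enumerate(selected, start=1):
        coefs[name] = float(coef[j])
        signs[name] = int(np.sign(coef[j]))
        t = coef[j] / se[j] if se[j] > 0 else np.inf
        pvals[name] = float(2 * sps.t.sf(abs(t), dof))
    return StepwiseResult(
        selected=selected,
        aic_path=aic_path,
        incremental_pct=incremental,
        coefficients=coefs,
        coef_signs=signs,
        p_values=pvals,
        r2=1.0 - rss / tss,
        n_used=n,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparisonReport:
    branch: str  # "anova_tukey", "mann_whitney", "kruskal_dunn"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None
    normality_p: dict
    notes: list = field(default_factory=list)


def dunn_posthoc(values, labels, fdr_method: str = "bh") -> pd.DataFrame:
    """Joint-rank Dunn z-tests for all group pairs, with tie correction."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    ranks = sps.rankdata(values)
    N = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            ra, rb = ranks[labels == a], ranks[labels == b]
            var = (N * (N + 1) / 12.0 - tie_term) * (1 / ra.size + 1 / rb.size)
            z = (ra.mean() - rb.mean()) / np.sqrt(var)
            p = 2 * sps.norm.sf(abs(z))
            rows.append(dict(group_a=a, group_b=b, z=float(z), p=max(float(p), 1e-300)))
    out = pd.DataFrame(rows)
    out["q"] = adjust_pvalues(out["p"].to_numpy(), method=fdr_method)
    return out


def group_compare(
    values,
    groups,
    paired: bool = False,
    alpha_normality: float = 0.05,
    fdr_method: str = "bh",
) -> GroupComparisonReport:
    """Normality-gated comparison of two or more groups.

    Per-group normality is assessed with the D'Agostino-Pearson omnibus
    test; if every group is consistent with normality the comparison is
    one-way ANOVA with Tukey HSD post hocs, otherwise two groups are
    compared with the two-tailed Mann-Whitney test and more than two with
    Kruskal-Wallis followed by joint-rank Dunn tests. Groups with fewer
    than 8 observations skip the normality test (it is unreliable there)
    and force the nonparametric branch.
    """
    if paired:
        raise NotImplementedError("paired designs are not implemented")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    notes = []
    keep_groups = []
    for g in pd.unique(groups):
        n_g = int((groups == g).sum())
        if n_g < 2:
            notes.append(f"excluded group {g!r} with n={n_g} < 2")
        else:
            keep_groups.append(g)
    if len(keep_groups) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    mask = np.isin(groups, keep_groups)
    values, groups = values[mask], groups[mask]
    samples = [values[groups == g] for g in keep_groups]

    normality_p = {}
    all_normal = True
    for g, s in zip(keep_groups, samples):
        if s.size < 8:
            notes.append(f"group {g!r} has n={s.size} < 8: nonparametric branch forced")
            all_normal = False
            normality_p[g] = np.nan
        else:
            p = float(sps.normaltest(s).pvalue)
            normality_p[g] = p
            if p <= alpha_normality:
                all_normal = False

    if all_normal:
        stat, p = sps.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(values, groups)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        return GroupComparisonReport("anova_tukey", float(stat), float(p), pairwise,
                                     normality_p, notes)
    if len(samples) == 2:
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparisonReport("mann_whitney", float(stat), float(p), None,
                                     normality_p, notes)
    stat, p = sps.kruskal(*samples)
    pairwise = dunn_posthoc(values, groups, fdr_method=fdr_method)
    return GroupComparisonReport("kruskal_dunn", float(stat), float(p), pairwise,
                                 normality_p, notes)


# ---------------------------------------------------------------------------
# outliers


def rout_outliers(values, Q: float = 0.01) -> np.ndarray:
    """ROUT-style robust outlier mask at target false-discovery rate Q.

    Location and scale come from the median and the MAD-derived robust
    standard deviation; standardised residuals get two-sided t-tail
    p-values which are screened by a Benjamini-Hochberg step-up at rate
    Q, flagging the most extreme points. This is a robust-location
    approximation of the original robust-regression procedure, suited to
    the univariate group data it is applied to here.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values")
    if not 0 < Q < 1:
        raise ValueError("Q must be in (0, 1)")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero: no outliers callable")
        return np.zeros(x.size, dtype=bool)
    rsdr = 1.4826 * mad
    t = (x - med) / rsdr
    p = 2 * sps.t.sf(np.abs(t), df=x.size - 1)
    order = np.argsort(p)
    thresh = Q * np.arange(1, x.size + 1) / x.size
    passed = p[order] <= thresh
    mask = np.zeros(x.size, dtype=bool)
    if passed.any():
        cutoff = np.max(np.flatnonzero(passed))
        mask[order[: cutoff + 1]] = True
    return mask


# ---------------------------------------------------------------------------
# glucose tolerance


@dataclass
class IpgttResult:
    """Summaries of an intraperitoneal glucose tolerance test excursion."""

    auc: float  # sum of glucose values over sampled timepoints (mM·timepoint)
    delta_g: float  # baseline-subtracted trapezoidal integral (mM·min)
    auc_trapezoid: float  # time-weighted alternative AUC (mM·min)
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray | None = None


def ipgtt_summary(glucose, times=None, insulin=None) -> IpgttResult:
    """AUC and ΔG of a glucose tolerance test.

    AUC follows the plain sum-of-sampled-values convention
    (``sum(glucose)``); ΔG is the area over the baseline value
    (first timepoint) integrated trapezoidally across the test. The
    trapezoidal AUC is also reported for completeness.
    """
    g = np.asarray(glucose, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(g < 0):
        raise ValueError("negative glucose value")
    t = (
        np.asarray(times, dtype=float)
        if times is not None
        else np.linspace(0, 120, g.size)
    )
    if t.size != g.size or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 (baseline) and increase")
    auc = float(g.sum())
    delta_g = float(np.trapezoid(g - g[0], t))
    auc_trap = float(np.trapezoid(g, t))
    ins = np.asarray(insulin, dtype=float) if insulin is not None else None
    return IpgttResult(auc, delta_g, auc_trap, t, g, ins)


# ---------------------------------------------------------------------------
# adjusted attribution


@dataclass
class AttributionReport:
    """Does each of two correlated predictors survive adjustment for the other?"""

    outcome: str
    var_a: str
    var_b: str
    rho_a: CorrelationResult  # a vs outcome | covariates
    rho_a_adj: CorrelationResult  # a vs outcome | covariates + b
    rho_b: CorrelationResult
    rho_b_adj: CorrelationResult
    rho_ab: float  # plain Spearman between a and b
    collapse_a: bool
    collapse_b: bool
    collapse_fraction: float


def adjusted_attribution(
    cohort: pd.DataFrame,
    outcome: str,
    var_a: str = "hippurate_au",
    var_b: str = "gene_count",
    covariates=("age", "sex", "bmi"),
    collapse_fraction: float = 0.5,
) -> AttributionReport:
    """The 2×2 adjustment pattern for two correlated predictors.

    Computes partial Spearman correlations of ``var_a`` and ``var_b``
    with the outcome, each with and without additional adjustment for
    the partner variable (all adjusted for the covariates), plus the
    plain correlation between the two predictors. A predictor's
    association is flagged as *collapsed* when adjustment for its
    partner shrinks |ρ| below ``collapse_fraction`` of its unadjusted
    value — the signature of an association mediated by the partner.
    """
    for colname in [outcome, var_a, var_b, *covariates]:
        if colname not in cohort.columns:
            raise ValueError(f"column {colname!r} not in cohort table")
    cov = cohort[list(covariates)]
    a, b, y = cohort[var_a], cohort[var_b], cohort[outcome]
    rho_a = partial_spearman(a, y, cov)
    rho_b = partial_spearman(b, y, cov)
    rho_a_adj = partial_spearman(a, y, pd.concat([cov, b], axis=1))
    rho_b_adj = partial_spearman(b, y, pd.concat([cov, a], axis=1))
    rho_ab = float(sps.spearmanr(a, b, nan_policy="omit").statistic)

    def collapsed(base: CorrelationResult, adj: CorrelationResult) -> bool:
        if base.flagged or adj.flagged or np.isnan(base.rho) or np.isnan(adj.rho):
            return False
        return abs(adj.rho) < collapse_fraction * abs(base.rho)

    return AttributionReport(
        outcome=outcome, var_a=var_a, var_b=var_b,
        rho_a=rho_a, rho_a_adj=rho_a_adj, rho_b=rho_b, rho_b_adj=rho_b_adj,
        rho_ab=rho_ab,
        collapse_a=collapsed(rho_a, rho_a_adj),
        collapse_b=collapsed(rho_b, rho_b_adj),
        collapse_fraction=collapse_fraction,
    )
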