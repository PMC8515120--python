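"""Community typing of genus-level gut microbiome profiles.

Enterotypes are discrete community types obtained by fitting Dirichlet-
multinomial mixtures (DMM) to genus count tables: each component is a
Dirichlet distribution over genus proportions, samples are multinomial
draws from a component-specific composition, and the number of components
is selected by the Laplace approximation to the negative log model
evidence. The module also provides the Hellinger transform and
Bray-Curtis principal coordinates ("enteroscape") used for the visual
layer, and Kruskal-Wallis + Dunn comparisons of a variable across
enterotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln, psi, polygamma, logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .stats import dunn_posthoc

__all__ = [
    "DirichletMultinomialMixture",
    "Ordination",
    "EnterotypeComparison",
    "hellinger_transform",
    "fit_dmm",
    "assign_enterotypes",
    "pcoa_braycurtis",
    "enterotype_compare",
]


def hellinger_transform(table):
    """Hellinger transform: sqrt of relative abundance per sample.

    Rows of the result have unit sum of squares, making compositional
    data amenable to Euclidean-style analyses.
    """
    X = np.asarray(table, dtype=float) if not isinstance(table, pd.DataFrame) else table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-sum row(s) cannot be Hellinger-transformed")
    H = np.sqrt(X / totals[:, None])
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(H, index=table.index, columns=table.columns)
    return H


def _dm_logpmf(X, row_sums, lgamma_counts, alpha):
    """Dirichlet-multinomial log pmf for every row at one alpha vector."""
    A = alpha.sum()
    return (
        lgamma_counts
        + gammaln(A)
        - gammaln(row_sums + A)
        + gammaln(X + alpha).sum(axis=1)
        - gammaln(alpha).sum()
    )


def _moment_alpha(X, weights=None):
    """Method-of-moments Dirichlet-multinomial estimate (weighted)."""
    P = X / X.sum(axis=1, keepdims=True)
    w = np.ones(X.shape[0]) if weights is None else weights
    w = w / w.sum()
    m = w @ P
    v = w @ (P - m) ** 2
    ok = (m > 1e-12) & (m < 1 - 1e-12) & (v > 0)
    if ok.any():
        theta = float(np.mean(v[ok] / (m[ok] * (1 - m[ok]))))
        theta = min(max(theta, 1e-6), 0.999)
        s = (1 - theta) / theta
    else:
        s = 50.0
    return np.maximum(s * m, 1e-8)


class DirichletMultinomialMixture(BaseEstimator):
    """EM fit of a Dirichlet-multinomial mixture over count rows.

    Parameters
    ----------
    n_components : int
    max_iter, tol : EM iteration cap and absolute log-likelihood tolerance.
    n_inner : fixed-point iterations of the alpha update per M-step.
    random_state : seeds the k-means initialisation.

    Attributes
    ----------
    component_alpha_ : ndarray (k, n_genera), positive
    mixture_weights_ : ndarray (k,), sums to 1
    assignments_ : posterior-argmax component per sample
    log_likelihoods_ : trace across EM iterations (non-decreasing)
    laplace_ : Laplace approximation to the negative log model evidence
    """

    def __init__(self, n_components: int = 3, max_iter: int = 250, tol: float = 1e-4,
                 n_inner: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_inner = n_inner
        self.random_state = random_state

    def _prepare(self, table):
        X = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
        if not np.allclose(X, np.round(X)) or (X < 0).any():
            raise ValueError(
                "Dirichlet-multinomial mixtures require nonnegative integer "
                "counts; supply raw counts, not relative abundances"
            )
        X = np.asarray(np.round(X), dtype=float)
        if np.any(X.sum(axis=1) <= 0):
            raise ValueError("zero-sum row(s) in count table")
        return X

    def fit(self, table, y=None):
        X = self._prepare(table)
        n, S = X.shape
        K = self.n_components
        if not 1 <= K < n:
            raise ValueError("n_components must be in [1, n_samples)")
        row_sums = X.sum(axis=1)
        lgamma_counts = gammaln(row_sums + 1) - gammaln(X + 1).sum(axis=1)

        if K == 1:
            resp = np.ones((n, 1))
        else:
            labels = KMeans(
                n_clusters=K, n_init=10, random_state=self.random_state
            ).fit_predict(np.sqrt(X / row_sums[:, None]))
            resp = np.full((n, K), 0.05 / max(K - 1, 1))
            resp[np.arange(n), labels] = 0.95
        alpha = np.stack([_moment_alpha(X, resp[:, k]) for k in range(K)])
        weights = resp.mean(axis=0)

        lls = []
        for _ in range(self.max_iter):
            L = np.stack(
                [_dm_logpmf(X, row_sums, lgamma_counts, alpha[k]) for k in range(K)],
                axis=1,
            )
            Lw = L + np.log(weights)
            ll = float(logsumexp(Lw, axis=1).sum())
            lls.append(ll)
            resp = np.exp(Lw - logsumexp(Lw, axis=1, keepdims=True))
            weights = np.maximum(resp.mean(axis=0), 1e-12)
            weights /= weights.sum()
            for k in range(K):
                r = resp[:, k]
                a = alpha[k]
                for _ in range(self.n_inner):
                    A = a.sum()
                    num = r @ (psi(X + a) - psi(a))
                    den = float(r @ (psi(row_sums + A) - psi(A)))
                    if den <= 0:
                        break
                    a = np.maximum(a * num / den, 1e-8)
                alpha[k] = a
            if len(lls) > 1 and abs(lls[-1] - lls[-2]) < self.tol:
                break
        else:
            warnings.warn(
                "DMM EM did not converge "
                f"(final log-likelihood delta {lls[-1] - lls[-2]:.3g})"
            )
        # final E-step quantities at the converged parameters
        L = np.stack(
            [_dm_logpmf(X, row_sums, lgamma_counts, alpha[k]) for k in range(K)], axis=1
        )
        Lw = L + np.log(weights)
        ll = float(logsumexp(Lw, axis=1).sum())
        lls.append(ll)
        self.component_alpha_ = alpha
        self.mixture_weights_ = weights
        self.responsibilities_ = np.exp(Lw - logsumexp(Lw, axis=1, keepdims=True))
        self.assignments_ = np.argmax(self.responsibilities_, axis=1)
        self.log_likelihoods_ = lls
        self.log_likelihood_ = ll
        self.laplace_ = self._laplace(X, row_sums)
        self.n_features_in_ = S
        return self

    #: variance of the zero-mean Gaussian prior on λ = log α used by the
    #: Laplace evidence (a weak regulariser, as in the published DMM score)
    prior_var: float = 10.0

    def _laplace(self, X, row_sums) -> float:
        """Laplace approximation to the negative log model evidence.

        −log L̂ − log prior(λ̂) + ½ log|H| − (d/2) log 2π, with a
        zero-mean Gaussian prior of variance ``prior_var`` on every
        λ = log α and H the block-diagonal Hessian of the
        responsibility-weighted negative log-posterior at the EM optimum
        (d = k × n_genera).
        """
        eta = self.prior_var
        total = -self.log_likelihood_
        d = 0
        logdet = 0.0
        for k in range(self.component_alpha_.shape[0]):
            a = self.component_alpha_[k]
            lam = np.log(a)
            r = self.responsibilities_[:, k]
            A = a.sum()
            rsum = r.sum()
            common = float(r @ (polygamma(1, row_sums + A))) - rsum * polygamma(1, A)
            diag_extra = r @ (polygamma(1, X + a)) - rsum * polygamma(1, a)
            H_a = np.full((a.size, a.size), common)
            H_a[np.diag_indices_from(H_a)] += diag_extra
            H_a = -H_a  # Hessian of the negative log-likelihood
            grad_a = -(r @ (psi(X + a) - psi(a)) - (r @ (psi(row_sums + A) - psi(A))) * 1.0)
            H_l = (a[:, None] * a[None, :]) * H_a + np.diag(a * grad_a)
            H_l[np.diag_indices_from(H_l)] += 1.0 / eta  # prior curvature
            total += float(lam @ lam) / (2 * eta) + 0.5 * a.size * np.log(2 * np.pi * eta)
            eigvals = np.linalg.eigvalsh((H_l + H_l.T) / 2)
            logdet += float(np.log(np.maximum(eigvals, 1.0 / eta)).sum())
            d += a.size
        return total + 0.5 * logdet - 0.5 * d * np.log(2 * np.pi)

    def predict_proba(self, table) -> np.ndarray:
        X = self._prepare(table)
        row_sums = X.sum(axis=1)
        lgamma_counts = gammaln(row_sums + 1) - gammaln(X + 1).sum(axis=1)
        L = np.stack(
            [
                _dm_logpmf(X, row_sums, lgamma_counts, self.component_alpha_[k])
                for k in range(self.component_alpha_.shape[0])
            ],
            axis=1,
        )
        Lw = L + np.log(self.mixture_weights_)
        return np.exp(Lw - logsumexp(Lw, axis=1, keepdims=True))

    def predict(self, table) -> np.ndarray:
        return np.argmax(self.predict_proba(table), axis=1)


def fit_dmm(
    table,
    k_candidates=range(1, 7),
    seed: int = 0,
    max_iter: int = 250,
    tol: float = 1e-4,
) -> DirichletMultinomialMixture:
    """Fit DMMs for every candidate k and keep the Laplace-best model.

    The returned estimator carries ``laplace_by_k_`` (model-selection
    score per candidate; smaller is better) in addition to the fitted
    attributes of the winning k.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    scores: dict[int, float] = {}
    best = None
    for k in ks:
        model = DirichletMultinomialMixture(
            n_components=k, max_iter=max_iter, tol=tol, random_state=seed
        ).fit(table)
        scores[k] = model.laplace_
        if best is None or model.laplace_ < best.laplace_:
            best = model
    best.laplace_by_k_ = scores
    return best


def assign_enterotypes(
    model: DirichletMultinomialMixture, table, label_rule: str = "dominant_taxon"
) -> pd.Series:
    """Posterior-argmax enterotype labels with dominant-taxon naming.

    With ``label_rule="dominant_taxon"`` each component is named after
    its highest-alpha genus; components sharing a dominant genus (the
    two Bacteroides types) are numbered by decreasing expected Shannon
    diversity of their composition, so the diverse type is ``…1`` and
    the low-diversity type ``…2``. ``label_rule="component"`` uses plain
    ``ET<k>`` labels.
    """
    if isinstance(table, pd.DataFrame):
        genera = list(table.columns)
        index = table.index
    else:
        table = np.asarray(table)
        genera = [f"g{j}" for j in range(table.shape[1])]
        index = pd.RangeIndex(table.shape[0])
    K = model.component_alpha_.shape[0]
    if len(genera) != model.component_alpha_.shape[1]:
        raise ValueError("table genera do not match the fitted model")

    if label_rule == "component":
        names = {k: f"ET{k + 1}" for k in range(K)}
    elif label_rule == "dominant_taxon":
        dominant = {k: genera[int(np.argmax(model.component_alpha_[k]))] for k in range(K)}
        names = {}
        by_genus: dict[str, list[int]] = {}
        for k, g in dominant.items():
            by_genus.setdefault(g, []).append(k)
        for g, comps in by_genus.items():
            if len(comps) == 1:
                names[comps[0]] = g
            else:
                def diversity(k):
                    p = model.component_alpha_[k] / model.component_alpha_[k].sum()
                    p = p[p > 0]
                    return float(-(p * np.log(p)).sum())

                for rank, k in enumerate(sorted(comps, key=diversity, reverse=True), 1):
                    names[k] = f"{g}{rank}"
    else:
        raise ValueError("label_rule must be 'dominant_taxon' or 'component'")

    proba = model.predict_proba(table)
    labels = pd.Series(
        [names[k] for k in np.argmax(proba, axis=1)], index=index, name="enterotype"
    )
    labels.attrs["component_names"] = names
    return labels


@dataclass
class Ordination:
    """Principal coordinates with eigenvalues (negatives reported, not dropped)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def braycurtis_matrix(table) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity on the table as given."""
    X = np.asarray(table, dtype=float) if not isinstance(table, pd.DataFrame) else table.to_numpy(dtype=float)
    return squareform(pdist(X, metric="braycurtis"))


def pcoa_braycurtis(table, n_axes: int = 2) -> Ordination:
    """Bray-Curtis principal coordinates of a genus abundance matrix.

    Classical Gower decomposition: eigendecompose the double-centred
    −D²/2 matrix. Bray-Curtis is generally non-Euclidean, so negative
    eigenvalues occur; they are reported alongside the positive spectrum
    rather than silently dropped (coordinates use the positive part
    only). Proportions explained are relative to the positive spectrum.
    """
    if isinstance(table, pd.DataFrame):
        ids = [str(i) for i in table.index]
    else:
        ids = [str(i) for i in range(np.asarray(table).shape[0])]
    n = len(ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 subjects")
    D = braycurtis_matrix(table)
    A = -0.5 * D**2
    J = np.eye(n) - 1.0 / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.maximum(eigvals[:n_axes], 0.0)
    coords = eigvecs[:, :n_axes] * np.sqrt(pos)
    pos_total = eigvals[eigvals > 0].sum()
    prop = np.where(eigvals > 0, eigvals, 0.0) / pos_total if pos_total > 0 else eigvals * 0
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class EnterotypeComparison:
    """Kruskal-Wallis omnibus plus pairwise Dunn table across enterotypes."""

    chi2: float
    p_value: float
    pairwise: pd.DataFrame
    groups: list
    notes: list


def enterotype_compare(values, labels, fdr_method: str = "bh") -> EnterotypeComparison:
    """Compare a variable (e.g. hippurate) across enterotypes.

    Kruskal-Wallis omnibus χ² followed by joint-rank Dunn z-tests with
    multiplicity correction; groups with fewer than 2 members are
    excluded with a warning.
    """
    from scipy.stats import kruskal

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    notes = []
    keep = []
    for g in pd.unique(labels):
        if (labels == g).sum() < 2:
            notes.append(f"excluded group {g!r} with n < 2")
            warnings.warn(notes[-1])
        else:
            keep.append(g)
    if len(keep) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    mask = np.isin(labels, keep)
    values, labels = values[mask], labels[mask]
    chi2, p = kruskal(*[values[labels == g] for g in keep])
    pairwise = dunn_posthoc(values, labels, fdr_method=fdr_method)
    return EnterotypeComparison(float(chi2), float(p), pairwise, keep, notes)
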