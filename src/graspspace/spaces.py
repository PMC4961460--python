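"""Dimensionality reduction and condition geometry.

PCA summarizes the variability of the 27-dimensional joint space; canonical
discriminant analysis (CDA) transforms the neural population space so that
between-condition separation relative to within-condition scatter is
maximized (the generalized eigenproblem of the between- and within-class
scatter matrices); condition geometry in the full N-space is measured with
Mahalanobis distances between condition means under the pooled within-group
covariance.  The within-class scatter can be shrunk towards its diagonal
(automatic Ledoit–Wolf-style intensity by default) when it is
ill-conditioned, e.g. for sessions with few trials per unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.decomposition import PCA

from .prep import JSpaceMatrix, NSpaceMatrix


@dataclass
class PCAResult:
    components: np.ndarray          # n_components x n_features, orthonormal rows
    scores: np.ndarray              # trials x n_components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(data: JSpaceMatrix | np.ndarray, n_components: int | None = None) -> PCAResult:
    """Column-mean-centred PCA (SVD) of a trials x features matrix."""
    x = data.values if isinstance(data, JSpaceMatrix) else np.asarray(data, float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two trials")
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix has zero variance; PCA undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return PCAResult(
        components=model.components_,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=model.mean_,
    )


def _class_stats(x: np.ndarray, labels: np.ndarray):
    classes = np.array(sorted(set(labels)))
    counts = np.array([(labels == c).sum() for c in classes])
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 trials; offending: {list(bad)}")
    means = np.stack([x[labels == c].mean(axis=0) for c in classes])
    return classes, counts, means


def _scatter_matrices(x: np.ndarray, labels: np.ndarray):
    """Between- and within-class scatter (covariance normalization N - k)."""
    n, p = x.shape
    classes, counts, means = _class_stats(x, labels)
    grand = x.mean(axis=0)
    centered_means = means - grand
    s_between = (centered_means * counts[:, None]).T @ centered_means / (len(classes) - 1)
    residuals = x - means[np.searchsorted(classes, labels)]
    s_within = residuals.T @ residuals / (n - len(classes))
    return classes, counts, means, s_between, s_within, residuals


def _shrink(s_within: np.ndarray, residuals: np.ndarray, shrinkage: float | str):
    """Shrink the within-class scatter towards its diagonal."""
    if shrinkage == "auto":
        lam = float(ledoit_wolf_shrinkage(residuals, assume_centered=True))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
    if lam == 0.0:
        return s_within, lam
    return (1.0 - lam) * s_within + lam * np.diag(np.diag(s_within)), lam


@dataclass
class CanonicalTransform:
    """CDA projection with eigenvalues and separation percentages.

    ``projection`` (features x components) maps centred data to canonical
    coordinates in which the within-class scatter is whitened; components are
    ordered by non-increasing eigenvalue, each axis oriented so that its
    largest-magnitude loading is positive.  ``percent_separation`` are the
    eigenvalue shares (%) of the retained components and sum to 100.
    """

    projection: np.ndarray
    eigenvalues: np.ndarray
    percent_separation: np.ndarray
    class_labels: np.ndarray
    class_means: np.ndarray      # classes x components, canonical coordinates
    grand_mean: np.ndarray
    shrinkage: float

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.grand_mean) @ self.projection


def cda(
    nspace: NSpaceMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    shrinkage: float | str = "auto",
    n_components: int | None = None,
    percent_basis: str = "eigenvalue",
) -> CanonicalTransform:
    """Canonical discriminant analysis of a trials x units matrix.

    Solves ``S_between a = lambda S_within a``; the first canonical variable
    is the linear combination of units with the largest one-way ANOVA
    F-statistic across conditions, subsequent ones are S_within-orthogonal to
    it.  At most ``min(n_classes - 1, n_features)`` components exist.
    """
    if isinstance(nspace, NSpaceMatrix):
        x, labels = nspace.values, nspace.condition_ids
    else:
        x = np.asarray(nspace, float)
        if labels is None:
            raise ValueError("labels required for array input")
    labels = np.asarray(labels)
    n, p = x.shape

    classes, counts, means, s_b, s_w, residuals = _scatter_matrices(x, labels)
    s_w_reg, lam = _shrink(s_w, residuals, shrinkage)
    max_components = min(len(classes) - 1, p)
    if n_components is None:
        n_components = max_components
    n_components = min(n_components, max_components)

    try:
        eigvals, eigvecs = linalg.eigh(s_b, s_w_reg)
    except linalg.LinAlgError as err:
        raise ValueError(
            "within-class scatter is singular; use shrinkage > 0"
        ) from err
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = np.maximum(eigvals[order], 0.0)
    vecs = eigvecs[:, order]

    # orient each axis so its largest-magnitude loading is positive
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip

    grand = x.mean(axis=0)
    if percent_basis == "eigenvalue":
        shares = eigvals
    elif percent_basis == "projected_variance":
        shares = ((x - grand) @ vecs).var(axis=0)
    else:
        raise ValueError("percent_basis must be 'eigenvalue' or 'projected_variance'")
    total = shares.sum()
    percent = 100.0 * shares / total if total > 0 else np.full_like(shares, np.nan)
    return CanonicalTransform(
        projection=vecs,
        eigenvalues=eigvals,
        percent_separation=percent,
        class_labels=classes,
        class_means=(means - grand) @ vecs,
        grand_mean=grand,
        shrinkage=lam,
    )


@dataclass
class ConditionDistanceMatrix:
    """Mahalanobis distances between condition means in full N-space."""

    matrix: pd.DataFrame
    shrinkage: float
    epoch: str | None = None

    @property
    def condition_ids(self) -> np.ndarray:
        return self.matrix.index.to_numpy()


def mahalanobis_condition_distances(
    nspace: NSpaceMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    shrinkage: float | str = "auto",
    epoch: str | None = None,
) -> ConditionDistanceMatrix:
    """``d(c1, c2) = sqrt((mu1 - mu2)^T W^-1 (mu1 - mu2))`` with W the pooled
    (optionally diagonal-shrunk) within-condition covariance."""
    if isinstance(nspace, NSpaceMatrix):
        x, labels = nspace.values, nspace.condition_ids
        epoch = epoch or nspace.epoch
    else:
        x = np.asarray(nspace, float)
        if labels is None:
            raise ValueError("labels required for array input")
    labels = np.asarray(labels)

    classes, counts, means, _s_b, s_w, residuals = _scatter_matrices(x, labels)
    s_w_reg, lam = _shrink(s_w, residuals, shrinkage)
    try:
        chol = linalg.cho_factor(s_w_reg)
    except linalg.LinAlgError as err:
        raise ValueError(
            "within-class scatter is singular; use shrinkage > 0"
        ) from err

    k = len(classes)
    dist = np.zeros((k, k))
    whitened = linalg.cho_solve(chol, means.T).T   # W^-1 mu
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            d2 = diff @ (whitened[i] - whitened[j])
            dist[i, j] = dist[j, i] = np.sqrt(max(d2, 0.0))
    return ConditionDistanceMatrix(
        matrix=pd.DataFrame(dist, index=classes, columns=classes),
        shrinkage=lam,
        epoch=epoch,
    )
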