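"""Dimensionality reduction and wrapper feature selection.

Three classical reducers — PCA on the population (1/n) covariance, a
literal five-step linear discriminant analysis, and recursive feature
elimination — plus the lion-optimization binary wrapper selector that
searches mask space by cross-validated classifier accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import clone
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold

from .loa import LOAConfig, optimize


@dataclass
class FeatureMatrix:
    """n x d real feature table with column labels."""

    values: np.ndarray
    feature_names: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("need n >= 1 samples and d >= 1 features")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal d")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self, labels=None) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        if labels is not None:
            frame["label"] = np.asarray(labels)
        return frame


@dataclass
class SelectionMask:
    """Binary mask naming the retained features."""

    mask: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise ValueError("a selection must retain at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.mask.sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.mask]

    def to_frame(self, feature_names) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_name": feature_names, "selected": self.mask.astype(int)}
        )


# ---------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    means: np.ndarray
    covariance: np.ndarray
    components: np.ndarray       # d x k, orthonormal columns
    explained_variance: np.ndarray  # k eigenvalues, descending


def population_covariance(X: np.ndarray) -> np.ndarray:
    """d x d covariance with 1/n normalization:
    sigma_jk = (1/n) * sum_i (x_j^(i) - mu_j)(x_k^(i) - mu_k)."""
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=0)
    return centered.T @ centered / X.shape[0]


def pca_reduce(X: FeatureMatrix, k: int):
    """Project onto the top-k eigenvectors of the 1/n covariance.

    Returns ``(model, reduced)`` with ``reduced`` the centered data
    times the d x k component matrix.
    """
    if X.n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= k <= X.d:
        raise ValueError(f"k must lie in [1, {X.d}], got {k}")
    means = X.values.mean(axis=0)
    cov = population_covariance(X.values)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    model = PCAModel(
        means=means,
        covariance=cov,
        components=eigvecs[:, :k],
        explained_variance=eigvals[:k],
    )
    reduced = (X.values - means) @ model.components
    return model, reduced


# ---------------------------------------------------------------------
# LDA


@dataclass
class LDAModel:
    class_means: np.ndarray      # B x d
    within_scatter: np.ndarray
    between_scatter: np.ndarray
    eigenvalues: np.ndarray      # descending
    projection: np.ndarray       # d x k
    projected: np.ndarray        # n x k


def lda_reduce(X: FeatureMatrix, y: np.ndarray, k: int,
               ridge: float = 1e-6) -> LDAModel:
    """Linear discriminant analysis in five steps: class means, within-
    and between-class scatter, eigen-decomposition of Sw^-1 Sb, sorting
    by eigenvalue, and the projection Y = X W.

    The within-class scatter inversion is ridge-regularized by
    ``ridge * trace(Sw)/d`` because deep-feature tables routinely have
    d >> n and a singular Sw.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if not 1 <= k <= X.d:
        raise ValueError(f"k must lie in [1, {X.d}], got {k}")
    d = X.d
    overall_mean = X.values.mean(axis=0)
    class_means = np.vstack([X.values[y == c].mean(axis=0) for c in classes])
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c, mean_c in zip(classes, class_means):
        Xc = X.values[y == c] - mean_c
        sw += Xc.T @ Xc
        diff = (mean_c - overall_mean)[:, None]
        sb += (y == c).sum() * (diff @ diff.T)
    reg = ridge * np.trace(sw) / d
    eigvals, eigvecs = scipy.linalg.eig(sb, sw + reg * np.eye(d))
    eigvals = eigvals.real
    eigvecs = eigvecs.real
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    W = eigvecs[:, order[:k]]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    return LDAModel(
        class_means=class_means,
        within_scatter=sw,
        between_scatter=sb,
        eigenvalues=eigvals,
        projection=W,
        projected=X.values @ W,
    )


# ---------------------------------------------------------------------
# RFE


def rfe_select(X: FeatureMatrix, y: np.ndarray, estimator, n_keep: int) -> SelectionMask:
    """Recursive feature elimination down to ``n_keep`` features.

    One feature is removed per round, ranked by the wrapped model's
    importances (squared coefficients for linear models).
    """
    if not 1 <= n_keep <= X.d:
        raise ValueError(f"n_keep must lie in [1, {X.d}], got {n_keep}")
    if not (hasattr(estimator, "coef_") or hasattr(estimator, "feature_importances_")
            or hasattr(type(estimator), "fit")):
        raise TypeError("estimator must be a fit/predict model with importances")
    selector = RFE(clone(estimator), n_features_to_select=n_keep, step=1)
    try:
        selector.fit(X.values, np.asarray(y))
    except (ValueError, AttributeError, RuntimeError) as exc:
        raise TypeError(
            "wrapped classifier does not expose per-feature importances"
        ) from exc
    return SelectionMask(mask=selector.support_, source="rfe")


# ---------------------------------------------------------------------
# LOA wrapper selection


def decode_mask(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decode of a real position in [0,1]^d: feature j is kept
    iff x_j > threshold; an all-zero decode falls back to the single
    argmax coordinate."""
    mask = np.asarray(position) > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def wrapper_cv_error(X: np.ndarray, y: np.ndarray, estimator,
                     mask: np.ndarray, folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold error of the wrapped classifier on the masked
    features — the quantity the lion optimizer minimizes."""
    y = np.asarray(y)
    Xm = np.asarray(X)[:, mask]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in splitter.split(Xm, y):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("cross-validation fold with a single class")
        model = clone(estimator)
        model.fit(Xm[train_idx], y[train_idx])
        correct += int((model.predict(Xm[test_idx]) == y[test_idx]).sum())
    return 1.0 - correct / y.size


def loa_select(X: FeatureMatrix, y: np.ndarray, estimator,
               loa_config: Optional[LOAConfig] = None, *,
               sparsity_weight: float = 0.0, folds: int = 5,
               seed: int = 0):
    """Lion-optimization wrapper feature selection.

    The optimizer searches [0,1]^d; a position decodes to the mask of
    coordinates above 0.5 and its fitness is the internal stratified
    k-fold error of the wrapped classifier on the masked features, plus
    an optional sparsity penalty ``sparsity_weight * selected/d``
    (0 by default). Fold assignment is fixed per run, so fitness is a
    pure function of the mask and repeated masks are memoized.

    Returns ``(mask, best_fitness, result)``.
    """
    if X.d < 2:
        raise ValueError("wrapper selection needs d >= 2 features")
    if loa_config is None:
        loa_config = LOAConfig(
            lower_bounds=np.zeros(X.d),
            upper_bounds=np.ones(X.d),
            population_size=40,
            num_prides=4,
            max_iterations=20,
            patience=8,
            seed=seed,
        )
    if loa_config.n_dim != X.d:
        raise ValueError("loa_config bounds must have length d")

    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        mask = decode_mask(position)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            error = wrapper_cv_error(X.values, y, estimator, mask,
                                     folds=folds, seed=seed)
            cache[key] = error + sparsity_weight * mask.sum() / X.d
        return cache[key]

    result = optimize(objective, loa_config)
    mask = decode_mask(result.best_position)
    return SelectionMask(mask=mask, source="loa"), result.best_fitness, result
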