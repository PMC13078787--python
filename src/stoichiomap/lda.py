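"""Linear discriminant analysis of preprocessed spectra by condition.

LDA finds the axes that maximize the ratio of between-condition to
within-condition scatter, reducing cells x channels spectra to at most
m-1 dimensions for m conditions. With far more channels than cells the
within-class scatter is singular, so the generalized eigenproblem is
solved inside a principal-component subspace of the total scatter (see
``ConditionLDA`` notes).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ConditionLDA", "condition_means", "growth_rate_correlation"]

_RANK_RTOL = 1e-10


class ConditionLDA(TransformerMixin, BaseEstimator):
    """Fisher discriminant axes for condition-labelled spectra.

    The generalized eigenproblem ``S_b w = lambda S_w w`` is solved after
    projecting the data onto the principal components of the total scatter.
    The retained dimensionality is capped at ``n_samples - n_classes`` (in
    addition to the numerical rank at relative tolerance 1e-10): inside the
    full-rank total-scatter subspace the within-class scatter still has rank
    at most ``n_samples - n_classes``, so without the cap the eigenproblem
    would be ill-posed whenever channels >> cells.

    Attributes
    ----------
    scalings_ : ndarray (n_channels, n_axes)
        Discriminant loadings mapped back to channel space. Each axis obeys
        the sign convention that its largest-magnitude loading is positive.
    eigenvalues_ : ndarray (n_axes,)
        Between/within scatter ratios, non-increasing and >= 0.
    class_means_ : ndarray (n_classes, n_axes)
        Projected mean score per condition (rows ordered as ``classes_``).
    classes_ : ndarray (n_classes,)
    grand_mean_ : ndarray (n_channels,)
    """

    def __init__(self, rank_rtol: float = _RANK_RTOL):
        self.rank_rtol = rank_rtol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x channels)")
        classes, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if classes.size < 2:
            raise ValueError("LDA needs at least 2 classes")
        if counts.min() < 2:
            small = classes[np.argmin(counts)]
            raise ValueError(f"class {small!r} has fewer than 2 cells")

        n, _ = X.shape
        self.grand_mean_ = X.mean(axis=0)
        Xc = X - self.grand_mean_

        # principal components of total scatter
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > self.rank_rtol * s[0])) if s.size and s[0] > 0 else 0
        r = min(rank, n - classes.size)
        if r == 0:
            warnings.warn("degenerate data: no usable total-scatter directions")
            self._set_empty(classes)
            return self
        V = Vt[:r].T
        Z = Xc @ V

        Sw = np.zeros((r, r))
        Sb = np.zeros((r, r))
        for c in range(classes.size):
            Zc = Z[y_idx == c]
            mc = Zc.mean(axis=0)
            dz = Zc - mc
            Sw += dz.T @ dz
            Sb += counts[c] * np.outer(mc, mc)

        if not np.any(np.abs(Sb) > self.rank_rtol * max(np.abs(Sw).max(), 1.0)):
            warnings.warn("identical class means: LDA returns zero axes")
            self._set_empty(classes)
            return self

        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        order = np.argsort(evals, kind="stable")[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = min(classes.size - 1, int(np.sum(evals > self.rank_rtol * max(evals[0], 1.0))))
        evals, evecs = np.clip(evals[:keep], 0.0, None), evecs[:, :keep]

        scalings = V @ evecs  # back to channel space
        # deterministic sign: largest-|loading| element positive
        for k in range(scalings.shape[1]):
            i = np.argmax(np.abs(scalings[:, k]))
            if scalings[i, k] < 0:
                scalings[:, k] = -scalings[:, k]

        self.scalings_ = scalings
        self.eigenvalues_ = evals
        self.classes_ = classes
        scores = Xc @ scalings
        self.class_means_ = np.vstack(
            [scores[y_idx == c].mean(axis=0) for c in range(classes.size)]
        )
        self.n_axes_ = scalings.shape[1]
        self.n_features_in_ = X.shape[1]
        return self

    def _set_empty(self, classes: np.ndarray) -> None:
        self.scalings_ = np.zeros((self.grand_mean_.size, 0))
        self.eigenvalues_ = np.zeros(0)
        self.classes_ = classes
        self.class_means_ = np.zeros((classes.size, 0))
        self.n_axes_ = 0
        self.n_features_in_ = self.grand_mean_.size

    def transform(self, X) -> np.ndarray:
        """Project spectra: center by the training grand mean, apply loadings."""
        check_is_fitted(self, "scalings_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} channels, model was fitted with "
                f"{self.n_features_in_}"
            )
        return (X - self.grand_mean_) @ self.scalings_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


def condition_means(
    scores: np.ndarray, labels: Sequence, condition_order: Sequence | None = None
) -> np.ndarray:
    """Mean score vector per condition (rows follow ``condition_order``)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if condition_order is None:
        condition_order = np.unique(labels)
    out = np.empty((len(condition_order), scores.shape[1]))
    for j, cond in enumerate(condition_order):
        mask = labels == cond
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no cells")
        out[j] = scores[mask].mean(axis=0)
    return out


class GrowthRateCorrelation(NamedTuple):
    r: float
    abs_r: float
    pvalue: float


def growth_rate_correlation(
    lda1_means: np.ndarray, growth_rates: np.ndarray
) -> GrowthRateCorrelation:
    """Pearson correlation of the first discriminant axis with growth rate.

    The sign of a discriminant axis is conventional, so |r| is reported
    alongside the signed value.
    """
    x = np.asarray(lda1_means, dtype=float)
    mu = np.asarray(growth_rates, dtype=float)
    if x.size != mu.size or x.size < 3:
        raise ValueError("need matching vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(mu) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, mu)
    return GrowthRateCorrelation(float(res.statistic), abs(float(res.statistic)), float(res.pvalue))
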