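"""Linear Raman-to-proteome correspondence.

The condition-mean proteome profile p_hat_j is modelled as an affine
function of the condition-mean discriminant-space Raman profile r_hat_j:

    p_hat_j = B . [1, r_hat_j]

with B an n x (K+1) coefficient matrix fitted per protein by ordinary
least squares (minimum-norm when underdetermined). Leave-one-out
cross-validation over conditions plus a permutation test validate the
correspondence; the coefficients normalized by their constant terms give
each protein a coordinate in the Raman-based proteome space Omega_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RamanProteomeRegression",
    "fit_B",
    "loocv",
    "LoocvReport",
    "permutation_test",
    "distance",
    "coefficient_proportionality",
]

_METRICS = ("euclidean_sq", "manhattan", "cosine_dist", "one_minus_pearson")


def distance(x: np.ndarray, y: np.ndarray, metric: str = "euclidean_sq") -> float:
    """Distance between two profiles.

    ``euclidean_sq`` is the squared Euclidean distance (the PRESS summand);
    ``cosine_dist`` is 1 - cosine similarity; ``one_minus_pearson`` is
    1 - Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("profiles have different lengths")
    if metric == "euclidean_sq":
        return float(np.sum((x - y) ** 2))
    if metric == "manhattan":
        return float(np.sum(np.abs(x - y)))
    if metric == "cosine_dist":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - np.dot(x, y) / (nx * ny))
    if metric == "one_minus_pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("Pearson distance undefined for a constant vector")
        return float(1.0 - np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


class RamanProteomeRegression(RegressorMixin, BaseEstimator):
    """Per-protein OLS of abundances on the Raman discriminant coordinates.

    Parameters
    ----------
    n_axes : int, default 4
        Number K of discriminant axes used (the first K columns of the
        condition-mean score matrix). The study-scale default uses the
        first four major axes; K = m-1 gives the full model, fitted as the
        minimum-norm least-squares solution when underdetermined.

    Attributes
    ----------
    B_ : ndarray (n_proteins, K+1)
        Column 0 holds the intercepts b_i0; columns 1..K the axis
        coefficients.
    """

    def __init__(self, n_axes: int = 4):
        self.n_axes = n_axes

    def _design(self, R: np.ndarray) -> np.ndarray:
        R = np.atleast_2d(np.asarray(R, dtype=float))
        if R.shape[1] < self.n_axes:
            raise ValueError(
                f"need at least {self.n_axes} Raman axes, got {R.shape[1]}"
            )
        return np.column_stack([np.ones(R.shape[0]), R[:, : self.n_axes]])

    def fit(self, R, P):
        """Fit on condition-mean Raman scores R (m x >=K) and profiles P (m x n)."""
        P = np.asarray(P, dtype=float)
        D = self._design(R)
        if P.shape[0] != D.shape[0]:
            raise ValueError("R and P must have one row per condition")
        if not np.any(np.abs(D) > 0):
            raise ValueError("design matrix has rank 0")
        sol, *_ = np.linalg.lstsq(D, P, rcond=None)  # minimum-norm when flat
        self.B_ = sol.T
        self.n_conditions_ = D.shape[0]
        return self

    def predict(self, R) -> np.ndarray:
        """Profiles B . [1, r_hat]; a single K-vector gives a single profile."""
        check_is_fitted(self, "B_")
        r = np.asarray(R, dtype=float)
        single = r.ndim == 1
        if single and r.size != self.n_axes:
            raise ValueError(f"expected a length-{self.n_axes} Raman vector")
        out = self._design(np.atleast_2d(r)[:, : self.n_axes] if not single else r[None, :]) @ self.B_.T
        return out[0] if single else out

    def normalized_coefficients(self, tolerance: float = 1e-8):
        """Omega_B coordinates beta_ik = b_ik / b_i0.

        Proteins whose intercept magnitude falls below
        ``tolerance * median(|b_0|)`` are excluded (their coordinates are
        unstable), never returned as NaN.

        Returns
        -------
        omega_b : ndarray (n_kept, K)
        kept : ndarray of kept protein indices
        excluded : ndarray of excluded protein indices
        """
        check_is_fitted(self, "B_")
        b0 = self.B_[:, 0]
        cut = tolerance * np.median(np.abs(b0))
        kept = np.flatnonzero(np.abs(b0) >= max(cut, np.finfo(float).tiny))
        if kept.size == 0:
            raise ValueError("all proteins excluded: every intercept is ~0")
        excluded = np.setdiff1d(np.arange(b0.size), kept)
        omega_b = self.B_[kept, 1:] / b0[kept, None]
        return omega_b, kept, excluded


def fit_B(P_hat: np.ndarray, R_hat: np.ndarray, n_axes: int = 4) -> RamanProteomeRegression:
    """Convenience wrapper: fit the correspondence model and return it."""
    return RamanProteomeRegression(n_axes=n_axes).fit(R_hat, P_hat)


@dataclass
class LoocvReport:
    """Leave-one-out cross-validation results over conditions."""

    predictions: np.ndarray  # m x n predicted profiles
    per_condition: dict  # metric -> length-m distance array
    overall: dict  # metric -> sum of distances
    B_average: np.ndarray  # average of the m leave-one-out coefficient matrices
    n_axes: int
    permutation_p: dict = field(default_factory=dict)  # metric -> p-value
    n_permutations: int = 0


def loocv(
    P_hat: np.ndarray,
    R_hat: np.ndarray,
    n_axes: int = 4,
    metrics: tuple[str, ...] = ("euclidean_sq",),
    n_permutations: int = 0,
    seed: int = 0,
) -> LoocvReport:
    """Hold out each condition in turn, refit B, predict the held-out profile.

    The overall error per metric is the sum over held-out conditions of
    dist(p_hat_j, p_hat_j^est). With ``n_permutations > 0`` a permutation
    test compares it against errors under random matchings of predictions
    to conditions.
    """
    P_hat = np.asarray(P_hat, dtype=float)
    R_hat = np.asarray(R_hat, dtype=float)
    m = P_hat.shape[0]
    if m < 3:
        raise ValueError("LOOCV needs at least 3 conditions")
    preds = np.empty_like(P_hat)
    B_sum = None
    for j in range(m):
        keep = np.arange(m) != j
        model = RamanProteomeRegression(n_axes=n_axes).fit(R_hat[keep], P_hat[keep])
        preds[j] = model.predict(R_hat[j, :n_axes])
        B_sum = model.B_ if B_sum is None else B_sum + model.B_
    per_condition = {
        met: np.array([distance(P_hat[j], preds[j], met) for j in range(m)])
        for met in metrics
    }
    overall = {met: float(v.sum()) for met, v in per_condition.items()}
    report = LoocvReport(
        predictions=preds,
        per_condition=per_condition,
        overall=overall,
        B_average=B_sum / m,
        n_axes=n_axes,
    )
    if n_permutations > 0:
        for met in metrics:
            report.permutation_p[met] = permutation_test(
                P_hat, preds, metric=met, n_permutations=n_permutations, seed=seed
            )
        report.n_permutations = n_permutations
    return report


def permutation_test(
    P_hat: np.ndarray,
    predictions: np.ndarray,
    metric: str = "euclidean_sq",
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """P(random matching of predictions to conditions does as well as observed).

    Permutations sigma are drawn uniformly (identity included); the p-value
    uses the add-one convention p = (1 + #{sigma: error_sigma <= observed})
    / (1 + n_permutations), so p is always in (0, 1].
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    P_hat = np.asarray(P_hat, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    m = P_hat.shape[0]
    # distance matrix: dist(p_hat_i, pred_j) for all pairs, so each
    # permutation is a trace over a column selection
    Dm = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            Dm[i, j] = distance(P_hat[i], predictions[j], metric)
    observed = float(np.trace(Dm))
    rng = np.random.default_rng(seed)
    count = 0
    rows = np.arange(m)
    for _ in range(n_permutations):
        sigma = rng.permutation(m)
        if Dm[rows, sigma].sum() <= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)


def coefficient_proportionality(
    B: np.ndarray | RamanProteomeRegression, group_indices: np.ndarray
):
    """Through-origin proportionality of axis coefficients to intercepts.

    For the proteins in ``group_indices``, regress each axis coefficient
    column b_.k on the intercept column b_.0 through the origin. A group
    that conserves stoichiometry perfectly has b_ik = c_k * b_i0 exactly,
    so every axis shows R^2 = 1.

    Returns
    -------
    slopes : ndarray (K,) of per-axis proportionality constants c_k
    r2 : ndarray (K,) of through-origin coefficients of determination
    """
    if isinstance(B, RamanProteomeRegression):
        B = B.B_
    B = np.asarray(B, dtype=float)
    idx = np.asarray(group_indices)
    if idx.size < 3:
        raise ValueError("group must have at least 3 members")
    b0 = B[idx, 0]
    denom = float(np.dot(b0, b0))
    if denom == 0:
        raise ValueError("degenerate group: all intercepts are zero")
    slopes = np.empty(B.shape[1] - 1)
    r2 = np.empty(B.shape[1] - 1)
    for k in range(1, B.shape[1]):
        bk = B[idx, k]
        c = float(np.dot(b0, bk)) / denom
        ss_tot = float(np.dot(bk, bk))
        ss_res = float(np.sum((bk - c * b0) ** 2))
        slopes[k - 1] = c
        r2[k - 1] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slopes, r2
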