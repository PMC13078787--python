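"""Comparing the Raman-based (Omega_B) and similarity-based (Omega_LE) structures.

The two (m-1)-dimensional proteome representations — normalized regression
coefficients and csLE coordinates — are related, after augmenting each with
its trivial axis, by an m x m orthogonal matrix Theta. Structural
similarity of the two spaces requires (i) Theta close to the identity and
(ii) proportionality between conservation centrality d and expression
generality g with the analytic slope ((sum_j d_j)/m)^{1/2}.

Theta is constructed operationally as the orthogonal polar factor of the
least-squares linear map between the two augmented protein representations.
Its closeness to the identity is scored against a Haar-random orthogonal
null through three diagnostics: a weighted-Pearson score on the Hadamard
square, cumulative off-diagonal band mass, and leading-principal-submatrix
mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correspondence import loocv
from .lda import ConditionLDA, condition_means
from .network import CosineLaplacianEmbedding

__all__ = [
    "compute_theta",
    "theta_report",
    "ThetaReport",
    "haar_orthogonal",
    "closeness_score",
    "offdiagonal_profile",
    "leading_submatrix_profile",
    "d_g_proportionality",
    "ProportionalityReport",
    "theta_from_dataset",
    "subsample_conditions",
]

_ORTHO_TOL = 1e-8


def compute_theta(
    le_coords: np.ndarray,
    le_trivial: np.ndarray,
    omega_b: np.ndarray,
) -> np.ndarray:
    """Orthogonal matrix relating the augmented Omega_LE and Omega_B coordinates.

    Both coordinate sets must cover the same proteins (rows aligned). The
    csLE side is augmented with its trivial (constant) eigenvector, the
    coefficient side with the constant column of ones; the least-squares
    map M solving [v0 | csLE] M ~= [1 | beta] is reduced to its orthogonal
    polar factor.
    """
    le_coords = np.asarray(le_coords, dtype=float)
    omega_b = np.asarray(omega_b, dtype=float)
    le_trivial = np.asarray(le_trivial, dtype=float).ravel()
    if le_coords.shape[0] != omega_b.shape[0] or le_trivial.size != le_coords.shape[0]:
        raise ValueError("coordinate sets must cover the same proteins (row-aligned)")
    if le_coords.shape[1] != omega_b.shape[1]:
        raise ValueError(
            f"axis counts differ: csLE has {le_coords.shape[1]}, "
            f"Omega_B has {omega_b.shape[1]}"
        )
    X_le = np.column_stack([le_trivial, le_coords])
    X_b = np.column_stack([np.ones(omega_b.shape[0]), omega_b])
    m = X_le.shape[1]
    for name, X in (("csLE", X_le), ("Omega_B", X_b)):
        if np.linalg.matrix_rank(X) < m:
            raise ValueError(f"{name} coordinates are rank-deficient")
    M, *_ = np.linalg.lstsq(X_le, X_b, rcond=None)
    U, _, Vt = np.linalg.svd(M)
    theta = U @ Vt
    if not np.allclose(theta.T @ theta, np.eye(m), atol=_ORTHO_TOL):
        raise RuntimeError("polar factor lost orthogonality")
    return theta


def haar_orthogonal(m: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """A Haar-distributed random orthogonal m x m matrix (QR with sign fix)."""
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = rng.standard_normal((m, m))
    Q, R = np.linalg.qr(Z)
    d = np.diagonal(R)
    return Q * np.where(d >= 0, 1.0, -1.0)


def closeness_score(Q: np.ndarray) -> float:
    """Identity-closeness of an orthogonal matrix via its Hadamard square.

    The Hadamard square W = Q o Q is treated as a 2-D histogram over
    coordinates (i, j) — total mass exactly m for orthogonal Q — and the
    weighted Pearson correlation of i with j is returned. The identity
    concentrates all mass on the diagonal and scores 1; the reversal
    permutation scores -1; Haar draws scatter around 0.
    """
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    if Q.shape != (m, m):
        raise ValueError("Q must be square")
    if m < 2:
        raise ValueError("closeness undefined for a 1 x 1 matrix")
    W = Q * Q
    total = W.sum()
    i = np.arange(m, dtype=float)
    wi = W.sum(axis=1)  # mass at row coordinate i
    wj = W.sum(axis=0)  # mass at column coordinate j
    Ei = (wi * i).sum() / total
    Ej = (wj * i).sum() / total
    cov = ((i - Ei)[:, None] * W * (i - Ej)[None, :]).sum() / total
    vari = (wi * (i - Ei) ** 2).sum() / total
    varj = (wj * (i - Ej) ** 2).sum() / total
    if vari <= 0 or varj <= 0:
        raise ValueError("degenerate weight distribution: zero variance")
    return float(cov / np.sqrt(vari * varj))


def offdiagonal_profile(Q: np.ndarray) -> np.ndarray:
    """Cumulative squared mass over diagonal bands, outermost pair first.

    Step t (t = 0..m-1) adds the +-(m-1-t) diagonals; the final step adds
    the main diagonal, after which the total is the squared Frobenius norm
    (equal to m for orthogonal Q). An identity-like matrix keeps the curve
    near zero until the last step.
    """
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    if Q.shape != (m, m):
        raise ValueError("Q must be square")
    sq = Q * Q
    steps = np.empty(m)
    for t in range(m):
        off = m - 1 - t
        band = np.trace(sq, offset=off)
        if off > 0:
            band += np.trace(sq, offset=-off)
        steps[t] = band
    return np.cumsum(steps)


def leading_submatrix_profile(Q: np.ndarray) -> np.ndarray:
    """Squared Frobenius mass of the k x k leading principal submatrix, k=1..m."""
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    if Q.shape != (m, m):
        raise ValueError("Q must be square")
    sq = Q * Q
    return np.array([sq[:k, :k].sum() for k in range(1, m + 1)])


@dataclass
class ThetaReport:
    theta: np.ndarray
    closeness: float
    null_scores: np.ndarray
    percentile: float  # fraction (in %) of null draws strictly below Theta's score
    offdiag_profile: np.ndarray
    offdiag_identity: np.ndarray
    offdiag_null_mean: np.ndarray
    leading_profile: np.ndarray
    leading_identity: np.ndarray
    leading_null_mean: np.ndarray


def theta_report(theta: np.ndarray, n_null: int = 1000, seed: int = 0) -> ThetaReport:
    """Score Theta against a Haar-random orthogonal null with all diagnostics."""
    theta = np.asarray(theta, dtype=float)
    m = theta.shape[0]
    if not np.allclose(theta.T @ theta, np.eye(m), atol=_ORTHO_TOL):
        raise ValueError("theta is not orthogonal")
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_null)
    off_sum = np.zeros(m)
    lead_sum = np.zeros(m)
    for t in range(n_null):
        Q = haar_orthogonal(m, rng)
        null_scores[t] = closeness_score(Q)
        off_sum += offdiagonal_profile(Q)
        lead_sum += leading_submatrix_profile(Q)
    score = closeness_score(theta)
    identity = np.eye(m)
    return ThetaReport(
        theta=theta,
        closeness=score,
        null_scores=null_scores,
        percentile=float(100.0 * np.mean(null_scores < score)),
        offdiag_profile=offdiagonal_profile(theta),
        offdiag_identity=offdiagonal_profile(identity),
        offdiag_null_mean=off_sum / n_null,
        leading_profile=leading_submatrix_profile(theta),
        leading_identity=leading_submatrix_profile(identity),
        leading_null_mean=lead_sum / n_null,
    )


@dataclass
class ProportionalityReport:
    slope: float  # analytic slope ((sum_j d_j) / m)^{1/2}
    residuals: np.ndarray  # d_i - slope * g_i
    spearman_r: float  # residuals vs growth rate at each protein's argmax condition
    spearman_p: float


def d_g_proportionality(
    d: np.ndarray,
    g: np.ndarray,
    m: int,
    growth_at_argmax: np.ndarray | None = None,
) -> ProportionalityReport:
    """Centrality-generality proportionality with its analytic slope.

    The slope is fixed analytically at ((sum_j d_j)/m)^{1/2}, not fitted.
    For a fully conserved uniform proteome (d_i = n, g_i = sqrt(m)) the
    slope is n/sqrt(m) and every residual vanishes. Residuals otherwise
    track the growth rate of each protein's most-expressed condition; pass
    those rates to get their Spearman correlation with the residuals.
    """
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if d.size == 0 or d.size != g.size:
        raise ValueError("d and g must be non-empty and of equal length")
    if m < 1:
        raise ValueError("m must be a positive condition count")
    slope = float(np.sqrt(d.sum() / m))
    residuals = d - slope * g
    r = p = np.nan
    if growth_at_argmax is not None:
        mu = np.asarray(growth_at_argmax, dtype=float)
        if mu.size != d.size:
            raise ValueError("growth_at_argmax must match the score table length")
        res = stats.spearmanr(residuals, mu)
        r, p = float(res.statistic), float(res.pvalue)
    return ProportionalityReport(slope=slope, residuals=residuals, spearman_r=r, spearman_p=p)


def _omega_b_from_B(B: np.ndarray, tolerance: float = 1e-8):
    """Normalized coefficients and kept-protein indices from a raw B matrix."""
    b0 = B[:, 0]
    cut = tolerance * np.median(np.abs(b0))
    kept = np.flatnonzero(np.abs(b0) >= max(cut, np.finfo(float).tiny))
    if kept.size == 0:
        raise ValueError("all proteins excluded: every intercept is ~0")
    return B[kept, 1:] / b0[kept, None], kept


def theta_from_dataset(
    proteome: pd.DataFrame,
    scores: np.ndarray,
    cell_conditions: np.ndarray,
    condition_order,
    use_loocv_average: bool = True,
) -> np.ndarray:
    """Theta for one dataset: full-axis Omega_B vs csLE on the same proteins.

    ``scores`` are per-cell discriminant coordinates with ``cell_conditions``
    labels; the correspondence model is fitted with all m-1 axes (minimum
    norm inside leave-one-out folds), averaged over folds by default.
    """
    m = proteome.shape[1]
    R_hat = condition_means(scores, cell_conditions, condition_order)[:, : m - 1]
    P_hat = proteome.to_numpy(dtype=float).T
    if use_loocv_average:
        B = loocv(P_hat, R_hat, n_axes=m - 1).B_average
    else:
        from .correspondence import RamanProteomeRegression

        B = RamanProteomeRegression(n_axes=m - 1).fit(R_hat, P_hat).B_
    omega_b, kept = _omega_b_from_B(B)
    emb = CosineLaplacianEmbedding(n_components=m - 1).fit(proteome)
    return compute_theta(emb.embedding_[kept], emb.trivial_vector_[kept], omega_b)


def subsample_conditions(
    proteome: pd.DataFrame,
    spectra_matrix: np.ndarray,
    cell_conditions: np.ndarray,
    sizes,
    reps: int = 10,
    seed: int = 0,
    n_null: int = 100,
) -> pd.DataFrame:
    """Theta closeness as a function of the number of conditions analyzed.

    For each subset size, draw ``reps`` random condition subsets, rerun the
    discriminant analysis on the subset's cells, refit the correspondence
    (all subset axes, leave-one-out averaged), re-embed the subset proteome
    with csLE, and score Theta's closeness to the identity. Returns one row
    per (size, rep) with the closeness score and its null percentile.
    """
    conds = np.asarray(proteome.columns)
    m = conds.size
    sizes = [int(s) for s in sizes]
    if any(s < 3 or s > m for s in sizes):
        raise ValueError(f"subset sizes must lie in [3, {m}]")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            subset = np.sort(rng.choice(m, size=size, replace=False))
            sub_conds = conds[subset]
            mask = np.isin(cell_conditions, sub_conds)
            lda = ConditionLDA().fit(spectra_matrix[mask], cell_conditions[mask])
            scores = lda.transform(spectra_matrix[mask])
            theta = theta_from_dataset(
                proteome[sub_conds], scores, cell_conditions[mask], sub_conds
            )
            score = closeness_score(theta)
            null = np.array(
                [closeness_score(haar_orthogonal(size, rng)) for _ in range(n_null)]
            )
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "closeness": score,
                    "null_percentile": float(100.0 * np.mean(null < score)),
                }
            )
    return pd.DataFrame(rows)
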