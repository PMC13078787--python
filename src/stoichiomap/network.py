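"""Stoichiometry-conservation network of expression profiles.

Each gene product i carries an m-dimensional non-negative expression
vector p_i across conditions. The cosine similarity

    A_ij = (p_i . p_j) / (||p_i||_2 ||p_j||_2)

equals 1 exactly when i and j keep a constant abundance ratio across all
conditions (perfect stoichiometry conservation). The complete graph
weighted by A supports:

* SCG extraction: connected components of the graph thresholded at a high
  similarity (default 0.995);
* conservation centrality d_i = sum_j A_ij (weighted degree);
* expression generality g_i = ||p_i||_1 / ||p_i||_2, in [1, sqrt(m)];
* the cosine-similarity Laplacian-eigenmap (csLE) embedding from the
  random-walk normalized Laplacian L_rw = I - D^-1 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SimilarityGraph",
    "cosine_matrix",
    "extract_scgs",
    "generality",
    "CosineLaplacianEmbedding",
    "within_group_condition_similarity",
    "pca_structure",
]

_NONTRIVIAL_TOL = 1e-8


def _as_matrix(P) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, ids) from a DataFrame or array of expression rows."""
    if isinstance(P, pd.DataFrame):
        return P.to_numpy(dtype=float), P.index.to_numpy()
    P = np.asarray(P, dtype=float)
    return P, np.arange(P.shape[0])


def _check_rows(X: np.ndarray, ids: np.ndarray) -> None:
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(f"negative abundance at protein {ids[i]!r}, column {j}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = ids[int(np.flatnonzero(norms == 0)[0])]
        raise ValueError(f"protein {bad!r} has an all-zero expression vector")


@dataclass
class SimilarityGraph:
    """Cosine-similarity adjacency with degrees and (optionally) components."""

    A: np.ndarray
    degree: np.ndarray
    ids: np.ndarray
    threshold: float | None = None
    components: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.A.shape[0]


def cosine_matrix(P) -> SimilarityGraph:
    """Pairwise cosine similarities of expression rows, with degree vector.

    The diagonal is set to exactly 1 (every node carries a unit self-loop),
    so the degree d_i = sum_j A_ij lies in [1, n] for non-negative data.
    """
    X, ids = _as_matrix(P)
    _check_rows(X, ids)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    A = np.clip(Xn @ Xn.T, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    return SimilarityGraph(A=A, degree=A.sum(axis=1), ids=ids)


def extract_scgs(graph: SimilarityGraph, threshold: float = 0.995) -> list[np.ndarray]:
    """Stoichiometrically conserved groups as thresholded connected components.

    Edges are pairs (i != j) with A_ij >= threshold. Components with at
    least two members are returned as arrays of ids, sorted by size
    descending (ties broken by smallest member index), so SCG 1 is the
    largest group — the homeostatic core. Singletons are dropped.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    adj = graph.A >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if members.size >= 2:
            comps.append(members)
    comps.sort(key=lambda mem: (-mem.size, mem.min()))
    graph.threshold = threshold
    graph.components = [graph.ids[mem] for mem in comps]
    return graph.components


def generality(P):
    """Expression generality g_i = ||p_i||_1 / ||p_i||_2 per gene product.

    Scale-invariant; equals 1 for a one-hot (fully condition-specific)
    vector and sqrt(m) for a uniform (fully general) vector.
    """
    X, ids = _as_matrix(P)
    _check_rows(X, ids)
    g = np.abs(X).sum(axis=1) / np.linalg.norm(X, axis=1)
    if isinstance(P, pd.DataFrame):
        return pd.Series(g, index=P.index, name="generality")
    return g


class CosineLaplacianEmbedding(TransformerMixin, BaseEstimator):
    """csLE: spectral embedding of the cosine-similarity complete graph.

    Eigenpairs of the random-walk Laplacian L_rw = I - D^-1 A are computed
    through the symmetric form D^-1/2 A D^-1/2 (same eigenvalues; the
    eigenvectors map back through D^-1/2). Since A has rank at most
    min(m, rank(P)), exactly min(m, rank(P)) - 1 nontrivial eigenvalues lie
    strictly in (0, 1); the remaining n - min(m, rank(P)) equal 1.

    Attributes
    ----------
    eigenvalues_ : ndarray (n_components,)
        Smallest nontrivial Laplacian eigenvalues, ascending.
    embedding_ : ndarray (n, n_components)
        csLE coordinates (columns csLE1, csLE2, ...), unit L2 norm, sign
        fixed so the largest-magnitude entry is positive.
    trivial_vector_ : ndarray (n,)
        Eigenvector of eigenvalue 0 (constant up to tolerance).
    n_informative_ : int
        How many of the returned eigenvalues are strictly below 1.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, P, y=None):
        if isinstance(P, SimilarityGraph):
            if self.n_components is None:
                raise ValueError("n_components is required when fitting from a graph")
            graph = P
            k = self.n_components
        else:
            graph = cosine_matrix(P)
            m = P.shape[1] if isinstance(P, pd.DataFrame) else np.asarray(P).shape[1]
            k = self.n_components if self.n_components is not None else m - 1
        d = graph.degree
        if np.any(d <= 0):
            raise ValueError("zero-degree node: embedding undefined")
        inv_sqrt_d = 1.0 / np.sqrt(d)
        M = graph.A * np.outer(inv_sqrt_d, inv_sqrt_d)
        M = (M + M.T) / 2.0
        w, V = scipy.linalg.eigh(M)  # ascending eigenvalues of D^-1/2 A D^-1/2
        lam = 1.0 - w[::-1]  # Laplacian eigenvalues, ascending
        V = V[:, ::-1]
        if k + 1 > lam.size:
            raise ValueError(f"cannot extract {k} axes from {lam.size} nodes")
        coords = inv_sqrt_d[:, None] * V[:, 1 : k + 1]
        coords /= np.linalg.norm(coords, axis=0, keepdims=True)
        for j in range(coords.shape[1]):
            i = np.argmax(np.abs(coords[:, j]))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        trivial = inv_sqrt_d * V[:, 0]
        trivial /= np.linalg.norm(trivial)
        if trivial[np.argmax(np.abs(trivial))] < 0:
            trivial = -trivial
        self.eigenvalues_ = lam[1 : k + 1]
        self.eigenvalues_full_ = lam
        self.embedding_ = coords
        self.trivial_vector_ = trivial
        self.degree_ = d
        self.ids_ = graph.ids
        self.n_informative_ = int(np.sum(self.eigenvalues_ < 1.0 - _NONTRIVIAL_TOL))
        return self

    def transform(self, P=None) -> np.ndarray:
        check_is_fitted(self, "embedding_")
        return self.embedding_

    def fit_transform(self, P, y=None, **fit_params):
        return self.fit(P).embedding_


def within_group_condition_similarity(
    P: pd.DataFrame, group_ids, measure: str = "pearson"
) -> pd.DataFrame:
    """Similarity of group-restricted expression profiles between condition pairs.

    For every unordered pair of conditions (m(m-1)/2 pairs), compare the two
    abundance vectors of the group's members under those conditions with
    Pearson correlation, Pearson correlation of log abundances, or cosine
    similarity. A strongly stoichiometry-conserving group scores near 1 for
    every pair.
    """
    if not isinstance(P, pd.DataFrame):
        P = pd.DataFrame(np.asarray(P, dtype=float))
    sub = P.loc[list(group_ids)] if group_ids is not None else P
    if sub.shape[0] < 2:
        raise ValueError("group must contain at least 2 gene products")
    X = sub.to_numpy(dtype=float)
    if measure == "pearson_log":
        if np.any(X <= 0):
            raise ValueError("log-scale Pearson requires strictly positive abundances")
        X = np.log(X)
    conds = list(sub.columns)
    rows = []
    for a in range(len(conds)):
        for b in range(a + 1, len(conds)):
            x, y = X[:, a], X[:, b]
            if measure in ("pearson", "pearson_log"):
                val = float(np.corrcoef(x, y)[0, 1])
            elif measure == "cosine":
                val = float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
            else:
                raise ValueError(f"unknown measure {measure!r}")
            rows.append((conds[a], conds[b], val))
    return pd.DataFrame(rows, columns=["condition_i", "condition_j", "similarity"])


def pca_structure(P, n_components: int | None = None) -> np.ndarray:
    """PCA scores of L2-normalized expression rows (structure comparison baseline).

    Rows are normalized to unit L2 norm first, so the decomposition acts on
    the same directional information as the cosine-similarity graph.
    """
    X, ids = _as_matrix(P)
    _check_rows(X, ids)
    if n_components is None:
        n_components = X.shape[1] - 1
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many gene products as conditions")
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    return PCA(n_components=n_components, svd_solver="full").fit_transform(Xn)
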