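"""Assumption-lean comparator clusterers: correlation K-means and
unnormalized-Laplacian spectral clustering.

Both operate on the dissimilarity ``d_ij = 1 - r_ij`` where ``r_ij`` is
the Pearson correlation between the connectivity profiles (rows) of ROIs
``i`` and ``j``. Neither thresholds the FC matrix nor assumes assortative
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DataError, FCCommError, NumericalError
from .types import FCMatrix, Partition

__all__ = [
    "DissimilarityMatrix",
    "SimilarityMatrix",
    "correlation_dissimilarity",
    "similarity_matrix",
    "graph_laplacian",
    "kmeans_fit",
    "spectral_fit",
    "KMeansResult",
]

_EPS = 1e-30


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric nonnegative profile dissimilarities, zero diagonal,
    entries in [0, 2] (1 - Pearson correlation)."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DataError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise DataError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(d) != 0.0):
            raise DataError("dissimilarity diagonal must be 0")
        if d.min() < -1e-10 or d.max() > 2.0 + 1e-10:
            raise DataError("dissimilarities must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Gaussian-kernel similarities ``exp(-d^2)``; entries in [exp(-4), 1]."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise DataError("similarity matrix must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise DataError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise DataError("similarity diagonal must be 1")
        if s.min() < np.exp(-4.0) - 1e-12:
            raise DataError("similarities must be >= exp(-4)")

    @property
    def n(self) -> int:
        return self.s.shape[0]


def correlation_dissimilarity(
    A: FCMatrix, exclude_self: bool = True
) -> DissimilarityMatrix:
    """``d_ij = 1 - Pearson(row_i, row_j)`` between connectivity profiles.

    With ``exclude_self=True`` (default) coordinates ``i`` and ``j`` are
    dropped from both rows before correlating: those positions carry the
    forced unit diagonal values ``A_ii = A_jj = 1``, which would otherwise
    bias the profile correlation. Closed-form corrections to the full-row
    sums make this O(n^2) rather than per-pair.
    """
    W = A.weights
    n = A.n
    if n < 3:
        raise FCCommError("row correlations need at least 3 ROIs")
    if exclude_self:
        # For pair (i, j) the retained coordinates are {1..n} \ {i, j}.
        # With unit diagonal: sum_i' = S_i - 1 - A_ij, sumsq_i' = Q_i - 1
        # - A_ij^2, cross' = (A @ A)_ij - 2 A_ij.
        npair = n - 2
        S = W.sum(axis=1)
        Q = (W**2).sum(axis=1)
        G = W @ W
        s1 = S[:, None] - 1.0 - W  # sum of row i over retained coords
        s2 = S[None, :] - 1.0 - W
        q1 = Q[:, None] - 1.0 - W**2
        q2 = Q[None, :] - 1.0 - W**2
        cross = G - 2.0 * W
        cov = cross - s1 * s2 / npair
        var1 = q1 - s1**2 / npair
        var2 = q2 - s2**2 / npair
        np.fill_diagonal(var1, 1.0)  # diagonal pairs are never used
        np.fill_diagonal(var2, 1.0)
        offd = ~np.eye(n, dtype=bool)
        if np.any(var1[offd] <= 1e-12):
            i = int(np.argwhere((var1 <= 1e-12) & offd)[0][0])
            raise DataError(f"ROI {i + 1} has a constant connectivity profile")
        r = cov / np.sqrt(var1 * var2)
    else:
        sd = W.std(axis=1)
        if np.any(sd == 0):
            i = int(np.argmax(sd == 0))
            raise DataError(f"ROI {i + 1} has a constant connectivity profile")
        r = np.corrcoef(W)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(np.clip(d, 0.0, 2.0))


def similarity_matrix(D: DissimilarityMatrix) -> SimilarityMatrix:
    """Gaussian kernel ``S_ij = exp(-d_ij^2)`` on profile dissimilarities."""
    return SimilarityMatrix(np.exp(-D.d**2))


def graph_laplacian(S: SimilarityMatrix) -> np.ndarray:
    """Unnormalized Laplacian ``L = D - S`` with degrees excluding self.

    ``D_ii = sum_{j != i} S_ij``; the similarity diagonal is zeroed first,
    so every row of ``L`` sums to zero and ``L`` is PSD.
    """
    s0 = S.s.copy()
    np.fill_diagonal(s0, 0.0)
    return np.diag(s0.sum(axis=1)) - s0


@dataclass(frozen=True)
class KMeansResult:
    """Best-of-restarts K-means output."""

    partition: Partition
    objective: float  # sum of point-to-centroid dissimilarities
    n_iter: int
    seed: int
    objective_trace: np.ndarray = None  # per-iteration objective, non-increasing


def _corr_to_centroids(Y: np.ndarray, cent: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between every row of Y and every centroid."""
    Zy = Y - Y.mean(axis=1, keepdims=True)
    Zy /= np.linalg.norm(Zy, axis=1, keepdims=True) + _EPS
    Zc = cent - cent.mean(axis=1, keepdims=True)
    Zc /= np.linalg.norm(Zc, axis=1, keepdims=True) + _EPS
    return 1.0 - Zy @ Zc.T


def _repair_empty(new, d, K):
    """Re-seed each empty cluster at the point farthest from its centroid,
    never stealing the sole member of another cluster."""
    n = new.size
    for k in range(K):
        if np.any(new == k):
            continue
        counts = np.bincount(new, minlength=K)
        movable = counts[new] > 1
        cand = np.where(movable)[0]
        far = int(cand[np.argmax(d[cand, new[cand]])])
        new[far] = k
    return new


def _lloyd_corr(Y, K, rng, max_iter):
    """One seeded Lloyd run with the 1 - correlation dissimilarity.

    The arithmetic-mean centroid is a surrogate minimizer under the
    correlation metric, so the objective is re-checked every iteration
    and the loop stops (keeping the previous assignment) if it would
    increase; the recorded trace is therefore non-increasing.
    """
    n = Y.shape[0]
    cent = Y[rng.choice(n, size=K, replace=False)].copy()
    labels = None
    prev_obj = np.inf
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        d = _corr_to_centroids(Y, cent)
        new = _repair_empty(np.argmin(d, axis=1), d, K)
        obj = float(d[np.arange(n), new].sum())
        if obj > prev_obj + 1e-12:
            break  # surrogate centroid step overshot; keep previous state
        trace.append(obj)
        if labels is not None and np.array_equal(new, labels):
            prev_obj = obj
            break
        labels, prev_obj = new, obj
        for k in range(K):
            cent[k] = Y[labels == k].mean(axis=0)
    return labels, prev_obj, it, np.asarray(trace)


def kmeans_fit(
    A: FCMatrix,
    K: int,
    n_restarts: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> KMeansResult:
    """Correlation K-means on the rows of the FC matrix.

    Lloyd iterations: assign each ROI row to the centroid with smallest
    ``1 - Pearson`` dissimilarity, recompute centroids as arithmetic means
    of member rows, stop when assignments stabilize. Initial centroids are
    K distinct ROI rows drawn at random per restart; the best restart by
    within-cluster dissimilarity sum wins. Deterministic given ``seed``.
    """
    if K > A.n:
        raise FCCommError(f"K={K} exceeds number of ROIs n={A.n}")
    if K < 1:
        raise FCCommError("K must be >= 1")
    Y = A.weights
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]).generate_state(1)[0])
        labels, obj, it, trace = _lloyd_corr(Y, K, rng, max_iter)
        if best is None or obj < best[1]:
            best = (labels, obj, it, trace)
    return KMeansResult(
        partition=Partition(best[0] + 1, K),
        objective=best[1],
        n_iter=best[2],
        seed=seed,
        objective_trace=best[3],
    )


def _lloyd_euclid(X, K, rng, max_iter=300):
    """Euclidean Lloyd on embedded rows (used by spectral clustering)."""
    n = X.shape[0]
    cent = X[rng.choice(n, size=K, replace=False)].copy()
    labels = None
    for _ in range(max_iter):
        d = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        new = _repair_empty(np.argmin(d, axis=1), d, K)
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
        for k in range(K):
            cent[k] = X[labels == k].mean(axis=0)
    d = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
    obj = float(d[np.arange(n), labels].sum())
    return labels, obj


def spectral_fit(
    A: FCMatrix,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    exclude_self: bool = True,
) -> Partition:
    """Unnormalized spectral clustering of the FC matrix.

    Pipeline: profile dissimilarities -> Gaussian-kernel similarities ->
    unnormalized Laplacian ``L = D - S`` -> eigenvectors of the K
    eigenvalues of smallest magnitude -> Euclidean K-means on the
    ``n x K`` embedding rows (multi-restart, seeded). Embedding rows are
    not length-normalized (unnormalized algorithm).
    """
    if K > A.n:
        raise FCCommError(f"K={K} exceeds number of ROIs n={A.n}")
    if K < 1:
        raise FCCommError("K must be >= 1")
    D = correlation_dissimilarity(A, exclude_self=exclude_self)
    L = graph_laplacian(similarity_matrix(D))
    try:
        evals, evecs = scipy.linalg.eigh(L)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"Laplacian eigendecomposition failed: {exc}") from exc
    order = np.argsort(np.abs(evals), kind="stable")[:K]
    X = evecs[:, order]
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]).generate_state(1)[0])
        labels, obj = _lloyd_euclid(X, K, rng)
        if best is None or obj < best[1]:
            best = (labels, obj)
    return Partition(best[0] + 1, K)
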