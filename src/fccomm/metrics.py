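"""Partition-quality and partition-comparison indices.

Quality indices (silhouette, Calinski-Harabasz, C-index, Dunn) score a
single partition against a dissimilarity matrix; modularity scores it
against the weighted adjacency itself. Comparison measures (VI distance,
NMI, Hamming distance with optimal relabeling) compare two partitions.
All logarithms are natural.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy

from .baselines import DissimilarityMatrix
from .errors import FCCommError, UndefinedIndexError
from .types import FCMatrix, Partition

__all__ = [
    "silhouette",
    "modularity",
    "vi_distance",
    "nmi",
    "ch_index",
    "c_index",
    "dunn_index",
    "hamming_distance",
    "contingency",
]


def _check_same_n(z1: Partition, z2: Partition) -> None:
    if z1.n != z2.n:
        raise FCCommError(f"partition lengths differ: {z1.n} != {z2.n}")


def silhouette(D: DissimilarityMatrix, z: Partition) -> float:
    """Mean silhouette width: average of (b_i - a_i)/max(a_i, b_i).

    ``a_i`` is the mean dissimilarity of ROI i to the other members of its
    community; ``b_i`` the smallest mean dissimilarity to any other
    community. ROIs in singleton communities score 0 (the common
    convention). Undefined for a single community.
    """
    if z.n != D.n:
        raise FCCommError("partition length does not match matrix size")
    if z.n_used < 2:
        raise UndefinedIndexError("silhouette needs at least 2 communities")
    d = D.d
    n = z.n
    labels = z.labels
    used = np.unique(labels)
    # per-community mean distance from every vertex: n x K_used
    sums = np.stack([d[:, labels == k].sum(axis=1) for k in used], axis=1)
    counts = np.array([(labels == k).sum() for k in used])
    own = np.searchsorted(used, labels)
    scores = np.zeros(n)
    for i in range(n):
        k = own[i]
        if counts[k] == 1:
            continue  # singleton: a(i) undefined, score 0
        a = sums[i, k] / (counts[k] - 1)
        others = [sums[i, s] / counts[s] for s in range(len(used)) if s != k]
        b = min(others)
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())


def modularity(A: FCMatrix, z: Partition, zero_diagonal: bool = True) -> float:
    """Weighted Newman-Girvan modularity Q.

    ``Q = (1/2m) sum_ij (A_ij - d_i d_j / 2m) 1{z_i = z_j}`` over ordered
    pairs. The unit self-weights are artifacts of the correlation matrix,
    so with ``zero_diagonal=True`` (default) the diagonal is zeroed before
    computing degrees and m; negative weights enter as-is.
    """
    if z.n != A.n:
        raise FCCommError("partition length does not match matrix size")
    W = A.weights.copy()
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    if two_m == 0:
        raise UndefinedIndexError("modularity undefined for total weight 0")
    deg = W.sum(axis=1)
    same = z.labels[:, None] == z.labels[None, :]
    Q = np.sum((W - np.outer(deg, deg) / two_m) * same) / two_m
    return float(Q)


def contingency(z1: Partition, z2: Partition) -> np.ndarray:
    """K1 x K2 contingency table of joint label counts."""
    _check_same_n(z1, z2)
    C = np.zeros((z1.K, z2.K))
    np.add.at(C, (z1.labels - 1, z2.labels - 1), 1.0)
    return C


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(xlogy(p, p)))


def vi_distance(z1: Partition, z2: Partition) -> float:
    """Variation of information: ``H(C1) + H(C2) - 2 I(C1, C2)``.

    An entropy-based metric on partitions (natural log); zero iff the
    partitions agree up to a relabeling of communities.
    """
    C = contingency(z1, z2) / z1.n
    p1 = C.sum(axis=1)
    p2 = C.sum(axis=0)
    h1, h2 = _entropy(p1), _entropy(p2)
    mi = float(np.sum(xlogy(C, C)) - np.sum(xlogy(p1, p1)) - np.sum(xlogy(p2, p2)))
    return max(h1 + h2 - 2.0 * mi, 0.0)


def nmi(z1: Partition, z2: Partition) -> float:
    """Normalized mutual information with geometric-mean normalization.

    ``I(C1, C2) / sqrt(H(C1) H(C2))``; defined as 1 when both partitions
    are single-community (identical trivial structure) and 0 when exactly
    one is.
    """
    C = contingency(z1, z2) / z1.n
    p1 = C.sum(axis=1)
    p2 = C.sum(axis=0)
    h1, h2 = _entropy(p1), _entropy(p2)
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    mi = float(np.sum(xlogy(C, C)) - np.sum(xlogy(p1, p1)) - np.sum(xlogy(p2, p2)))
    return float(np.clip(mi / np.sqrt(h1 * h2), 0.0, 1.0))


def ch_index(D: DissimilarityMatrix, z: Partition) -> float:
    """Calinski-Harabasz pseudo-F ratio on squared dissimilarities.

    ``CH = (SSA/(K-1)) / (SSW/(n-K))`` with ``SSW = sum_k (1/n_k)
    sum_{i<j in C_k} d_ij^2`` and ``SSA = SST - SSW``,
    ``SST = (1/n) sum_{i<j} d_ij^2``. Returns +inf when SSW is zero
    (perfectly compact communities).
    """
    if z.n != D.n:
        raise FCCommError("partition length does not match matrix size")
    K = z.n_used
    n = z.n
    if K < 2 or K > n - 1:
        raise UndefinedIndexError("CH index needs 2 <= K <= n-1 used communities")
    d2 = D.d**2
    iu = np.triu_indices(n, k=1)
    sst = d2[iu].sum() / n
    ssw = 0.0
    for k in np.unique(z.labels):
        idx = np.where(z.labels == k)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    if ssw == 0.0:
        return float("inf")
    ssa = sst - ssw
    return float((ssa / (K - 1)) / (ssw / (n - K)))


def c_index(D: DissimilarityMatrix, z: Partition) -> float:
    """C-index: ``(SW - Smin) / (Smax - Smin)`` in [0, 1].

    ``SW`` is the sum of within-community pairwise dissimilarities; with
    ``NW`` within pairs, ``Smin``/``Smax`` are the sums of the NW smallest
    and largest of *all* pairwise dissimilarities.
    """
    if z.n != D.n:
        raise FCCommError("partition length does not match matrix size")
    n = z.n
    iu = np.triu_indices(n, k=1)
    same = z.labels[iu[0]] == z.labels[iu[1]]
    nw = int(same.sum())
    if nw == 0:
        raise UndefinedIndexError("C-index undefined with no within pairs")
    if nw >= iu[0].size:
        raise UndefinedIndexError("C-index undefined with only within pairs")
    all_d = np.sort(D.d[iu])
    sw = float(D.d[iu][same].sum())
    smin = float(all_d[:nw].sum())
    smax = float(all_d[-nw:].sum())
    if smax == smin:
        raise UndefinedIndexError("C-index undefined: all dissimilarities equal")
    return float(np.clip((sw - smin) / (smax - smin), 0.0, 1.0))


def dunn_index(D: DissimilarityMatrix, z: Partition) -> float:
    """Dunn index: min between-community single-linkage distance over the
    maximum community diameter."""
    if z.n != D.n:
        raise FCCommError("partition length does not match matrix size")
    used = np.unique(z.labels)
    if used.size < 2:
        raise UndefinedIndexError("Dunn index needs at least 2 communities")
    groups = [np.where(z.labels == k)[0] for k in used]
    diam = 0.0
    for idx in groups:
        if idx.size > 1:
            diam = max(diam, float(D.d[np.ix_(idx, idx)].max()))
    if diam == 0.0:
        raise UndefinedIndexError("Dunn index undefined: all communities singletons")
    sep = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            sep = min(sep, float(D.d[np.ix_(groups[a], groups[b])].min()))
    return float(sep / diam)


def hamming_distance(z1: Partition, z2: Partition) -> tuple[float, np.ndarray]:
    """Minimum mismatch proportion over all relabelings of ``z2``.

    Builds the label-agreement matrix, solves the assignment problem
    maximizing matches (Hungarian algorithm), and returns the minimized
    mismatch fraction together with the optimal permutation ``perm``:
    ``perm[b - 1]`` is the new (z1-aligned) label for old z2 label ``b``.
    """
    _check_same_n(z1, z2)
    K = max(z1.K, z2.K)
    C = np.zeros((K, K))
    np.add.at(C, (z1.labels - 1, z2.labels - 1), 1.0)
    rows, cols = linear_sum_assignment(-C)
    matches = C[rows, cols].sum()
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows + 1  # z2 label b -> z1 label
    return float(1.0 - matches / z1.n), perm
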