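"""Core data containers: FC matrices, partitions, block parameters.

Conventions
-----------
* An FC (functional-connectivity) matrix is a dense symmetric ``n x n``
  matrix of pairwise temporal correlations between regions of interest
  (ROIs), with a unit diagonal. It is treated as the weighted adjacency
  matrix of a complete graph; no thresholding is ever applied.
* Community labels are 1-based integers in ``{1..K}``, stored alongside the
  declared community count ``K``. A partition may *use* fewer than ``K``
  distinct labels (an "invalid" solution in the model-selection sense);
  the declared ``K`` is what the fitting routine was asked for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["FCMatrix", "Partition", "BlockParams"]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric weighted adjacency matrix of temporal correlations.

    Parameters
    ----------
    weights
        ``n x n`` real matrix; must be symmetric with unit diagonal.
    roi_names
        Optional length-``n`` sequence of ROI identifiers.
    """

    weights: np.ndarray
    roi_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError(f"FC matrix must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise DataError("FC matrix needs at least 2 ROIs")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise DataError(f"non-finite FC entry at row {i + 1}, column {j + 1}")
        if not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0.0):
            i, j = np.argwhere(np.abs(w - w.T) > _SYM_TOL)[0]
            raise DataError(
                f"FC matrix not symmetric: A[{i + 1}][{j + 1}] != A[{j + 1}][{i + 1}]"
            )
        if not np.allclose(np.diag(w), 1.0, atol=_SYM_TOL, rtol=0.0):
            i = int(np.argmax(np.abs(np.diag(w) - 1.0)))
            raise DataError(f"FC diagonal must be 1, got {w[i, i]} at ROI {i + 1}")
        if self.roi_names is not None:
            names = tuple(str(x) for x in self.roi_names)
            if len(names) != w.shape[0]:
                raise DataError("roi_names length does not match matrix size")
            object.__setattr__(self, "roi_names", names)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def offdiag(self) -> np.ndarray:
        """Weights with the (non-random, unit) diagonal zeroed out."""
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return w


@dataclass(frozen=True)
class Partition:
    """Community assignment: 1-based labels plus the declared count ``K``."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 1 or lab.size == 0:
            raise DataError("labels must be a nonempty 1-D vector")
        if self.K < 1:
            raise DataError(f"K must be >= 1, got {self.K}")
        if lab.min() < 1 or lab.max() > self.K:
            raise DataError(
                f"labels must lie in 1..{self.K}, got range "
                f"[{lab.min()}, {lab.max()}]"
            )

    @classmethod
    def from_labels(cls, labels, K: int | None = None) -> "Partition":
        lab = np.asarray(labels, dtype=np.int64)
        return cls(lab, int(lab.max()) if K is None else int(K))

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_used(self) -> int:
        """Number of distinct labels actually used."""
        return int(np.unique(self.labels).size)

    def sizes(self) -> np.ndarray:
        """Member count of each community 1..K (zeros for unused labels)."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    def relabeled(self, perm: np.ndarray) -> "Partition":
        """Apply a label permutation: new label of ROI i is ``perm[old-1]``."""
        perm = np.asarray(perm, dtype=np.int64)
        if perm.size < self.K:
            raise DataError("permutation shorter than K")
        return Partition(perm[self.labels - 1], self.K)


@dataclass(frozen=True)
class BlockParams:
    """Per-block-pair Gaussian edge-weight parameters.

    ``mu[a, b]`` is the mean and ``sigma2[a, b]`` the variance of edge
    weights between communities ``a+1`` and ``b+1``; both matrices are
    ``K x K`` symmetric and ``sigma2`` strictly positive.
    """

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        s2 = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", s2)
        for name, m in (("mu", mu), ("sigma2", s2)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise DataError(f"{name} must be square, got shape {m.shape}")
            if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0.0):
                raise DataError(f"{name} must be symmetric")
        if mu.shape != s2.shape:
            raise DataError("mu and sigma2 must have the same shape")
        if np.any(s2 <= 0.0):
            raise DataError("sigma2 entries must be strictly positive")

    @property
    def K(self) -> int:
        return self.mu.shape[0]
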