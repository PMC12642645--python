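"""Synthetic connectome generator with planted block structure.

Emulates the simulation design used throughout the package's benchmark:
``n = 100`` ROIs split into ``K = 5`` planted communities of sizes
30/15/25/20/10, with every edge weight drawn from a normal distribution
whose mean and variance depend only on the community pair of its endpoints.
Block means are drawn once per network from configurable ranges chosen to
resemble within-/between-system correlation levels seen in adult
resting-state cohorts; see ``docs/methods.md``.
"""

from __future__ import annotations

import numpy as np

from .errors import FCCommError
from .types import BlockParams, FCMatrix, Partition

__all__ = [
    "DEFAULT_SIZES",
    "DEFAULT_WITHIN_MEAN_RANGE",
    "DEFAULT_BETWEEN_MEAN_RANGE",
    "DEFAULT_SD_RANGE",
    "make_planted_partition",
    "make_block_params",
    "sample_fc_matrix",
    "planted_network",
]

#: Planted community sizes of the reference simulation (n = 100, K = 5).
DEFAULT_SIZES = (30, 15, 25, 20, 10)
#: Within-community mean edge-weight range (correlation units).
DEFAULT_WITHIN_MEAN_RANGE = (0.3, 0.6)
#: Between-community mean edge-weight range.
DEFAULT_BETWEEN_MEAN_RANGE = (-0.05, 0.2)
#: Edge-weight standard-deviation range (variance is the square of the draw).
DEFAULT_SD_RANGE = (0.05, 0.15)


def make_planted_partition(sizes, shuffle_seed: int | None = None) -> Partition:
    """Ground-truth partition with ``sizes[k]`` members in community ``k+1``.

    Members are contiguous by community (ROIs ``1..sizes[0]`` get label 1,
    and so on). Downstream methods are permutation-equivariant, so the
    contiguous layout is a pure convenience; pass ``shuffle_seed`` to apply
    a seeded random permutation of ROI order instead.
    """
    sizes = [int(s) for s in sizes]
    if len(sizes) == 0:
        raise FCCommError("sizes must be nonempty")
    if any(s <= 0 for s in sizes):
        raise FCCommError(f"all community sizes must be positive, got {sizes}")
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        labels = rng.permutation(labels)
    return Partition(labels, K=len(sizes))


def _check_interval(name: str, iv) -> tuple[float, float]:
    lo, hi = float(iv[0]), float(iv[1])
    if lo > hi:
        raise FCCommError(f"{name} interval is inverted: ({lo}, {hi})")
    return lo, hi


def make_block_params(
    K: int,
    within_mean_range=DEFAULT_WITHIN_MEAN_RANGE,
    between_mean_range=DEFAULT_BETWEEN_MEAN_RANGE,
    sd_range=DEFAULT_SD_RANGE,
    seed: int = 0,
) -> BlockParams:
    """Draw symmetric block mean/variance matrices from uniform ranges.

    Diagonal (within-community) means come from ``within_mean_range``,
    off-diagonal from ``between_mean_range``; standard deviations come from
    ``sd_range`` and are squared into variances. Deterministic given
    ``seed``.
    """
    if K < 1:
        raise FCCommError(f"K must be >= 1, got {K}")
    wlo, whi = _check_interval("within_mean_range", within_mean_range)
    blo, bhi = _check_interval("between_mean_range", between_mean_range)
    slo, shi = _check_interval("sd_range", sd_range)
    if slo <= 0:
        raise FCCommError("sd_range must be strictly positive")

    rng = np.random.default_rng(seed)
    mu = np.zeros((K, K))
    # Fixed draw order: diagonal first, then upper triangle row by row.
    mu[np.diag_indices(K)] = rng.uniform(wlo, whi, size=K)
    iu = np.triu_indices(K, k=1)
    mu[iu] = rng.uniform(blo, bhi, size=iu[0].size)
    mu = mu + np.triu(mu, k=1).T

    sd = np.zeros((K, K))
    iu0 = np.triu_indices(K)
    sd[iu0] = rng.uniform(slo, shi, size=iu0[0].size)
    sd = sd + np.triu(sd, k=1).T
    return BlockParams(mu=mu, sigma2=sd**2)


def sample_fc_matrix(
    partition: Partition,
    params: BlockParams,
    seed: int = 0,
    clip: bool = True,
) -> FCMatrix:
    """Sample a symmetric FC matrix from the planted Gaussian block model.

    Each upper-triangle entry ``A[i, j]`` is drawn from
    ``Normal(mu[z_i, z_j], sigma2[z_i, z_j])``, the matrix is symmetrized
    and the diagonal set to 1. With ``clip=True`` (default) draws are
    clipped to ``[-1, 1]`` so entries stay interpretable as correlations;
    pass ``clip=False`` for the pure Gaussian model.
    """
    if int(partition.labels.max()) > params.K:
        raise FCCommError(
            f"partition uses label {partition.labels.max()} but params have "
            f"K={params.K}"
        )
    n = partition.n
    z = partition.labels - 1
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    means = params.mu[z[iu[0]], z[iu[1]]]
    sds = np.sqrt(params.sigma2[z[iu[0]], z[iu[1]]])
    draws = rng.normal(means, sds)
    if clip:
        draws = np.clip(draws, -1.0, 1.0)
    w = np.zeros((n, n))
    w[iu] = draws
    w = w + w.T
    np.fill_diagonal(w, 1.0)
    return FCMatrix(w)


def planted_network(
    sizes=DEFAULT_SIZES,
    within_mean_range=DEFAULT_WITHIN_MEAN_RANGE,
    between_mean_range=DEFAULT_BETWEEN_MEAN_RANGE,
    sd_range=DEFAULT_SD_RANGE,
    seed: int = 0,
    clip: bool = True,
) -> tuple[FCMatrix, Partition, BlockParams]:
    """Convenience wrapper: partition + block params + sampled FC matrix.

    Block parameters and edge noise use independent streams derived from
    ``seed``, so the same seed always yields the same network.
    """
    ss = np.random.SeedSequence(seed)
    s_params, s_edges = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    part = make_planted_partition(sizes)
    params = make_block_params(
        len(sizes), within_mean_range, between_mean_range, sd_range, seed=s_params
    )
    A = sample_fc_matrix(part, params, seed=s_edges, clip=clip)
    return A, part, params
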