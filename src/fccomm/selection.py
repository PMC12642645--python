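"""Choosing the number of communities K by bootstrap likelihood differences.

For each candidate K a pool of criterion values is collected from the
valid solutions of a multi-restart WSBM ensemble. For every transition
K -> K+1, percentile bootstrap confidence intervals of the difference in
criterion values are formed; the selected K* is the smallest K at which
the interval is no longer strictly positive — i.e. adding a community no
longer yields a significant improvement. The criterion defaults to the
ELBO (VB's approximation of log P(A | M), making successive differences
approximate log Bayes factors); the plug-in log-likelihood is available
as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FCCommError
from .types import FCMatrix
from .wsbm import EnsembleResult, WSBMFit, WSBMPrior, fit_ensemble

__all__ = ["KSelectionResult", "bootstrap_diff_ci", "select_k", "best_fit"]


def bootstrap_diff_ci(
    pool_k,
    pool_k1,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    mode: str = "pairs",
) -> tuple[float, float]:
    """Percentile bootstrap CI of the criterion difference between two pools.

    With ``mode="pairs"`` (default) each replicate draws one value with
    replacement from each pool and records ``pool_k1 - pool_k``; with
    ``mode="means"`` each replicate records the difference of resampled
    pool means. Returns the (alpha/2, 1-alpha/2) percentile interval,
    deterministic given ``seed``.
    """
    pool_k = np.asarray(pool_k, dtype=float)
    pool_k1 = np.asarray(pool_k1, dtype=float)
    if pool_k.size == 0 or pool_k1.size == 0:
        raise FCCommError("bootstrap_diff_ci needs nonempty pools")
    if n_boot < 1:
        raise FCCommError("n_boot must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise FCCommError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "pairs":
        reps = rng.choice(pool_k1, size=n_boot) - rng.choice(pool_k, size=n_boot)
    elif mode == "means":
        reps = rng.choice(pool_k1, size=(n_boot, pool_k1.size)).mean(
            axis=1
        ) - rng.choice(pool_k, size=(n_boot, pool_k.size)).mean(axis=1)
    else:
        raise FCCommError(f"unknown bootstrap mode {mode!r}")
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass(frozen=True)
class KSelectionResult:
    """Outcome of the bootstrap K-selection procedure."""

    k_grid: tuple[int, ...]
    pools: dict  # K -> np.ndarray of criterion values from valid runs
    n_invalid: dict  # K -> number of discarded (invalid) runs
    diffs_ci: tuple  # ((K, K+1, lower, upper) per consecutive pair; None bounds
    #                   when the K+1 pool was empty)
    chosen_k: int
    n_boot: int
    alpha: float
    seed: int
    statistic: str
    no_overlap_fallback: bool = False  # True when no transition qualified
    ensembles: dict | None = None  # K -> EnsembleResult when kept

    @property
    def chosen_ensemble(self) -> EnsembleResult | None:
        if self.ensembles is None:
            return None
        return self.ensembles.get(self.chosen_k)


def _criterion(fit: WSBMFit, statistic: str) -> float:
    if statistic == "elbo":
        return fit.elbo
    if statistic == "loglik":
        return fit.loglik
    raise FCCommError(f"unknown selection statistic {statistic!r}")


def select_k(
    A: FCMatrix,
    k_grid=range(2, 21),
    n_runs: int = 1000,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    prior: WSBMPrior | None = None,
    n_trials: int = 5,
    statistic: str = "elbo",
    mode: str = "pairs",
    keep_fits: bool = True,
) -> KSelectionResult:
    """Select the number of communities via bootstrap criterion differences.

    For each K in the ascending ``k_grid``, fits a ``fit_ensemble`` of
    ``n_runs`` members and pools the criterion values of the valid
    solutions. The chosen K* is the smallest K whose K -> K+1 interval is
    not strictly positive (it contains 0 or lies below it), or — when the
    K+1 pool is empty — the K at which valid (K+1)-community solutions
    ceased to exist. If every transition shows a significant improvement,
    the grid maximum is returned with ``no_overlap_fallback=True``.

    Seeds for the per-K ensembles and per-transition bootstraps are all
    derived deterministically from ``seed``.
    """
    k_grid = tuple(int(k) for k in k_grid)
    if len(k_grid) < 2 or any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise FCCommError("k_grid must be ascending with at least 2 entries")
    if any(b - a != 1 for a, b in zip(k_grid, k_grid[1:])):
        raise FCCommError("k_grid must contain consecutive K values")

    ss = np.random.SeedSequence(seed)
    ens_seeds = ss.spawn(len(k_grid))
    boot_seeds = ss.spawn(len(k_grid) - 1)

    pools: dict[int, np.ndarray] = {}
    n_invalid: dict[int, int] = {}
    ensembles: dict[int, EnsembleResult] = {}
    for K, child in zip(k_grid, ens_seeds):
        base = int(child.generate_state(1)[0] % 2**31)
        ens = fit_ensemble(
            A, K, n_runs, prior=prior, base_seed=base, n_trials=n_trials
        )
        pools[K] = np.asarray([_criterion(f, statistic) for f in ens])
        n_invalid[K] = ens.n_invalid
        if keep_fits:
            ensembles[K] = ens

    if all(p.size == 0 for p in pools.values()):
        raise FCCommError("no valid solutions at any K; selection impossible")

    diffs = []
    chosen = None
    for (K, K1), child in zip(zip(k_grid, k_grid[1:]), boot_seeds):
        if pools[K].size == 0:
            diffs.append((K, K1, None, None))
            continue
        if pools[K1].size == 0:
            # No valid (K+1)-community solutions: the data cannot support
            # K+1 communities, so the search stops at K.
            diffs.append((K, K1, None, None))
            if chosen is None:
                chosen = K
            continue
        bs = int(child.generate_state(1)[0] % 2**31)
        lo, hi = bootstrap_diff_ci(
            pools[K], pools[K1], n_boot=n_boot, alpha=alpha, seed=bs, mode=mode
        )
        diffs.append((K, K1, lo, hi))
        if chosen is None and lo <= 0.0:
            chosen = K

    fallback = chosen is None
    if fallback:
        chosen = max(k for k in k_grid if pools[k].size > 0)

    return KSelectionResult(
        k_grid=k_grid,
        pools=pools,
        n_invalid=n_invalid,
        diffs_ci=tuple(diffs),
        chosen_k=int(chosen),
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
        statistic=statistic,
        no_overlap_fallback=fallback,
        ensembles=ensembles if keep_fits else None,
    )


def best_fit(pool, statistic: str = "loglik") -> WSBMFit:
    """The fit with the largest criterion value; ties broken by smaller seed.

    At the selected K the final reported solution is the
    maximum-log-likelihood valid fit (``statistic="loglik"``).
    """
    fits = list(pool)
    if not fits:
        raise FCCommError("best_fit needs a nonempty pool")
    return max(fits, key=lambda f: (_criterion(f, statistic), -f.seed))
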