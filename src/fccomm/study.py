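"""End-to-end simulation study: generate, fit, select K, score, aggregate.

Mirrors the benchmark design: a planted 5-community network of 100 ROIs,
WSBM K-selection by bootstrap criterion differences, silhouette curves
across K for all three clusterers, final-solution quality indices,
pairwise cross-method agreement, and a consensus partition over the WSBM
ensemble at the selected K.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .baselines import correlation_dissimilarity, kmeans_fit, spectral_fit
from .consensus import consensus_partition
from .errors import UndefinedIndexError
from .metrics import (
    c_index,
    ch_index,
    dunn_index,
    hamming_distance,
    modularity,
    nmi,
    silhouette,
    vi_distance,
)
from .selection import best_fit, select_k
from .synthetic import (
    DEFAULT_BETWEEN_MEAN_RANGE,
    DEFAULT_SD_RANGE,
    DEFAULT_SIZES,
    DEFAULT_WITHIN_MEAN_RANGE,
    planted_network,
)
from .types import FCMatrix, Partition
from .wsbm import map_labels

__all__ = ["RunConfig", "silhouette_curve", "run_simulation_study"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulation study run."""

    sizes: tuple = DEFAULT_SIZES
    within_mean_range: tuple = DEFAULT_WITHIN_MEAN_RANGE
    between_mean_range: tuple = DEFAULT_BETWEEN_MEAN_RANGE
    sd_range: tuple = DEFAULT_SD_RANGE
    clip: bool = True
    k_min: int = 2
    k_max: int = 8
    n_runs: int = 100  # WSBM ensemble size per K
    n_boot: int = 500  # bootstrap replicates per transition
    alpha: float = 0.05
    n_replicates: int = 10  # baseline replications per K (silhouette curves)
    statistic: str = "elbo"
    seed: int = 0


def _derive(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def silhouette_curve(
    A: FCMatrix,
    method: str,
    k_grid,
    n_replicates: int = 10,
    seed: int = 0,
) -> dict:
    """Best silhouette across replications for each K.

    For every K the method is rerun ``n_replicates`` times with distinct
    seeds; each solution is scored by the silhouette of the profile
    dissimilarities, and the highest-silhouette solution represents that K
    (the final-solution rule used for the baseline clusterers). Returns
    ``{"k": [...], "silhouette": [...], "best": {K: Partition}}``.
    """
    D = correlation_dissimilarity(A)
    seeds = _derive(seed, len(list(k_grid)) * n_replicates)
    out_k, out_s, best = [], [], {}
    it = iter(seeds)
    for K in k_grid:
        vals = []
        parts = []
        for _ in range(n_replicates):
            s = next(it)
            if method == "kmeans":
                part = kmeans_fit(A, K, n_restarts=1, seed=s).partition
            elif method == "spectral":
                part = spectral_fit(A, K, seed=s, n_restarts=1)
            else:
                raise ValueError(f"unknown method {method!r}")
            try:
                vals.append(silhouette(D, part))
            except UndefinedIndexError:
                vals.append(-np.inf)
            parts.append(part)
        j = int(np.argmax(vals))
        out_k.append(int(K))
        out_s.append(float(vals[j]))
        best[int(K)] = parts[j]
    return {"k": out_k, "silhouette": out_s, "best": best}


def _indices(A: FCMatrix, D, z: Partition) -> dict:
    out = {}
    for name, fn in (
        ("silhouette", lambda: silhouette(D, z)),
        ("modularity", lambda: modularity(A, z)),
        ("ch_index", lambda: ch_index(D, z)),
        ("c_index", lambda: c_index(D, z)),
        ("dunn_index", lambda: dunn_index(D, z)),
    ):
        try:
            out[name] = float(fn())
        except UndefinedIndexError as exc:
            out[name] = f"undefined ({exc})"
    return out


def run_simulation_study(config: RunConfig = RunConfig()) -> dict:
    """Run the full synthetic benchmark and return a JSON-ready report."""
    s_net, s_sel, s_sil, s_cons = _derive(config.seed, 4)

    A, planted, params = planted_network(
        sizes=config.sizes,
        within_mean_range=config.within_mean_range,
        between_mean_range=config.between_mean_range,
        sd_range=config.sd_range,
        seed=s_net,
        clip=config.clip,
    )
    D = correlation_dissimilarity(A)
    k_grid = range(config.k_min, config.k_max + 1)

    sel = select_k(
        A,
        k_grid=k_grid,
        n_runs=config.n_runs,
        n_boot=config.n_boot,
        alpha=config.alpha,
        seed=s_sel,
        statistic=config.statistic,
    )
    k_star = sel.chosen_k

    curves = {
        m: silhouette_curve(A, m, k_grid, config.n_replicates, seed=s_sil + i)
        for i, m in enumerate(("spectral", "kmeans"))
    }
    # WSBM silhouette per K from the valid solutions already fitted
    wsbm_k, wsbm_sil = [], []
    for K in k_grid:
        ens = (sel.ensembles or {}).get(K)
        if ens is None or len(ens) == 0:
            continue
        vals = []
        for f in ens:
            try:
                vals.append(silhouette(D, map_labels(f)))
            except UndefinedIndexError:
                vals.append(-np.inf)
        wsbm_k.append(int(K))
        wsbm_sil.append(float(np.max(vals)))

    finals: dict[str, Partition] = {}
    ens = sel.chosen_ensemble
    if ens is not None and len(ens) > 0:
        finals["wsbm"] = map_labels(best_fit(ens))
    for m in ("spectral", "kmeans"):
        finals[m] = curves[m]["best"].get(
            k_star, curves[m]["best"][max(curves[m]["best"])]
        )

    report = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": {
            "network": s_net,
            "selection": s_sel,
            "silhouette": s_sil,
            "consensus": s_cons,
        },
        "n": A.n,
        "true_k": planted.K,
        "selection": {
            "chosen_k": k_star,
            "fallback": sel.no_overlap_fallback,
            "pool_sizes": {k: int(v.size) for k, v in sel.pools.items()},
            "n_invalid": sel.n_invalid,
            "diffs_ci": [
                {"k": a, "k1": b, "lower": lo, "upper": hi}
                for a, b, lo, hi in sel.diffs_ci
            ],
        },
        "silhouette_curves": {
            **{
                m: {"k": c["k"], "silhouette": c["silhouette"]}
                for m, c in curves.items()
            },
            "wsbm": {"k": wsbm_k, "silhouette": wsbm_sil},
        },
        "silhouette_peak_k": {
            m: int(c["k"][int(np.argmax(c["silhouette"]))]) for m, c in curves.items()
        },
        "final_solutions": {},
        "cross_method": {},
    }

    for m, z in finals.items():
        ham, _ = hamming_distance(planted, z)
        report["final_solutions"][m] = {
            "labels": z.labels,
            "k": z.K,
            "nmi_vs_planted": nmi(planted, z),
            "vi_vs_planted": vi_distance(planted, z),
            "hamming_vs_planted": ham,
            "indices": _indices(A, D, z),
        }
    names = sorted(finals)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            if finals[m1].K == finals[m2].K:
                ham, _ = hamming_distance(finals[m1], finals[m2])
                report["cross_method"][f"{m1}_vs_{m2}"] = {
                    "nmi": nmi(finals[m1], finals[m2]),
                    "hamming": ham,
                }

    if ens is not None and len(ens) > 1:
        parts = [map_labels(f) for f in ens]
        cons = consensus_partition(
            parts, reference_rule="max_score", scores=[f.loglik for f in ens]
        )
        ham, _ = hamming_distance(planted, cons.consensus)
        report["consensus"] = {
            "k": k_star,
            "labels": cons.consensus.labels,
            "mean_agreement": float(cons.agreement.mean()),
            "uses_all_labels": cons.uses_all_labels,
            "nmi_vs_planted": nmi(planted, cons.consensus),
            "hamming_vs_planted": ham,
        }

    return report
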