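"""Choose the number of communities with the bootstrap criterion.

For each K the WSBM is refit from many seeded restarts; only valid
solutions (using all K labels) enter the per-K criterion pool. For each
transition K -> K+1 a percentile bootstrap CI of the criterion
difference (an approximate log Bayes factor) is formed; the selected K*
is the smallest K at which adding a community no longer significantly
improves the criterion.
"""

from fccomm import planted_network, select_k

A, planted, _ = planted_network(seed=7)

res = select_k(A, k_grid=range(2, 9), n_runs=100, n_boot=500, seed=1)

print(f"true K = {planted.K}, chosen K* = {res.chosen_k}")
print("per-K pools (valid solutions / criterion mean):")
for k in res.k_grid:
    pool = res.pools[k]
    mean = f"{pool.mean():.1f}" if pool.size else "--"
    print(f"  K={k}: {pool.size:3d} valid ({res.n_invalid[k]:3d} discarded), mean {mean}")
print("transition CIs (K -> K+1 criterion difference):")
for k, k1, lo, hi in res.diffs_ci:
    if lo is None:
        print(f"  {k}->{k1}: not evaluable (empty pool)")
    else:
        mark = "  <- first non-positive interval" if k == res.chosen_k else ""
        print(f"  {k}->{k1}: [{lo:8.1f}, {hi:8.1f}]{mark}")
print("a strictly positive interval means K+1 communities fit significantly "
      "better; the first interval reaching 0 stops the search")
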