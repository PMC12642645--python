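"""Independent brute-force reference implementations.

Deliberately written as plain double/triple loops over vertices and
pairs, with no shared code paths with the package, so they can serve as
oracles in equivalence tests.
"""

import itertools
import math

import numpy as np


def loglik_pairwise(W, labels, mu, sigma2):
    """Gaussian block log-likelihood, one pair at a time."""
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i] - 1, labels[j] - 1
            s2 = sigma2[a][b]
            total += -0.5 * math.log(2 * math.pi * s2) - (W[i][j] - mu[a][b]) ** 2 / (
                2 * s2
            )
    return total


def modularity_loops(W, labels):
    n = W.shape[0]
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    two_m = sum(W[i][j] for i in range(n) for j in range(n))
    deg = [sum(W[i][j] for j in range(n)) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i][j] - deg[i] * deg[j] / two_m
    return q / two_m


def entropy_of(labels):
    n = len(labels)
    h = 0.0
    for k in set(labels):
        p = sum(1 for z in labels if z == k) / n
        h -= p * math.log(p)
    return h


def mutual_info(z1, z2):
    n = len(z1)
    mi = 0.0
    for a in set(z1):
        for b in set(z2):
            pab = sum(1 for i in range(n) if z1[i] == a and z2[i] == b) / n
            if pab == 0:
                continue
            pa = sum(1 for z in z1 if z == a) / n
            pb = sum(1 for z in z2 if z == b) / n
            mi += pab * math.log(pab / (pa * pb))
    return mi


def vi_loops(z1, z2):
    return entropy_of(z1) + entropy_of(z2) - 2.0 * mutual_info(z1, z2)


def nmi_loops(z1, z2):
    h1, h2 = entropy_of(z1), entropy_of(z2)
    if h1 == 0 and h2 == 0:
        return 1.0
    if h1 == 0 or h2 == 0:
        return 0.0
    return mutual_info(z1, z2) / math.sqrt(h1 * h2)


def ch_loops(d, labels):
    n = len(labels)
    sst = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for k in set(labels):
        members = [i for i in range(n) if labels[i] == k]
        if len(members) < 2:
            continue
        s = sum(
            d[i][j] ** 2
            for ai, i in enumerate(members)
            for j in members[ai + 1 :]
        )
        ssw += s / len(members)
    K = len(set(labels))
    if ssw == 0:
        return float("inf")
    return ((sst - ssw) / (K - 1)) / (ssw / (n - K))


def c_index_loops(d, labels):
    n = len(labels)
    within = []
    alld = []
    for i in range(n):
        for j in range(i + 1, n):
            alld.append(d[i][j])
            if labels[i] == labels[j]:
                within.append(d[i][j])
    nw = len(within)
    alld.sort()
    smin = sum(alld[:nw])
    smax = sum(alld[-nw:])
    return (sum(within) - smin) / (smax - smin)


def dunn_loops(d, labels):
    ks = sorted(set(labels))
    diam = 0.0
    for k in ks:
        members = [i for i in range(len(labels)) if labels[i] == k]
        for ai, i in enumerate(members):
            for j in members[ai + 1 :]:
                diam = max(diam, d[i][j])
    sep = float("inf")
    for a_idx, a in enumerate(ks):
        for b in ks[a_idx + 1 :]:
            for i in [x for x in range(len(labels)) if labels[x] == a]:
                for j in [x for x in range(len(labels)) if labels[x] == b]:
                    sep = min(sep, d[i][j])
    return sep / diam


def hamming_exhaustive(z1, z2, K):
    """Minimum mismatch fraction over all K! relabelings of z2."""
    n = len(z1)
    best = 1.0
    for perm in itertools.permutations(range(1, K + 1)):
        mismatch = sum(1 for i in range(n) if z1[i] != perm[z2[i] - 1]) / n
        best = min(best, mismatch)
    return best


def pearson_excluding(W, i, j):
    """Two-pass Pearson correlation of rows i, j with coords i, j dropped."""
    n = W.shape[0]
    xs = [W[i][m] for m in range(n) if m not in (i, j)]
    ys = [W[j][m] for m in range(n) if m not in (i, j)]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    dy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return num / (dx * dy)
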