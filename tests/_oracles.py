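"""Independent brute-force reference implementations used only by tests."""

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_dbscan(pts: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) density-reachability reference.

    Core points: closed eps-ball holds >= min_pts points (self included).
    Clusters: connected components of the core-core adjacency, numbered by
    their lowest core index in ascending scan order.  Border points join the
    lowest-id cluster among their core neighbours; everything else is -1.
    Clusters left with fewer than min_pts members (shared borders claimed
    elsewhere) are dissolved into noise and survivors renumbered compactly.
    """
    n = len(pts)
    within = cdist(pts, pts) <= eps
    core = within.sum(axis=1) >= min_pts
    comp = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or comp[i] != -1:
            continue
        stack = [i]
        comp[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j] & core):
                if comp[k] == -1:
                    comp[k] = cluster
                    stack.append(k)
        cluster += 1
    labels = np.full(n, -1)
    labels[core] = comp[core]
    for i in np.flatnonzero(~core):
        neigh = comp[within[i] & core]
        if len(neigh):
            labels[i] = neigh.min()
    out = np.full(n, -1)
    next_id = 0
    for c in range(cluster):
        members = labels == c
        if members.sum() >= min_pts:
            out[members] = next_id
            next_id += 1
    return out


def bisect_sigma(distances_sq: np.ndarray, perplexity: float,
                 lo: float = 1e-8, hi: float = 1e8, iters: int = 200) -> float:
    """Standalone bisection for one point's Gaussian bandwidth sigma.

    ``distances_sq`` are the squared distances to the other points; the
    entropy is evaluated by direct summation and sigma is bisected until
    exp(H) matches the target perplexity.
    """
    target = np.log(perplexity)

    def entropy(sigma):
        w = np.exp(-distances_sq / (2.0 * sigma**2))
        w_sum = w.sum()
        if w_sum <= 0:
            return 0.0
        p = w / w_sum
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if entropy(mid) > target:
            hi = mid
        else:
            lo = mid
    return np.sqrt(lo * hi)


def kl_double_loop(P: np.ndarray, Y: np.ndarray) -> float:
    """Term-by-term KL(P||Q) with the Student-t q, via explicit double loops."""
    n = len(Y)
    num = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                num[i, j] = 1.0 / (1.0 + ((Y[i] - Y[j]) ** 2).sum())
    Z = num.sum()
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and P[i, j] > 0:
                total += P[i, j] * np.log(P[i, j] / (num[i, j] / Z))
    return total
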