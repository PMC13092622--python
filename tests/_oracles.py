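"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by direct enumeration or naive
computation, sharing no code with the package's implementation path.
"""

import numpy as np


def psyn_bruteforce(pre, post, lag, delta_t):
    """Window-count postsynaptic spike probability, the naive way.

    Each postsynaptic spike is credited to at most one presynaptic spike
    (the nearest window center); plain double loop.
    """
    pre = list(pre)
    post = list(post)
    if not pre:
        raise ValueError("empty pre")
    used = [False] * len(post)
    hits = 0
    # credit each post spike to its nearest center, then count
    for j, tp in enumerate(post):
        best = None
        bestd = None
        for i, t in enumerate(pre):
            d = abs(tp - (t + lag))
            if d <= delta_t and (bestd is None or d < bestd):
                best, bestd = i, d
        if best is not None and not used[j]:
            used[j] = True
            hits += 1
    return min(1.0, hits / len(pre))


def te_bruteforce(x, y, k, delta):
    """Plug-in TE by dictionary counting over all joint state histograms."""
    x = list(int(v) for v in x)
    y = list(int(v) for v in y)
    n = len(x)
    t0 = k + delta
    joint = {}
    for t in range(t0, n):
        past = tuple(x[t - k:t])
        key = (x[t], past, y[t - delta])
        joint[key] = joint.get(key, 0) + 1
    total = n - t0
    # marginals
    c_p, c_py, c_xp = {}, {}, {}
    for (xt, p, yv), c in joint.items():
        c_p[p] = c_p.get(p, 0) + c
        c_py[(p, yv)] = c_py.get((p, yv), 0) + c
        c_xp[(xt, p)] = c_xp.get((xt, p), 0) + c
    te = 0.0
    for (xt, p, yv), c in joint.items():
        te += c * np.log2(c * c_p[p] / (c_py[(p, yv)] * c_xp[(xt, p)]))
    return max(0.0, te / total)


def match_bruteforce(a, b, max_lat):
    """Exhaustive order-preserving matching: maximum cardinality, then
    minimum total latency.  Recursion with memoization; small inputs only.
    """
    from functools import lru_cache
    a = tuple(a)
    b = tuple(b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) or j == len(b):
            return (0, 0.0, ())
        best = rec(i + 1, j)
        cand = rec(i, j + 1)
        if (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
        d = b[j] - a[i]
        if 0.0 < d <= max_lat:
            m, lat, pairs = rec(i + 1, j + 1)
            cand = (m + 1, lat + d, ((i, j),) + pairs)
            if (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
        return best

    m, lat, pairs = rec(0, 0)
    return list(pairs), lat


def ks_bruteforce(a, b):
    """Supremum of |ECDF_a - ECDF_b| by direct evaluation at every point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    d = 0.0
    for g in grid:
        fa = np.mean(a <= g)
        fb = np.mean(b <= g)
        d = max(d, abs(fa - fb))
    return d


def beta_profile_sum(ts_eval, event_times, weights, tau1, tau2):
    """Direct superposition of beta profiles (naive double loop)."""
    tp = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
    norm = np.exp(-tp / tau1) - np.exp(-tp / tau2)
    out = np.zeros_like(np.asarray(ts_eval, dtype=float))
    for te, w in zip(event_times, weights):
        dt = np.asarray(ts_eval) - te
        prof = np.where(dt >= 0,
                        (np.exp(-dt / tau1) - np.exp(-dt / tau2)) / norm,
                        0.0)
        out = out + w * prof
    return out
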