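"""Independent reference implementations used only to check the package.

Each oracle is deliberately written from the definition, in a different
style from the library code (recursion, enumeration, explicit formulas),
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def naive_linkage(D: np.ndarray, method: str) -> list[float]:
    """Brute-force agglomeration: keep explicit member lists and recompute
    the Lance-Williams working distance between every pair of clusters at
    every step from a dict. Returns merge heights."""
    n = D.shape[0]
    work = {}  # frozenset pair -> working distance
    clusters = [frozenset([i]) for i in range(n)]
    sq = method == "ward_d2"
    for i in range(n):
        for j in range(i + 1, n):
            d = D[i, j] ** 2 if sq else D[i, j]
            work[frozenset([clusters[i], clusters[j]])] = d
    heights = []
    order = {frozenset([i]): i for i in range(n)}  # creation order for ties
    next_id = n
    while len(clusters) > 1:
        best_key, best_val, best_pair = None, None, None
        for a_i in range(len(clusters)):
            for b_i in range(a_i + 1, len(clusters)):
                a, b = clusters[a_i], clusters[b_i]
                pair = tuple(sorted((order[a], order[b])))
                v = work[frozenset([a, b])]
                if best_val is None or v < best_val or (v == best_val and pair < best_pair):
                    best_key, best_val, best_pair = (a, b), v, pair
        a, b = best_key
        heights.append(math.sqrt(best_val) if sq else best_val)
        merged = a | b
        for c in clusters:
            if c is a or c is b:
                continue
            dca = work[frozenset([c, a])]
            dcb = work[frozenset([c, b])]
            if method == "complete":
                new = max(dca, dcb)
            else:
                na, nb, nc = len(a), len(b), len(c)
                tot = na + nb + nc
                new = ((na + nc) * dca + (nb + nc) * dcb - nc * best_val) / tot
            work[frozenset([c, merged])] = new
        clusters = [c for c in clusters if c is not a and c is not b] + [merged]
        order[merged] = next_id
        next_id += 1
    return heights


def irls_logistic(X: np.ndarray, y: np.ndarray, maxiter: int = 200, tol: float = 1e-12):
    """Plain Newton/IRLS maximum-likelihood logistic fit.

    Returns (beta, se, wald_p) with p from the normal approximation.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (mu * (1 - mu))) @ X
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return beta, se, p


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by explicit enumeration with exact binomials."""
    total = 0.0
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / denom
    return total


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    idx = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = idx[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def gsea_running_sum(stats_sorted: np.ndarray, hit_mask: np.ndarray, w: float = 1.0):
    """Running-sum ES recomputed step by step with a Python loop."""
    nr = sum(abs(s) ** w for s, h in zip(stats_sorted, hit_mask) if h)
    n_miss = len(stats_sorted) - int(hit_mask.sum())
    run, best = 0.0, 0.0
    profile = []
    for s, h in zip(stats_sorted, hit_mask):
        run += (abs(s) ** w) / nr if h else -1.0 / n_miss
        profile.append(run)
        if abs(run) > abs(best):
            best = run
    return best, np.array(profile)


def pooled_t(a: np.ndarray, b: np.ndarray):
    """Textbook pooled-variance two-sample t with the t CDF."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def binomial_ci_bounds(n: int, k: int, level: float = 0.95):
    """Exact binomial quantile oracle for the bootstrap percentile CI."""
    alpha = (1 - level) / 2
    lo = stats.binom.ppf(alpha, n, k / n) / n
    hi = stats.binom.ppf(1 - alpha, n, k / n) / n
    return lo, hi
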