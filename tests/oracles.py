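"""Independent brute-force oracles used by the tests and acceptance checks.

These deliberately avoid the package's own algorithms: breadth-first search
over event sequences for the minimum-event distance, exhaustive enumeration
of breakpoint subsets for the segmentation objective, the raw Morisita-Horn
formula, and a dense-grid likelihood maximization for Pagel's lambda.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.stats import multivariate_normal


def bfs_med(p, q=None, cap_slack: int = 2, cap: int | None = None):
    """BFS minimum-event distances from profile ``p``.

    Events add or subtract 1 on a contiguous interval; positions at 0 are
    absorbed (unchanged by any event); decrements floor at 0. Intermediate
    copy numbers are capped at max(p, q) + ``cap_slack``. With ``q`` given
    returns a single distance (None if unreachable); otherwise a dict of
    distances to every reachable state.
    """
    p = tuple(int(v) for v in p)
    L = len(p)
    if cap is None:
        cap = max(p + (tuple(int(v) for v in q) if q is not None else (0,))) + cap_slack
    dist = {p: 0}
    frontier = deque([p])
    target = tuple(int(v) for v in q) if q is not None else None
    if target == p:
        return 0
    while frontier:
        state = frontier.popleft()
        d = dist[state]
        for i in range(L):
            for j in range(i, L):
                for delta in (1, -1):
                    new = list(state)
                    changed = False
                    ok = True
                    for k in range(i, j + 1):
                        if new[k] == 0:
                            continue  # absorbed
                        v = new[k] + delta
                        if v > cap:
                            ok = False
                            break
                        new[k] = max(0, v)
                        changed = True
                    if not ok or not changed:
                        continue
                    ns = tuple(new)
                    if ns not in dist:
                        dist[ns] = d + 1
                        if ns == target:
                            return d + 1
                        frontier.append(ns)
    return dist if target is None else None


def brute_force_segmentation_objective(y: np.ndarray, gamma: float) -> float:
    """Minimum penalized SSE over all breakpoint subsets of one chromosome.

    ``y`` is (n_samples, n_bins) already on the scale the objective uses;
    breakpoints are shared across samples and cost ``gamma`` each.
    """
    n = y.shape[1]
    best = np.inf
    for pattern in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(pattern) if b] + [n]
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = y[:, a:b]
            sse += float(np.sum((seg - seg.mean(axis=1, keepdims=True)) ** 2))
        cost = sse + gamma * (len(bounds) - 2)
        best = min(best, cost)
    return best


def direct_morisita_horn(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    num = 2.0 * sum(xi * yi for xi, yi in zip(x, y))
    den = (sum(xi * xi for xi in x) / X**2 + sum(yi * yi for yi in y) / Y**2) * X * Y
    return num / den


def grid_lambda(C: np.ndarray, y: np.ndarray, step: float = 0.01):
    """Dense-grid ML for Pagel's lambda using scipy's multivariate normal."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    one = np.ones(n)
    best = (-np.inf, 0.0)
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        Vi = np.linalg.inv(V)
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        resid = y - mu
        sigma2 = (resid @ Vi @ resid) / n
        if sigma2 <= 0:
            continue
        ll = multivariate_normal(mean=np.full(n, mu), cov=sigma2 * V,
                                 allow_singular=True).logpdf(y)
        if ll > best[0]:
            best = (float(ll), float(lam))
    return best[1], best[0]
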