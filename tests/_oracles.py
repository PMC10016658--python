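"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (exhaustive enumeration, textbook
formulas) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# graph metrics by exhaustive simple-path enumeration


def brute_distances(w: np.ndarray) -> np.ndarray:
    """Shortest 1/w-length distances by enumerating every simple path."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src in range(n):
        for perm_len in range(1, n):
            for mid in itertools.permutations(
                [v for v in range(n) if v != src], perm_len
            ):
                path = (src, *mid)
                length = 0.0
                ok = True
                for a, b in zip(path, path[1:]):
                    if w[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / w[a, b]
                if ok:
                    d[src, path[-1]] = min(d[src, path[-1]], length)
    return d


def brute_lp(w: np.ndarray) -> tuple[float, np.ndarray]:
    d = brute_distances(w)
    n = w.shape[0]
    nodal = np.full(n, np.nan)
    finite_all = []
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])]
        if finite:
            nodal[i] = float(np.mean(finite))
        finite_all.extend(finite)
    gl = float(np.mean(finite_all)) if finite_all else float("nan")
    return gl, nodal


def brute_eglob(w: np.ndarray) -> tuple[float, np.ndarray]:
    d = brute_distances(w)
    n = w.shape[0]
    nodal = np.zeros(n)
    for i in range(n):
        nodal[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])
        ) / (n - 1)
    return float(np.mean(nodal)), nodal


def brute_strength(w: np.ndarray) -> tuple[float, np.ndarray]:
    nodal = np.array([sum(w[i]) for i in range(w.shape[0])])
    return float(np.mean(nodal)), nodal


def brute_onnela_cp(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    wmax = w.max()
    nodal = np.zeros(n)
    if wmax == 0:
        return 0.0, nodal
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if w[j, h] > 0:
                s += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (
                    1.0 / 3.0
                )
        nodal[i] = 2.0 * s / (k * (k - 1))
    return float(np.mean(nodal)), nodal


def brute_eloc(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    nodal = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        nodal[i] = brute_eglob(sub)[0]
    return float(np.mean(nodal)), nodal


def random_graph(rng: np.random.Generator, n_max: int = 6) -> np.ndarray:
    """Random small weighted graph (possibly disconnected / empty)."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.2, 0.9)
    upper = np.triu((rng.random((n, n)) < p) * rng.uniform(0.05, 1.0, (n, n)), 1)
    return upper + upper.T


# ---------------------------------------------------------------------------
# statistics


def exact_mannwhitney(x, y) -> tuple[float, float]:
    """(min-U, two-sided p) by enumerating every group labelling."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_min(sample_x):
        u1 = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in sample_x
            for b in (v for v in pooled_rest(sample_x))
        )
        return min(u1, n1 * n2 - u1)

    def pooled_rest(sample_x):
        rest = pooled.copy()
        for v in sample_x:
            rest.remove(v)
        return rest

    observed = u_min(x)
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        sample = [pooled[i] for i in combo]
        total += 1
        if u_min(sample) <= observed + 1e-12:
            count += 1
    return observed, count / total


def bh_stepup(p_values) -> list[float]:
    """Textbook Benjamini-Hochberg: q_(i) = min_{j>=i} m p_(j) / j, capped."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = running
    return adjusted


def spearman_via_pearson_ranks(x, y) -> float:
    """Spearman rho as the Pearson correlation of the rank vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def ranks(a):
        order = np.argsort(a, kind="stable")
        r = np.empty_like(a)
        r[order] = np.arange(1, a.size + 1, dtype=float)
        # midranks for ties
        for v in np.unique(a):
            mask = a == v
            if mask.sum() > 1:
                r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))
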