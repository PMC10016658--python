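"""Weighted graph-theory measures on thresholded functional networks.

All measures operate on symmetric nonnegative weighted adjacency matrices
with zero diagonal.  Path-based measures use edge lengths 1/w, so stronger
connections are shorter.  Conventions:

* degree (strength): sum of a node's edge weights;
* characteristic path length Lp: mean shortest-path distance over finite
  node pairs (disconnected pairs are excluded, not imputed);
* global efficiency Eglob: mean inverse shortest-path distance, with
  1/inf = 0, so disconnection contributes zero rather than breaking the
  mean;
* clustering coefficient Cp: Onnela geometric-mean weighted triangles,
  weights max-normalised within the network;
* local efficiency Eloc: global efficiency of each node's
  neighbour-induced subgraph (original weights, centre node removed);
* small-worldness sigma: (Cp/Cp_rand)/(Lp/Lp_rand) against
  degree-preserving Maslov-Sneppen rewired surrogates whose edge weights
  are a random reassignment of the original weights.

Network metrics are evaluated at every density of the threshold family and
then averaged across densities, which is how the per-subject summary
values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityResult

__all__ = [
    "shortest_path_distances",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "local_efficiency",
    "degree_strength",
    "small_worldness",
    "metrics_over_densities",
    "SubjectMetrics",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

NODAL_METRICS = ("degree", "Lp", "Eglob", "Cp", "Eloc")
GLOBAL_METRICS = ("degree", "Lp", "Eglob", "Cp", "Eloc", "sigma")


def _check_adjacency(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(w < 0):
        raise ValueError("adjacency must be nonnegative")
    if np.any(np.diag(w) != 0):
        raise ValueError("adjacency must have zero diagonal")
    return w


def _apsp(w: np.ndarray) -> np.ndarray:
    """Min-plus matrix-squaring all-pairs shortest paths (no validation)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    nz = w > 0
    d[nz] = 1.0 / w[nz]
    np.fill_diagonal(d, 0.0)
    # doubling: after ceil(log2(n-1)) rounds all shortest paths are found
    rounds = max(1, int(np.ceil(np.log2(max(n - 1, 2)))))
    for _ in range(rounds):
        new = np.minimum(d, (d[:, :, None] + d[None, :, :]).min(axis=1))
        if np.array_equal(new, d):
            break
        d = new
    return d


def shortest_path_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/w.

    Min-plus matrix squaring: O(log R) dense relaxation rounds, fast for
    the small dense graphs this package works with.  Unreachable pairs are
    +inf; the diagonal is 0.
    """
    return _apsp(_check_adjacency(w))


def characteristic_path_length(w: np.ndarray) -> tuple[float, np.ndarray]:
    """(global Lp, nodal Lp_i): means over finite off-diagonal distances.

    Nodal Lp_i is NaN for a node with no reachable partner; the global
    value is the mean over all ordered finite pairs (NaN for an empty
    network).
    """
    gl, nodal = _lp(_check_adjacency(w))
    return gl, nodal


def _lp(w: np.ndarray) -> tuple[float, np.ndarray]:
    d = _apsp(w)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        nodal = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    total = counts.sum()
    global_lp = float(sums.sum() / total) if total else float("nan")
    return global_lp, nodal


def global_efficiency(w: np.ndarray) -> tuple[float, np.ndarray]:
    """(global Eglob, nodal Eglob_i): mean inverse distance, 1/inf = 0."""
    return _eglob(_check_adjacency(w))


def _eglob(w: np.ndarray) -> tuple[float, np.ndarray]:
    d = _apsp(w)
    n = d.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    inv = np.zeros_like(d)
    ok = np.isfinite(d) & (d > 0)
    inv[ok] = 1.0 / d[ok]
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


def degree_strength(w: np.ndarray) -> tuple[float, np.ndarray]:
    """(mean degree, nodal degree_i): weighted strength, row sums."""
    w = _check_adjacency(w)
    nodal = w.sum(axis=1)
    return float(nodal.mean()), nodal


def clustering_coefficient(w: np.ndarray) -> tuple[float, np.ndarray]:
    """(global Cp, nodal Cp_i): Onnela weighted clustering.

    Weights are normalised by the network maximum, so Cp_i is 1 on a
    uniform-weight clique and reduces to the binary clustering coefficient
    on uniform-weight graphs.  Nodes with binary degree < 2 get Cp_i = 0.
    """
    return _cp(_check_adjacency(w))


def _cp(w: np.ndarray) -> tuple[float, np.ndarray]:
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    cube = np.cbrt(w / wmax)
    triangles = np.diag(cube @ cube @ cube)  # 2 * sum of weighted triangles at i
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    nodal = np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)
    return float(nodal.mean()), nodal


def local_efficiency(w: np.ndarray) -> tuple[float, np.ndarray]:
    """(global Eloc, nodal Eloc_i).

    Eloc_i is the global efficiency of the subgraph induced by i's
    neighbours (node i removed, original weights); 0 when i has fewer
    than two neighbours.
    """
    return _eloc(_check_adjacency(w))


def _eloc(w: np.ndarray) -> tuple[float, np.ndarray]:
    # batched min-plus over all neighbour subgraphs at once: pad each
    # subgraph to the largest neighbourhood; padding nodes stay at +inf
    # and cannot shorten any path
    n = w.shape[0]
    nodal = np.zeros(n)
    neighbours = [np.flatnonzero(w[i] > 0) for i in range(n)]
    ks = np.array([nb.size for nb in neighbours])
    active = np.flatnonzero(ks >= 2)
    if active.size == 0:
        return 0.0, nodal
    lengths = np.full_like(w, np.inf)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    for k in np.unique(ks[active]):
        batch = active[ks[active] == k]
        d = np.empty((batch.size, k, k))
        for row, i in enumerate(batch):
            nb = neighbours[i]
            d[row] = lengths[np.ix_(nb, nb)]
        d[:, np.arange(k), np.arange(k)] = 0.0
        rounds = max(1, int(np.ceil(np.log2(max(k - 1, 2)))))
        for _ in range(rounds):
            new = np.minimum(d, (d[:, :, :, None] + d[:, None, :, :]).min(axis=2))
            if np.array_equal(new, d):
                break
            d = new
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        nodal[batch] = inv.sum(axis=(1, 2)) / (k * (k - 1))
    return float(nodal.mean()), nodal


def _rewired_surrogate(
    edges: np.ndarray, n_nodes: int, rng: np.random.Generator, swaps_per_edge: int
) -> np.ndarray | None:
    """Maslov-Sneppen degree-preserving rewiring of the binary topology.

    Performs ``swaps_per_edge * n_edges`` successful double-edge swaps (or
    gives up after 100x that many attempts).  Returns the rewired edge
    array, or None when the graph is too small to swap.
    """
    m = edges.shape[0]
    if m < 2:
        return None
    # plain python containers: the inner loop is much faster than numpy
    # scalar indexing here
    e: list[tuple[int, int]] = [tuple(p) for p in edges.tolist()]
    present = {(a, b) for a, b in e} | {(b, a) for a, b in e}
    target = swaps_per_edge * m
    max_attempts = 100 * target
    done = attempts = 0
    while done < target and attempts < max_attempts:
        chunk = min(2 * (target - done) + 64, max_attempts - attempts)
        pick = rng.integers(0, m, size=2 * chunk).tolist()
        flip = rng.integers(0, 2, size=chunk).tolist()
        for t in range(chunk):
            attempts += 1
            e1, e2 = pick[2 * t], pick[2 * t + 1]
            if e1 == e2:
                continue
            a, b = e[e1]
            c, d = e[e2]
            if flip[t]:  # swap to (a,d),(c,b) vs (a,c),(b,d)
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if (a, d) in present or (c, b) in present:
                continue
            present.difference_update(((a, b), (b, a), (c, d), (d, c)))
            present.update(((a, d), (d, a), (c, b), (b, c)))
            e[e1] = (a, d)
            e[e2] = (c, b)
            done += 1
            if done >= target:
                break
    return np.asarray(e, dtype=np.intp)


def small_worldness(
    w: np.ndarray,
    n_nulls: int = 100,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
    max_retries: int = 10,
) -> float:
    """Small-world sigma against rewired null networks.

    sigma = (Cp / <Cp_rand>) / (Lp / <Lp_rand>), where the null ensemble
    consists of ``n_nulls`` Maslov-Sneppen rewired surrogates of the binary
    topology with the original edge weights randomly reassigned.  A null
    with no finite path at all is resampled up to ``max_retries`` times.
    Deterministic for a fixed seed.
    """
    if n_nulls < 10:
        raise ValueError("need at least 10 null networks")
    w = _check_adjacency(w)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lp, _ = _lp(w)
    cp, _ = _cp(w)
    if not np.isfinite(lp) or lp <= 0 or cp <= 0:
        return float("nan")
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = w[iu, ju] > 0
    edges = np.column_stack((iu[mask], ju[mask]))
    weights = w[iu, ju][mask]
    lp_rand = np.empty(n_nulls)
    cp_rand = np.empty(n_nulls)
    for k in range(n_nulls):
        for attempt in range(max_retries + 1):
            e = _rewired_surrogate(edges, w.shape[0], rng, swaps_per_edge)
            if e is None:
                return float("nan")
            null = np.zeros_like(w)
            shuffled = rng.permutation(weights)
            null[e[:, 0], e[:, 1]] = shuffled
            null = null + null.T
            lp_k, _ = _lp(null)
            cp_k, _ = _cp(null)
            if np.isfinite(lp_k) and lp_k > 0 and cp_k > 0:
                lp_rand[k] = lp_k
                cp_rand[k] = cp_k
                break
        else:
            raise RuntimeError(
                "could not draw a null network with finite path length"
            )
    return float((cp / cp_rand.mean()) / (lp / lp_rand.mean()))


@dataclass
class SubjectMetrics:
    """Per-density and density-averaged metrics for one subject.

    ``global_per_density``: DataFrame indexed by density, one column per
    global metric.  ``nodal_per_density``: DataFrame with (density, node)
    MultiIndex.  The averaged views are arithmetic means across densities;
    nodal NaNs (disconnected nodes) are excluded from the mean and counted
    in ``n_missing_nodal``.
    """

    subject_id: str
    global_per_density: pd.DataFrame
    nodal_per_density: pd.DataFrame
    global_avg: pd.Series
    nodal_avg: pd.DataFrame
    n_missing_nodal: int


def metrics_over_densities(
    conn: ConnectivityResult,
    n_nulls: int = 100,
    seed: int | np.random.Generator | None = None,
    node_names: list[str] | None = None,
    include_sigma: bool = True,
) -> SubjectMetrics:
    """Evaluate every metric at each density level and average the levels."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    densities = sorted(conn.z_networks)
    n = conn.r_matrix.shape[0]
    names = node_names if node_names is not None else [str(i) for i in range(n)]
    glob_rows, nodal_blocks = [], []
    for d in densities:
        w = conn.z_networks[d]
        _check_adjacency(w)
        deg_g, deg_i = degree_strength(w)
        lp_g, lp_i = _lp(w)
        eg_g, eg_i = _eglob(w)
        cp_g, cp_i = _cp(w)
        el_g, el_i = _eloc(w)
        row = {"degree": deg_g, "Lp": lp_g, "Eglob": eg_g, "Cp": cp_g, "Eloc": el_g}
        if include_sigma:
            row["sigma"] = small_worldness(w, n_nulls=n_nulls, seed=rng)
        glob_rows.append(pd.Series(row, name=d))
        nodal_blocks.append(np.column_stack([deg_i, lp_i, eg_i, cp_i, el_i]))
    global_per_density = pd.DataFrame(glob_rows)
    global_per_density.index.name = "density"
    stacked = np.vstack(nodal_blocks)
    nodal_per_density = pd.DataFrame(
        stacked,
        columns=list(NODAL_METRICS),
        index=pd.MultiIndex.from_product([densities, names], names=["density", "node"]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN node
        avg = np.nanmean(stacked.reshape(len(densities), n, -1), axis=0)
    nodal_avg = pd.DataFrame(avg, index=names, columns=list(NODAL_METRICS))
    n_missing = int(np.isnan(stacked[:, 1]).sum())
    return SubjectMetrics(
        subject_id=conn.subject_id,
        global_per_density=global_per_density,
        nodal_per_density=nodal_per_density,
        global_avg=global_per_density.mean(axis=0),
        nodal_avg=nodal_avg,
        n_missing_nodal=n_missing,
    )
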