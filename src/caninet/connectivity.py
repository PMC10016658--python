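"""Functional network construction from ROI time series.

For every subject the pipeline (i) computes the Pearson correlation matrix
between all pairs of ROI time series, (ii) removes the weakest connections
by keeping the top-k positive correlations at a set of network densities
(20%-50% in 5% steps by default; density = retained edges / possible
edges), and (iii) Fisher r-to-z transforms the surviving weights.  Negative
correlations are always discarded: only positive weights enter the
connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityGrid",
    "ConnectivityResult",
    "correlation_matrix",
    "threshold_by_density",
    "fisher_z",
    "build_connectivity",
]

_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class DensityGrid:
    """Ordered set of network density levels in (0, 1)."""

    levels: tuple[float, ...] = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)

    def __post_init__(self) -> None:
        lv = self.levels
        if not lv:
            raise ValueError("density grid is empty")
        if any(not 0.0 < d < 1.0 for d in lv):
            raise ValueError("densities must lie in (0, 1)")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("densities must be strictly increasing")

    def edge_count(self, n_nodes: int, density: float) -> int:
        """Number of retained edges: round-half-away-from-zero of d*M."""
        m = n_nodes * (n_nodes - 1) // 2
        return int(np.floor(density * m + 0.5))


@dataclass
class ConnectivityResult:
    """Raw correlation matrix plus the thresholded z-weighted networks.

    ``z_networks`` maps each density level to a symmetric nonnegative
    adjacency matrix (zero diagonal) of Fisher-z weights; ``edge_counts``
    records how many edges were actually retained at each level.
    """

    subject_id: str
    r_matrix: np.ndarray
    z_networks: dict[float, np.ndarray]
    edge_counts: dict[float, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def correlation_matrix(data: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Pearson correlation between all column pairs of a T x R matrix."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 time points")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = [names[i] if names else f"column {i}" for i in dead]
        raise ValueError(f"zero-variance ROI time series: {', '.join(map(str, labels))}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def threshold_by_density(
    r_matrix: np.ndarray, density: float, _warnings: list[str] | None = None
) -> np.ndarray:
    """Keep the k strongest positive correlations at the given density.

    k = round(density * R(R-1)/2); ties at the cutoff are broken by
    lexicographic (row, col) order so the result is deterministic.  When
    fewer than k positive correlations exist, all of them are kept and a
    warning is issued.  Output is symmetric, nonnegative, zero diagonal,
    still on the correlation scale.
    """
    r = np.asarray(r_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    n = r.shape[0]
    k = DensityGrid().edge_count(n, density)
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    pos = vals > 0
    n_pos = int(pos.sum())
    if n_pos < k:
        msg = (
            f"only {n_pos} positive correlations available for "
            f"{k} requested edges at density {density:g}"
        )
        if _warnings is not None:
            _warnings.append(msg)
        else:
            warnings.warn(msg, stacklevel=2)
        keep = pos
    else:
        # stable sort on (-value, i, j) makes the cutoff tie-break deterministic
        order = np.lexsort((ju, iu, -vals))
        top = order[:k]
        keep = np.zeros(vals.size, dtype=bool)
        keep[top] = pos[top]
    out = np.zeros_like(r)
    out[iu[keep], ju[keep]] = vals[keep]
    return out + out.T


def fisher_z(adjacency: np.ndarray) -> np.ndarray:
    """Fisher r-to-z (atanh) transform of the nonzero weights.

    Zeros (absent edges) stay zero.  Weights >= 1 are clipped just below 1
    with a warning; they cannot arise from distinct time series but may
    from degenerate input.
    """
    w = np.asarray(adjacency, dtype=float)
    if np.any(w < 0):
        raise ValueError("thresholded adjacency must be nonnegative")
    if np.any(w >= 1.0):
        warnings.warn("weights >= 1 clipped before the r-to-z transform", stacklevel=2)
        w = np.minimum(w, _Z_CLIP)
    return np.arctanh(w)


def build_connectivity(
    data: np.ndarray,
    subject_id: str = "",
    grid: DensityGrid | None = None,
    names: list[str] | None = None,
) -> ConnectivityResult:
    """Full per-subject construction: Pearson -> density threshold -> z."""
    grid = grid or DensityGrid()
    r = correlation_matrix(data, names=names)
    notes: list[str] = []
    z_networks: dict[float, np.ndarray] = {}
    edge_counts: dict[float, int] = {}
    for d in grid.levels:
        thr = threshold_by_density(r, d, _warnings=notes)
        z_networks[d] = fisher_z(thr)
        edge_counts[d] = int(np.count_nonzero(np.triu(thr, k=1)))
    return ConnectivityResult(
        subject_id=subject_id,
        r_matrix=r,
        z_networks=z_networks,
        edge_counts=edge_counts,
        warnings=notes,
    )
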