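"""Three-level nonparametric group comparison of network measures.

Differences between patient and control groups are assessed with the
Mann-Whitney U test at three levels: (1) the six density-averaged global
metrics, (2) five nodal metrics in the anxiety-circuit regions plus the
vermis control region (nodal values averaged between left and right
hemispheres), and (3) connection strength (density-averaged Fisher-z) for
every region pair within the circuit.  Benjamini-Hochberg FDR correction
is applied within each family: across the global metrics, across regions
within each nodal metric, and across the tested connections.

The reported U statistic is min(U1, U2), the convention under which
smaller values mean stronger separation and U <= n1*n2/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import Atlas

__all__ = [
    "mann_whitney_u",
    "fdr_adjust",
    "nodal_lr_average",
    "edge_region_average",
    "edge_value_table",
    "run_three_level_comparison",
    "ComparisonResult",
]

_EXACT_N_MAX = 30  # auto mode: exact null enumeration up to this many animals


def mann_whitney_u(
    x,
    y,
    mode: str = "auto",
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (min(U1, U2), p).

    ``mode``:
      * ``"exact"`` - exact rank-sum null; with ties the null is
        approximated by >= ``n_resamples`` permutations of the observed
        data;
      * ``"approximate"`` - normal approximation with tie-corrected
        variance and continuity correction;
      * ``"auto"`` - exact when n1 + n2 <= 30 and the data are tie-free,
        otherwise approximate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    if mode not in ("exact", "approximate", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both samples", stacklevel=2)
        return n1 * n2 / 2.0, 1.0
    if mode == "auto":
        mode = "exact" if (n1 + n2 <= _EXACT_N_MAX and not has_ties) else "approximate"
    if mode == "exact":
        if has_ties:
            rng = (
                seed
                if isinstance(seed, np.random.Generator)
                else np.random.default_rng(seed)
            )
            method = sps.PermutationMethod(n_resamples=n_resamples, rng=rng)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    return min(u1, n1 * n2 - u1), float(min(res.pvalue, 1.0))


def fdr_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = list(p_values)
    if not p:
        return []
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def nodal_lr_average(nodal: pd.DataFrame, atlas: Atlas) -> pd.DataFrame:
    """Collapse per-node metrics to region level.

    ``nodal``: DataFrame indexed by full node name (atlas order), one
    column per metric.  Bilateral regions become the mean of their left
    and right values; when one hemisphere is missing (disconnected node)
    the available side is used.  Midline regions pass through unchanged.
    """
    if list(nodal.index) != atlas.names:
        raise ValueError("nodal table index must match the atlas node names")
    values = nodal.to_numpy(dtype=float)
    rows = []
    for base in atlas.base_names:
        nodes = atlas.nodes_of(base)
        block = values[nodes]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice
            rows.append(np.nanmean(block, axis=0))
    return pd.DataFrame(rows, index=atlas.base_names, columns=nodal.columns)


def edge_region_average(
    z_networks: dict[float, np.ndarray],
    atlas: Atlas,
    pair: tuple[str, str],
) -> float:
    """Region-level connection strength for one subject.

    Averages the Fisher-z weights over all node pairs spanning the two
    regions (intra- plus interhemispheric; the homotopic pair when the
    same bilateral region is given twice) and then over the density
    levels.  Zero weights are genuine sub-threshold values and stay in the
    average.
    """
    node_pairs = atlas.spanning_node_pairs(*pair)
    vals = [
        z[i, j]
        for z in z_networks.values()
        for i, j in node_pairs
    ]
    return float(np.mean(vals))


def edge_value_table(
    results,
    atlas: Atlas,
    pairs: list[tuple[str, str]],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long table of per-subject region-pair connection strengths.

    ``results``: iterable of ConnectivityResult.  ``pairs``: region-name
    pairs; (a, a) requests the homotopic connection of a bilateral region.
    """
    rows = []
    for conn in results:
        for pair in pairs:
            rows.append(
                {
                    "subject_id": conn.subject_id,
                    "group": groups.get(conn.subject_id) if groups else None,
                    "pair": _pair_label(pair),
                    "z": edge_region_average(conn.z_networks, atlas, pair),
                }
            )
    return pd.DataFrame(rows)


def _pair_label(pair: tuple[str, str]) -> str:
    a, b = (p.strip().lower() for p in pair)
    if a == b:
        return f"{a} L-R"
    return " - ".join(sorted((a, b)))


def circuit_pairs(atlas: Atlas, include_homotopic: bool = False) -> list[tuple[str, str]]:
    """The tested region pairs: all unordered circuit pairs, optionally
    plus the homotopic connections of the bilateral circuit regions."""
    regs = list(atlas.circuit_regions)
    pairs = [
        (regs[i], regs[j]) for i in range(len(regs)) for j in range(i + 1, len(regs))
    ]
    if include_homotopic:
        pairs += [(r, r) for r in regs if atlas.is_bilateral(r)]
    return pairs


@dataclass(frozen=True)
class ComparisonResult:
    level: str  # global | nodal | edge
    target: str  # metric, "region:metric", or pair label
    u_statistic: float
    p_raw: float
    p_fdr: float
    direction: int  # sign(patient median - control median)
    median_control: float
    median_patient: float
    iqr_control: float
    iqr_patient: float


def _compare(
    level: str,
    target: str,
    ctrl: np.ndarray,
    pat: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> ComparisonResult:
    u, p = mann_whitney_u(pat, ctrl, mode=mode, seed=rng)
    med_c, med_p = float(np.median(ctrl)), float(np.median(pat))
    iqr = lambda a: float(np.subtract(*np.percentile(a, [75, 25])))  # noqa: E731
    return ComparisonResult(
        level=level,
        target=target,
        u_statistic=u,
        p_raw=p,
        p_fdr=float("nan"),
        direction=int(np.sign(med_p - med_c)),
        median_control=med_c,
        median_patient=med_p,
        iqr_control=iqr(ctrl),
        iqr_patient=iqr(pat),
    )


def _apply_fdr(results: list[ComparisonResult]) -> list[ComparisonResult]:
    adj = fdr_adjust([r.p_raw for r in results])
    return [
        ComparisonResult(**{**r.__dict__, "p_fdr": q}) for r, q in zip(results, adj)
    ]


def run_three_level_comparison(
    global_table: pd.DataFrame,
    nodal_table: pd.DataFrame,
    edge_table: pd.DataFrame,
    mode: str = "auto",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full three-level patient-vs-control comparison.

    Inputs (all density-averaged):
      * ``global_table``: subjects x global metrics, plus a ``group``
        column;
      * ``nodal_table``: long format with columns subject_id, group,
        region, metric, value (region level, circuit + control regions);
      * ``edge_table``: long format with columns subject_id, group, pair,
        z.

    FDR families: the global metrics together; regions within each nodal
    metric; all tested connections together.  Returns one row per test.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for name, df, col in (
        ("global", global_table, "group"),
        ("nodal", nodal_table, "group"),
        ("edge", edge_table, "group"),
    ):
        if df is not None and not set(df[col].unique()) <= {"control", "patient"}:
            raise ValueError(f"{name} table has groups other than control/patient")

    out: list[ComparisonResult] = []

    if global_table is not None and len(global_table):
        metrics = [c for c in global_table.columns if c != "group"]
        ctrl = global_table[global_table["group"] == "control"]
        pat = global_table[global_table["group"] == "patient"]
        block = [
            _compare("global", m, ctrl[m].to_numpy(), pat[m].to_numpy(), mode, rng)
            for m in metrics
            if ctrl[m].notna().all() and pat[m].notna().all()
        ]
        out.extend(_apply_fdr(block))

    if nodal_table is not None and len(nodal_table):
        for metric, sub in nodal_table.groupby("metric", sort=False):
            block = []
            for region, rsub in sub.groupby("region", sort=False):
                ctrl = rsub.loc[rsub["group"] == "control", "value"].to_numpy()
                pat = rsub.loc[rsub["group"] == "patient", "value"].to_numpy()
                block.append(
                    _compare("nodal", f"{region}:{metric}", ctrl, pat, mode, rng)
                )
            out.extend(_apply_fdr(block))

    if edge_table is not None and len(edge_table):
        block = []
        for pair, sub in edge_table.groupby("pair", sort=False):
            ctrl = sub.loc[sub["group"] == "control", "z"].to_numpy()
            pat = sub.loc[sub["group"] == "patient", "z"].to_numpy()
            block.append(_compare("edge", pair, ctrl, pat, mode, rng))
        out.extend(_apply_fdr(block))

    return pd.DataFrame([r.__dict__ for r in out])
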