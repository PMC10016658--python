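"""End-to-end analysis: networks -> metrics -> statistics -> correlations.

The stage order mirrors the study: per-subject correlation matrices,
density-thresholded z-weighted networks, global and nodal graph metrics
averaged over densities, three-level group comparison, and Spearman
correlations of network features with the patients' behaviour scores.
A single seed drives all stochastic stages through named substreams, so
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, canine_atlas
from .behavior import correlate_features
from .connectivity import ConnectivityResult, DensityGrid, build_connectivity
from .metrics import metrics_over_densities
from .stats import (
    circuit_pairs,
    edge_value_table,
    nodal_lr_average,
    run_three_level_comparison,
)
from .synthetic import SubjectTimeSeries

__all__ = ["AnalysisResult", "analyze_cohort", "build_subject_tables"]

#: Nodal metrics carried into the symptom-correlation stage.
_CORRELATION_NODAL_METRICS = ("degree", "Eglob", "Cp")


@dataclass
class AnalysisResult:
    """All tables produced by one analysis run."""

    global_table: pd.DataFrame
    nodal_table: pd.DataFrame
    edge_table: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame | None
    metrics_long: pd.DataFrame | None = None
    connectivity: list[ConnectivityResult] | None = None
    warnings: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.comparisons[self.comparisons["p_fdr"] < alpha].reset_index(
            drop=True
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.global_table.to_csv(outdir / "global_metrics.csv")
        self.nodal_table.to_csv(outdir / "nodal_metrics.csv", index=False)
        self.edge_table.to_csv(outdir / "edge_values.csv", index=False)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "significant.json").write_text(
            self.significant().to_json(orient="records", indent=2) + "\n"
        )
        if self.correlations is not None:
            self.correlations.to_csv(outdir / "correlations.csv", index=False)
        if self.metrics_long is not None:
            self.metrics_long.to_csv(outdir / "metrics_long.csv", index=False)
        if self.connectivity is not None:
            from .io import write_connectivity

            for conn in self.connectivity:
                write_connectivity(conn, outdir / "connectivity")


def build_subject_tables(
    subjects: list[SubjectTimeSeries],
    atlas: Atlas | None = None,
    grid: DensityGrid | None = None,
    n_nulls: int = 100,
    seed: int | None = None,
    include_sigma: bool = True,
    include_homotopic_edges: bool = False,
    long_sink: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[ConnectivityResult], list[str]]:
    """Per-subject networks and density-averaged metric tables.

    Returns (global_table, nodal_table, edge_table, connectivity results,
    warnings).  ``global_table`` is indexed by subject with a ``group``
    column; ``nodal_table`` is long format at region level (L/R averaged);
    ``edge_table`` holds the circuit region-pair connection strengths.
    When ``long_sink`` is a list, one long-format DataFrame per subject
    (per-density and density-averaged values, global and nodal level) is
    appended to it for export.
    """
    atlas = atlas or canine_atlas()
    grid = grid or DensityGrid()
    groups = {s.subject_id: s.group for s in subjects}
    ss = np.random.SeedSequence(seed, spawn_key=(ord("m"),))
    child_seeds = ss.spawn(len(subjects))
    conns: list[ConnectivityResult] = []
    global_rows, nodal_rows, notes = [], [], []
    for s, child in zip(subjects, child_seeds):
        conn = build_connectivity(s.data, s.subject_id, grid, names=atlas.names)
        conns.append(conn)
        notes.extend(f"{s.subject_id}: {w}" for w in conn.warnings)
        sm = metrics_over_densities(
            conn,
            n_nulls=n_nulls,
            seed=np.random.default_rng(child),
            node_names=atlas.names,
            include_sigma=include_sigma,
        )
        if sm.n_missing_nodal:
            notes.append(
                f"{s.subject_id}: {sm.n_missing_nodal} disconnected nodal values "
                "excluded from density averages"
            )
        if long_sink is not None:
            long_sink.append(_subject_long_format(s, sm))
        global_rows.append(sm.global_avg.rename(s.subject_id))
        region_avg = nodal_lr_average(sm.nodal_avg, atlas)
        long = region_avg.reset_index(names="region").melt(
            id_vars="region", var_name="metric", value_name="value"
        )
        long.insert(0, "subject_id", s.subject_id)
        long.insert(1, "group", s.group)
        nodal_rows.append(long)
    global_table = pd.DataFrame(global_rows)
    global_table.insert(0, "group", [groups[i] for i in global_table.index])
    global_table.index.name = "subject_id"
    nodal_table = pd.concat(nodal_rows, ignore_index=True)
    pairs = circuit_pairs(atlas, include_homotopic=include_homotopic_edges)
    edge_table = edge_value_table(conns, atlas, pairs, groups=groups)
    return global_table, nodal_table, edge_table, conns, notes


def _subject_long_format(subject, sm) -> pd.DataFrame:
    """Long export: subject, group, density (level value or 'avg'),
    level (global/node), node name (blank for global), metric, value."""
    frames = []
    gl = sm.global_per_density.reset_index().melt(
        id_vars="density", var_name="metric", value_name="value"
    )
    gl_avg = sm.global_avg.rename_axis("metric").reset_index(name="value")
    gl_avg.insert(0, "density", "avg")
    for df in (gl, gl_avg):
        df["level"] = "global"
        df["node"] = ""
        frames.append(df)
    nd = sm.nodal_per_density.reset_index().melt(
        id_vars=["density", "node"], var_name="metric", value_name="value"
    )
    nd_avg = sm.nodal_avg.rename_axis("node").reset_index().melt(
        id_vars="node", var_name="metric", value_name="value"
    )
    nd_avg.insert(0, "density", "avg")
    for df in (nd, nd_avg):
        df["level"] = "node"
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", subject.subject_id)
    out.insert(1, "group", subject.group)
    return out[
        ["subject_id", "group", "density", "level", "node", "metric", "value"]
    ]


def _correlation_features(
    global_table: pd.DataFrame,
    nodal_table: pd.DataFrame,
    conns: list[ConnectivityResult],
    atlas: Atlas,
    patient_ids: list[str],
) -> pd.DataFrame:
    """Feature matrix for the symptom-correlation stage (patients only).

    Global metrics, nodal degree / global efficiency / clustering in the
    circuit regions, and circuit connection strengths including the
    homotopic pairs (prefix ``fc:``, the FDR-corrected family).
    """
    feats = global_table.loc[patient_ids].drop(columns="group")
    feats.columns = [f"global:{c}" for c in feats.columns]
    nod = nodal_table[
        nodal_table["subject_id"].isin(patient_ids)
        & nodal_table["region"].isin(atlas.circuit_regions)
        & nodal_table["metric"].isin(_CORRELATION_NODAL_METRICS)
    ]
    wide = nod.pivot_table(
        index="subject_id",
        columns=["region", "metric"],
        values="value",
        sort=False,
    )
    wide.columns = [f"{r}:{m}" for r, m in wide.columns]
    pairs = circuit_pairs(atlas, include_homotopic=True)
    groups = {c.subject_id: "patient" for c in conns}
    edge = edge_value_table(
        [c for c in conns if c.subject_id in set(patient_ids)], atlas, pairs, groups
    )
    edge_wide = edge.pivot(index="subject_id", columns="pair", values="z")
    edge_wide.columns = [f"fc:{c}" for c in edge_wide.columns]
    return pd.concat([feats, wide, edge_wide], axis=1).loc[patient_ids]


def analyze_cohort(
    subjects: list[SubjectTimeSeries],
    behavior: pd.DataFrame | None = None,
    atlas: Atlas | None = None,
    grid: DensityGrid | None = None,
    n_nulls: int = 100,
    seed: int | None = None,
    stats_mode: str = "auto",
    include_homotopic_edges: bool = False,
    include_sigma: bool = True,
) -> AnalysisResult:
    """Run the full comparison and correlation analysis on a cohort."""
    atlas = atlas or canine_atlas()
    long_sink: list = []
    global_table, nodal_table, edge_table, conns, notes = build_subject_tables(
        subjects,
        atlas=atlas,
        grid=grid,
        n_nulls=n_nulls,
        seed=seed,
        include_sigma=include_sigma,
        include_homotopic_edges=include_homotopic_edges,
        long_sink=long_sink,
    )
    circuit_nodal = nodal_table[
        nodal_table["region"].isin((*atlas.circuit_regions, atlas.control_region))
    ]
    stats_rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(ord("s"),))
    )
    comparisons = run_three_level_comparison(
        global_table, circuit_nodal, edge_table, mode=stats_mode, seed=stats_rng
    )
    correlations = None
    if behavior is not None:
        patient_ids = [s.subject_id for s in subjects if s.group == "patient"]
        feats = _correlation_features(
            global_table, nodal_table, conns, atlas, patient_ids
        )
        correlations = correlate_features(feats, behavior.loc[patient_ids])
    return AnalysisResult(
        global_table=global_table,
        nodal_table=nodal_table,
        edge_table=edge_table,
        comparisons=comparisons,
        correlations=correlations,
        metrics_long=pd.concat(long_sink, ignore_index=True),
        connectivity=conns,
        warnings=notes,
    )
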