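"""Plain-text readers and writers for cohorts and results.

Cohort layout on disk:

* ``timeseries/<subject_id>.tsv`` - T rows x 30 columns, header = atlas
  node names;
* ``manifest.csv`` - subject_id, group;
* ``behavior.csv`` - subject_id plus the 13 C-BARQ scale columns, missing
  scores written as ``ND``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, canine_atlas
from .behavior import C_BARQ_SCALES
from .synthetic import SubjectTimeSeries

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_behavior",
    "read_behavior",
    "write_provenance",
]

_TS_DIR = "timeseries"
_FLOAT_FMT = "%.6f"


def write_cohort(
    subjects: list[SubjectTimeSeries],
    behavior: pd.DataFrame | None,
    outdir: str | Path,
    atlas: Atlas | None = None,
) -> Path:
    """Write per-subject TSVs, the group manifest and the behaviour CSV."""
    atlas = atlas or canine_atlas()
    outdir = Path(outdir)
    (outdir / _TS_DIR).mkdir(parents=True, exist_ok=True)
    header = "\t".join(atlas.names)
    for s in subjects:
        if s.data.shape[1] != atlas.n_regions:
            raise ValueError(f"{s.subject_id}: column count != atlas size")
        np.savetxt(
            outdir / _TS_DIR / f"{s.subject_id}.tsv",
            s.data,
            delimiter="\t",
            header=header,
            comments="",
            fmt=_FLOAT_FMT,
        )
    manifest = pd.DataFrame(
        {"subject_id": [s.subject_id for s in subjects], "group": [s.group for s in subjects]}
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if behavior is not None:
        write_behavior(behavior, outdir / "behavior.csv")
    return outdir


def read_cohort(
    cohort_dir: str | Path, atlas: Atlas | None = None
) -> tuple[list[SubjectTimeSeries], pd.DataFrame | None]:
    """Read a cohort written by :func:`write_cohort`.

    The TSV header of every subject is checked against the atlas node
    names; a mismatch is an explicit schema failure.
    """
    atlas = atlas or canine_atlas()
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        path = cohort_dir / _TS_DIR / f"{row.subject_id}.tsv"
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != atlas.names:
            bad = [c for c in df.columns if c not in atlas.names]
            raise ValueError(
                f"{path.name}: header does not match atlas node names "
                f"(unexpected columns: {bad or 'order differs'})"
            )
        subjects.append(
            SubjectTimeSeries(str(row.subject_id), str(row.group), df.to_numpy())
        )
    behavior_path = cohort_dir / "behavior.csv"
    behavior = read_behavior(behavior_path) if behavior_path.exists() else None
    return subjects, behavior


def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    out = behavior[list(C_BARQ_SCALES)].copy()
    out.index.name = "subject_id"
    out.to_csv(path, na_rep="ND", float_format="%.2f")


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Behaviour CSV with the 13 C-BARQ scale columns; 'ND' or blank = missing."""
    df = pd.read_csv(path, na_values=["ND", ""], index_col="subject_id")
    missing = [s for s in C_BARQ_SCALES if s not in df.columns]
    if missing:
        raise ValueError(f"behaviour CSV lacks scale columns: {missing}")
    return df[list(C_BARQ_SCALES)].astype(float)


def write_provenance(path: str | Path, **fields) -> None:
    """Config echo (seed, versions, parameters) for reproducibility."""
    from . import __version__

    payload = {"caninet_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_connectivity(conn, outdir: str | Path, atlas: Atlas | None = None) -> Path:
    """Persist one subject's raw correlation matrix and thresholded networks.

    Writes ``r_matrix.csv`` (node names as header/index) and one
    ``edges_<density>.tsv`` per level with columns node_i, node_j, z.
    """
    atlas = atlas or canine_atlas()
    outdir = Path(outdir) / conn.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    names = atlas.names
    pd.DataFrame(conn.r_matrix, index=names, columns=names).to_csv(
        outdir / "r_matrix.csv", float_format=_FLOAT_FMT
    )
    for density, z in conn.z_networks.items():
        iu, ju = np.triu_indices(z.shape[0], k=1)
        mask = z[iu, ju] > 0
        edges = pd.DataFrame(
            {
                "node_i": [names[i] for i in iu[mask]],
                "node_j": [names[j] for j in ju[mask]],
                "z": z[iu[mask], ju[mask]],
            }
        )
        edges.to_csv(
            outdir / f"edges_{int(round(density * 100)):02d}.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
    return outdir
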