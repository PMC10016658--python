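"""Synthetic resting-state cohorts with prescribed network structure.

No public scan data exist for the study cohort, so every downstream stage
is exercised on simulated ROI time series.  The generator draws
multivariate Gaussian signals from a target correlation matrix, band-pass
filters them to the resting-state band (0.01-0.1 Hz at TR = 2 s by
default) with a zero-phase FFT mask, and re-standardises the columns.
Because the same filter acts on every column, the instantaneous
correlation structure is preserved in expectation.

The default target matrix mimics a coarse functional organisation:
correlated modules (posterior cortex, frontal/paralimbic cortex,
subcortical-limbic structures, cerebellum), stronger homotopic (L-R)
connectivity within each bilateral region, and weak baseline coupling
between modules.  This modular structure is what gives the thresholded
networks their small-world character.  Group differences are implanted as
correlation-scale deltas on region pairs; the default effect set is the
anxiety-circuit pattern (six hyper-connected pairs, one hypo-connected
pair, patients only).

Patient behaviour scores are generated from a Gaussian copula: the rank
of the subject's named network feature is mapped to a normal score, mixed
with independent noise so that the expected Spearman correlation equals
the configured target, and squashed monotonically into the 0-5 C-BARQ
range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .atlas import Atlas, canine_atlas
from .behavior import C_BARQ_SCALES

__all__ = [
    "GeneratorConfig",
    "SubjectTimeSeries",
    "generate_cohort",
    "cbarq_patient_scores",
    "connectivity_feature",
    "ANXIETY_HYPER_EDGES",
    "ANXIETY_HYPO_EDGE",
    "default_effect_edges",
    "default_behavior_links",
]

#: Region pairs reported hyper-connected in patients.
ANXIETY_HYPER_EDGES: tuple[tuple[str, str], ...] = (
    ("amygdala", "hippocampus"),
    ("amygdala", "mesencephalon"),
    ("amygdala", "thalamus"),
    ("frontal lobe", "hippocampus"),
    ("frontal lobe", "thalamus"),
    ("hippocampus", "thalamus"),
)

#: Region pair reported hypo-connected in patients.
ANXIETY_HYPO_EDGE: tuple[str, str] = ("hippocampus", "mesencephalon")

# Coarse functional modules used for the default target correlation.
_MODULES: tuple[tuple[str, ...], ...] = (
    ("temporal lobe", "parietal lobe", "occipital lobe"),
    (
        "frontal lobe",
        "anterior cingulate gyrus",
        "posterior cingulate gyrus",
        "insular cortex",
    ),
    (
        "hippocampus",
        "thalamus",
        "amygdala",
        "caudate nucleus",
        "piriform lobe",
        "mesencephalon",
        "diencephalon",
    ),
    ("cerebral hemisphere", "vermis"),
)


def default_effect_edges(delta: float = 0.25) -> list[tuple[str, str, float]]:
    """The anxiety-circuit effect pattern on the correlation scale."""
    edges = [(a, b, +delta) for a, b in ANXIETY_HYPER_EDGES]
    edges.append((*ANXIETY_HYPO_EDGE, -delta))
    return edges


def default_behavior_links() -> list[tuple[str, str, float]]:
    """Default symptom links: scale name, network feature, target Spearman."""
    return [
        ("stranger-directed fear", "strength:amygdala", 0.6),
        ("excitability", "strength:amygdala", -0.6),
        ("touch sensitivity", "strength:hippocampus", 0.8),
        ("attachment/attention-seeking", "edge:amygdala-thalamus", 0.85),
        ("familiar dog aggression", "strength:frontal lobe", 0.8),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; defaults follow the study design."""

    n_control: int = 25
    n_patient: int = 13
    n_roi: int = 30
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    passband: tuple[float, float] = (0.01, 0.1)
    base_connectivity: float = 0.3
    between_connectivity: float = 0.05
    homotopic_boost: float = 0.25
    effect_edges: tuple = field(default_factory=lambda: tuple(default_effect_edges()))
    behavior_links: tuple = field(
        default_factory=lambda: tuple(default_behavior_links())
    )
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_timepoints <= self.n_roi:
            raise ValueError("n_timepoints must exceed n_roi")
        lo, hi = self.passband
        nyquist = 0.5 / self.tr_seconds
        if not 0 < lo < hi <= nyquist:
            raise ValueError("passband must satisfy 0 < low < high <= Nyquist")
        if not 0.0 <= self.base_connectivity < 1.0:
            raise ValueError("base_connectivity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for scale, _, rho in self.behavior_links:
            if scale not in C_BARQ_SCALES:
                raise ValueError(f"unknown C-BARQ scale {scale!r}")
            if not -1.0 < rho < 1.0:
                raise ValueError("target Spearman rho must lie in (-1, 1)")


@dataclass
class SubjectTimeSeries:
    """One subject's T x R ROI signal matrix (columns zero-mean)."""

    subject_id: str
    group: str  # "control" | "patient"
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError("group must be 'control' or 'patient'")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x R matrix")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")


# ---------------------------------------------------------------------------
# target correlation structure


def _expand_edges(
    effect_edges, atlas: Atlas, n_roi: int
) -> list[tuple[int, int, float]]:
    """Region-name effect edges -> all spanning 0-based node pairs."""
    out: list[tuple[int, int, float]] = []
    for a, b, delta in effect_edges:
        if isinstance(a, str) or isinstance(b, str):
            if atlas is None:
                raise ValueError("region-name effect edges require an atlas")
            for i, j in atlas.spanning_node_pairs(str(a), str(b)):
                out.append((i, j, float(delta)))
        else:
            i, j = int(a), int(b)
            if not (0 <= i < n_roi and 0 <= j < n_roi) or i == j:
                raise ValueError(f"bad node-index edge ({a}, {b})")
            out.append((min(i, j), max(i, j), float(delta)))
    return out


def base_target_correlation(config: GeneratorConfig, atlas: Atlas | None) -> np.ndarray:
    """Module-structured baseline correlation matrix shared by both groups."""
    n = config.n_roi
    c = np.full((n, n), config.between_connectivity)
    if atlas is not None:
        module_of: dict[int, int] = {}
        for m, bases in enumerate(_MODULES):
            for base in bases:
                if base in atlas.base_names:
                    for node in atlas.nodes_of(base):
                        module_of[node] = m
        for i in range(n):
            for j in range(n):
                if i != j and module_of.get(i) == module_of.get(j):
                    c[i, j] = config.base_connectivity
        for left, right in atlas.homotopic_pairs:
            c[left, right] = c[right, left] = min(
                config.base_connectivity + config.homotopic_boost, 0.95
            )
    else:
        c[:] = config.base_connectivity
    np.fill_diagonal(c, 1.0)
    return c


def _psd_repair(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest-correlation shortcut: clip eigenvalues, renormalise diagonal."""
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    if vals.min() >= floor:
        return c
    vals = np.maximum(vals, floor)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def group_target_correlation(
    config: GeneratorConfig, atlas: Atlas | None, patient: bool
) -> np.ndarray:
    """Target observed correlation matrix for one group (PSD-repaired)."""
    c = base_target_correlation(config, atlas)
    edges = (
        _expand_edges(config.effect_edges, atlas, config.n_roi)
        if patient and len(config.effect_edges)
        else []
    )
    for i, j, delta in edges:
        c[i, j] += delta
        c[j, i] += delta
    offdiag = c[~np.eye(config.n_roi, dtype=bool)]
    if np.any(np.abs(offdiag) >= 1.0):
        raise ValueError("target correlations must satisfy |base + delta| < 1")
    repaired = _psd_repair(c)
    bad = [
        (i, j)
        for i, j, _ in edges
        if abs(repaired[i, j] - c[i, j]) > 0.05
    ]
    if bad:
        raise ValueError(
            f"target covariance not positive semi-definite; PSD repair moved "
            f"effect edges {bad} by more than 0.05"
        )
    return repaired


# ---------------------------------------------------------------------------
# signal generation


def band_limit(x: np.ndarray, tr_seconds: float, passband: tuple[float, float]) -> np.ndarray:
    """Zero-phase FFT band-pass along axis 0 and column re-standardisation."""
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    lo, hi = passband
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("passband contains no resolvable frequency")
    spec = np.fft.rfft(x, axis=0)
    spec[~mask] = 0.0
    y = np.fft.irfft(spec, n=t, axis=0)
    y -= y.mean(axis=0)
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    return y / sd


def _simulate_subject(
    chol: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    t, r = config.n_timepoints, config.n_roi
    x = rng.standard_normal((t, r)) @ chol.T
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal((t, r))
    return band_limit(x, config.tr_seconds, config.passband)


# ---------------------------------------------------------------------------
# behaviour generation


def connectivity_feature(r_matrix: np.ndarray, atlas: Atlas, feature: str) -> float:
    """Simple network features evaluated on a raw correlation matrix.

    ``"edge:regionA-regionB"``: mean correlation over the node pairs
    spanning the two regions.  ``"strength:region"``: mean (over the
    region's nodes) of the summed positive correlations to all other
    nodes.
    """
    kind, _, rest = feature.partition(":")
    if kind == "edge":
        a, _, b = rest.partition("-")
        pairs = atlas.spanning_node_pairs(a, b)
        return float(np.mean([r_matrix[i, j] for i, j in pairs]))
    if kind == "strength":
        nodes = atlas.nodes_of(rest)
        pos = np.clip(r_matrix, 0.0, None).copy()
        np.fill_diagonal(pos, 0.0)
        return float(np.mean(pos[nodes].sum(axis=1)))
    raise ValueError(f"unknown network feature {feature!r}")


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion: rho_P = 2 sin(pi * rho_S / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _behavior_scores(
    feature_values: np.ndarray, rho_target: float, rng: np.random.Generator
) -> np.ndarray:
    """Scores in (0, 5) with expected Spearman rho_target to the feature."""
    n = feature_values.size
    ranks = np.argsort(np.argsort(feature_values)) + 1.0
    z = ndtri((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    rho_p = _spearman_to_pearson(rho_target)
    v = rho_p * z + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    return 5.0 * ndtr(v)


def _behavior_table(
    patients: list[SubjectTimeSeries],
    atlas: Atlas | None,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    index = [p.subject_id for p in patients]
    table = pd.DataFrame(index=index, columns=list(C_BARQ_SCALES), dtype=float)
    table.index.name = "subject_id"
    links = {scale: (feat, rho) for scale, feat, rho in config.behavior_links}
    r_matrices = None
    for scale in C_BARQ_SCALES:
        if scale in links and atlas is not None:
            feat, rho = links[scale]
            if r_matrices is None:
                r_matrices = [np.corrcoef(p.data, rowvar=False) for p in patients]
            values = np.array(
                [connectivity_feature(r, atlas, feat) for r in r_matrices]
            )
            table[scale] = _behavior_scores(values, rho, rng)
        else:
            table[scale] = 5.0 * ndtr(rng.standard_normal(len(index)))
    return table


# ---------------------------------------------------------------------------
# public entry points


def generate_cohort(
    config: GeneratorConfig, atlas: Atlas | None = None
) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Generate the full cohort and the patients' behaviour table.

    Deterministic for a fixed ``config.seed``.  With the default atlas the
    ROI count must be 30; pass ``atlas=None`` (flat correlation structure,
    numeric effect edges only) for other sizes.
    """
    if atlas is None and config.n_roi == 30:
        atlas = canine_atlas()
    if atlas is not None and atlas.n_regions != config.n_roi:
        raise ValueError("atlas size does not match n_roi")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    compensation = 1.0 + config.noise_sd**2

    def observed_to_signal(c: np.ndarray) -> np.ndarray:
        s = c * compensation  # sensor noise dilutes correlations; pre-scale
        np.fill_diagonal(s, 1.0)
        if np.any(np.abs(s[~np.eye(len(s), dtype=bool)]) >= 1.0):
            raise ValueError("noise_sd too large for the requested correlations")
        return _psd_repair(s)

    chol = {
        "control": np.linalg.cholesky(
            observed_to_signal(group_target_correlation(config, atlas, patient=False))
        ),
        "patient": np.linalg.cholesky(
            observed_to_signal(group_target_correlation(config, atlas, patient=True))
        ),
    }
    subjects: list[SubjectTimeSeries] = []
    width = max(2, len(str(max(config.n_control, config.n_patient))))
    for group, count, prefix in (
        ("control", config.n_control, "ctrl"),
        ("patient", config.n_patient, "pat"),
    ):
        for k in range(count):
            data = _simulate_subject(chol[group], config, rng)
            subjects.append(
                SubjectTimeSeries(f"{prefix}{k + 1:0{width}d}", group, data)
            )
    patients = [s for s in subjects if s.group == "patient"]
    behavior = _behavior_table(patients, atlas, config, rng)
    return subjects, behavior


# Verbatim C-BARQ scores of the 13 patients (ND -> NaN), with demographics.
_CBARQ_PATIENT_ROWS = [
    (64, "Jack Russell terrier", "FC", 1.50, 0.80, 0.00, 2.63, 0.50, 3.50, 1.50, 1.83, 0.00, 0.50, 2.00, 1.67, 2.00),
    (66, "Belgian shepherd", "MC", 2.25, 0.00, 0.63, 2.88, 1.00, 3.50, 0.00, 0.17, 0.00, 0.75, 2.83, 0.17, 2.00),
    (71, "Galgo Espanol", "FC", 1.75, 0.00, 0.38, 0.00, 2.50, 1.75, 4.00, 3.83, 0.13, 0.25, 1.17, 3.00, 1.00),
    (64, "White Swiss Shepherd", "FC", 3.50, 3.20, 0.00, 2.50, 0.00, 2.50, 0.75, 0.67, 0.88, 0.50, 1.67, 3.17, 2.00),
    (111, "Akita Inu", "MC", 2.88, 1.00, 0.25, 1.25, np.nan, 2.25, 1.50, 0.00, 0.00, 1.50, 1.00, 2.00, 0.00),
    (90, "Labrador retriever", "MC", 1.50, 0.00, 0.00, 0.75, np.nan, 1.00, 3.00, 2.83, 0.00, 0.50, 2.00, 0.33, 0.00),
    (41, "Spanish water dog", "MC", 3.63, 2.30, 0.00, 1.00, np.nan, 1.50, 0.00, 0.50, 0.50, 1.00, 2.33, 2.67, 0.00),
    (86, "Galgo Espanol", "MC", 0.13, 0.00, 0.00, 4.00, 0.00, 1.25, 3.75, 3.83, 0.00, 0.50, 1.67, 0.17, 1.00),
    (55, "Belgian shepherd", "FC", 3.75, 0.70, 0.00, 0.13, np.nan, 1.00, 1.50, 2.67, 0.00, 1.00, 2.33, 3.67, 4.00),
    (98, "Border collie", "MC", 2.13, 0.00, 0.00, 1.00, np.nan, 2.00, 0.50, 2.00, 0.13, 1.00, 2.67, 1.67, 1.50),
    (57, "American hairless terrier", "FC", 3.75, 0.00, 0.00, 0.75, 0.50, 2.25, 1.75, 2.67, 0.00, 1.25, 2.00, 3.67, 2.00),
    (151, "Jack Russell terrier", "MC", 1.38, 0.30, 0.25, 2.50, 0.00, 0.25, 1.25, 0.67, 1.88, 3.25, 2.67, 3.00, 2.00),
    (39, "English cocker spaniel", "FC", 2.63, 2.00, 0.00, 2.50, 0.50, 2.75, 3.00, 1.00, 0.25, 1.75, 2.33, 2.17, 2.00),
]


def cbarq_patient_scores() -> pd.DataFrame:
    """The 13 patients' published C-BARQ scores (ND encoded as NaN).

    Index is P01..P13; the first three columns are demographics
    (age_months, breed, sex), followed by the 13 scale columns in
    canonical order.
    """
    df = pd.DataFrame(
        _CBARQ_PATIENT_ROWS,
        columns=["age_months", "breed", "sex", *C_BARQ_SCALES],
        index=[f"P{i + 1:02d}" for i in range(13)],
    )
    df.index.name = "subject_id"
    return df
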