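"""Spearman correlations between network features and C-BARQ scores.

The C-BARQ owner questionnaire summarises canine temperament in 13 scales
scored 0-5.  Scores may be missing ("ND"); missing values are dropped
pairwise per correlation and the number of usable animals is reported.
Note that for trainability a higher score means *better* behaviour, the
opposite polarity of the other scales; this is metadata only and no score
is numerically flipped.

Following the study's statistical plan, false-discovery-rate correction is
applied only within the family of connection-strength correlations;
metric-symptom correlations are reported uncorrected (a flag allows
correcting everything).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fdr_adjust

__all__ = [
    "C_BARQ_SCALES",
    "SpearmanResult",
    "spearman_rho",
    "correlate_features",
]

#: The 13 C-BARQ scale names, fixed column order.
C_BARQ_SCALES: tuple[str, ...] = (
    "trainability",
    "stranger-directed aggression",
    "owner-directed aggression",
    "dog-directed aggression",
    "familiar dog aggression",
    "chasing",
    "stranger-directed fear",
    "nonsocial fear",
    "separation-related problems",
    "touch sensitivity",
    "excitability",
    "attachment/attention-seeking",
    "energy",
)

#: Scales where a higher score means better (not worse) behaviour.
REVERSED_SCALES: frozenset[str] = frozenset({"trainability"})

_EXACT_N_MAX = 9  # exact permutation p-value up to this many pairs


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n_used: int
    note: str = ""

    @property
    def computed(self) -> bool:
        return math.isfinite(self.rho)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full permutation distribution of Spearman rho.

    Enumerates all n! pairings of the (mid)ranks; feasible for n <= 9.
    """
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    ax = rx - rx.mean()
    ay = ry - ry.mean()
    denom = math.sqrt((ax**2).sum() * (ay**2).sum())
    rhos = ay[perms] @ ax / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rho(
    x: np.ndarray, y: np.ndarray, min_n: int = 5
) -> SpearmanResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    rho is the Pearson correlation of midranks.  The p-value comes from
    the exact permutation distribution when n_used <= 9, otherwise from
    the t approximation.  Fewer than ``min_n`` complete pairs, or zero
    rank variance in either variable, yields a flagged NaN result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_used = int(ok.sum())
    if n_used < min_n:
        return SpearmanResult(float("nan"), float("nan"), n_used, "too few complete pairs")
    xs, ys = x[ok], y[ok]
    rx = sps.rankdata(xs)
    ry = sps.rankdata(ys)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(float("nan"), float("nan"), n_used, "zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n_used <= _EXACT_N_MAX:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(xs, ys).pvalue)
    return SpearmanResult(rho, p, n_used)


def correlate_features(
    features: pd.DataFrame,
    behavior: pd.DataFrame,
    connection_features: set[str] | None = None,
    scales: tuple[str, ...] = C_BARQ_SCALES,
    min_n: int = 5,
    fdr_all: bool = False,
) -> pd.DataFrame:
    """Correlate every network feature with every behaviour scale.

    ``features``: DataFrame indexed by subject_id, one column per network
    feature (global metric, nodal metric or connection strength).
    ``behavior``: DataFrame indexed by subject_id with the C-BARQ scale
    columns; NaN encodes ND.  Rows are aligned on subject_id and must
    match exactly.

    The connection-strength family (``connection_features``, defaulting to
    columns named ``fc:...``) receives Benjamini-Hochberg correction per
    scale; other features keep raw p-values unless ``fdr_all``.
    """
    missing = features.index.difference(behavior.index)
    extra = behavior.index.difference(features.index)
    if len(missing) or len(extra):
        raise ValueError(
            "subject ids do not match between features and behaviour tables: "
            f"missing={list(missing)}, extra={list(extra)}"
        )
    behavior = behavior.loc[features.index]
    if connection_features is None:
        connection_features = {c for c in features.columns if str(c).startswith("fc:")}
    unknown = [s for s in scales if s not in behavior.columns]
    if unknown:
        raise ValueError(f"behaviour table lacks scales: {unknown}")

    rows = []
    for scale in scales:
        y = behavior[scale].to_numpy(dtype=float)
        for feat in features.columns:
            res = spearman_rho(features[feat].to_numpy(dtype=float), y, min_n=min_n)
            rows.append(
                {
                    "feature": feat,
                    "scale": scale,
                    "family": "connection" if feat in connection_features else "metric",
                    "rho": res.rho,
                    "p_raw": res.p,
                    "n_used": res.n_used,
                    "note": res.note,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for scale in scales:
        fam = (out["scale"] == scale) & (
            (out["family"] == "connection") | fdr_all
        ) & out["p_raw"].notna()
        if fam.any():
            out.loc[fam, "p_fdr"] = fdr_adjust(out.loc[fam, "p_raw"].tolist())
    return out
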