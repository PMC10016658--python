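# Methods

`caninet` implements a graph-theoretical analysis of resting-state
functional connectivity in a 30-region canine brain parcellation, together
with a synthetic-cohort generator that reproduces the statistical
structure of a 25-control / 13-patient anxiety study so that every stage
can be exercised and calibrated without scan data.

## The analysis model

Each subject contributes a T × 30 matrix of ROI-averaged BOLD time series
(TR = 2 s, band-passed to 0.01–0.1 Hz).  Functional connectivity is the
Pearson correlation r_ij between ROI pairs.  Networks are built per
subject at seven density levels d ∈ {0.20, 0.25, …, 0.50}: the k =
round(d · R(R−1)/2) strongest *positive* correlations are kept (negative
correlations are discarded outright, not ranked by magnitude), then the
surviving weights are Fisher-transformed, z = atanh(r).  Because atanh is
strictly increasing, thresholding before or after the transform selects
identical edge sets; the package thresholds first and a property test
asserts the commutation.

Rounding of k is half-away-from-zero; ties at the cutoff value are broken
lexicographically by (row, column) so that runs are reproducible.  Both
conventions are arbitrary at the margins and are recorded here rather than
hidden.

## Graph measures

All measures act on the symmetric, nonnegative z-weighted adjacency with
zero diagonal.  Path-based measures use edge lengths 1/w.

* **Degree (strength)** k_i = Σ_j w_ij.
* **Characteristic path length** Lp_i = mean of the finite shortest-path
  distances from i; the global Lp averages over all ordered finite pairs.
  Disconnected pairs are *excluded* rather than imputed — at 20% density a
  node is occasionally isolated, and imputing a surrogate distance would
  contaminate the density average.  Excluded counts are logged.
* **Global efficiency** Eglob_i = (R−1)⁻¹ Σ_j 1/d_ij with 1/∞ = 0, so
  disconnection contributes zero instead of breaking the mean.
* **Clustering coefficient** Cp_i: Onnela geometric-mean form,
  Cp_i = 2/(k_i(k_i−1)) Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, with weights ŵ
  normalised by the maximum weight of the same thresholded network.  On
  uniform weights this reduces exactly to the binary clustering
  coefficient (asserted against networkx).  Nodes with fewer than two
  neighbours get Cp_i = 0.
* **Local efficiency** Eloc_i: the global efficiency of the subgraph
  induced by i's neighbours, original weights, centre removed; 0 for
  degree < 2.
* **Small-worldness** σ = (Cp/⟨Cp_rand⟩) / (Lp/⟨Lp_rand⟩) against 100
  degree-preserving Maslov–Sneppen surrogates: the binary topology is
  rewired with 10 successful double-edge swaps per edge (attempt cap
  100×), and the original weight multiset is randomly reassigned to the
  rewired edges.  A surrogate with no finite path is redrawn (cap 10).
  σ is computed per density and then density-averaged, consistent with how
  every other metric is averaged.

Every metric is computed at each density and summarised as the arithmetic
mean across the seven levels.  All-pairs shortest paths use min-plus
matrix squaring, a dense O(R³ log R) recurrence that is considerably
faster than per-call sparse Dijkstra at R = 30 and below; agreement with
Dijkstra and with exhaustive path enumeration (graphs ≤ 6 nodes) is
asserted in the test suite.  Local-efficiency subgraphs are batched by
neighbourhood size and solved as one tensor recurrence per size.

## Group statistics

Three comparison levels, all Mann–Whitney U, all Benjamini–Hochberg
corrected within their own family:

1. **Global** — the six density-averaged global metrics (mean degree, Lp,
   Eglob, Cp, Eloc, σ); FDR across the six tests.
2. **Nodal** — five nodal metrics in the five anxiety-circuit regions
   (amygdala, frontal lobe, hippocampus, mesencephalon, thalamus) plus the
   vermis negative control.  Nodal values of bilateral regions are the
   arithmetic mean of left and right (a disconnected hemisphere falls back
   to the available side, logged); midline regions pass through.  FDR is
   applied across the six regions *within* each metric — the most literal
   reading of "correcting multiple comparisons between nodes".
3. **Edge** — region-level connection strength: for a pair of bilateral
   regions the z-values of all four intra- and interhemispheric node pairs
   are averaged, then averaged over the seven densities.  A zero z is a
   genuine sub-threshold observation and stays in the average.  All ten
   circuit pairs are tested (homotopic L–R pairs optionally, off by
   default); FDR across the tested connections.

U is reported as min(U₁, U₂) ≤ n₁n₂/2.  Modes: `exact` enumerates the
rank-sum null (with ties, a ≥10⁵-resample permutation of the observed
data); `approximate` uses the normal approximation with tie-corrected
variance and continuity correction; `auto` picks exact for tie-free
samples up to 30 observations total, otherwise approximate.  At the
study's 25 + 13 the auto path is the approximation, which the tests show
agrees with a 10⁵-permutation p to within 0.01.

## Behaviour correlations

Spearman's ρ between network features (global metrics; nodal degree,
Eglob, Cp in the circuit regions; circuit connection strengths including
homotopic pairs) and the 13 C-BARQ scales across patients.  Missing scores
("ND") are deleted pairwise with the usable n reported; below 5 complete
pairs the correlation is marked not computed — the published table itself
bottoms out at 8 usable values for familiar-dog aggression, and anything
much smaller is noise.  ρ is the Pearson correlation of midranks; p comes
from the full permutation distribution when n ≤ 9 and from the
t-approximation otherwise.  FDR is applied only within the
connection-strength family, mirroring the study's plan (a flag corrects
everything).  Trainability's reversed polarity (higher = better) is
metadata; no scores are flipped.

## The synthetic cohort

Signals are multivariate Gaussian draws from a group-level target
correlation matrix, band-limited with a zero-phase FFT mask (which leaves
instantaneous cross-correlations unchanged in expectation and makes the
out-of-band power identically zero), and re-standardised per column.
Additive white sensor noise of standard deviation `noise_sd` dilutes
correlations by 1/(1+sd²); the generator pre-compensates the target so the
*observed* correlations converge to the configured values (verified at 200
subjects, T = 500, tolerance 0.05).

The default target matrix is modular rather than flat: four coarse
functional modules (posterior cortex; frontal/paralimbic cortex;
subcortical–limbic structures including mesencephalon and diencephalon;
cerebellum) with within-module correlation `base_connectivity` = 0.3,
between-module baseline 0.05, and homotopic L–R edges boosted by 0.25.  A
flat matrix would threshold into an Erdős–Rényi-like graph with σ ≈ 1;
modular structure is what gives real resting-state networks — and these
synthetic ones — their small-world character.  Non-PSD targets are
repaired by eigenvalue clipping and diagonal renormalisation; if the
repair moves any implanted effect edge by more than 0.05 the generator
fails loudly, naming the offending edges.

Group differences are implanted as correlation-scale deltas on region
pairs, expanded to all spanning node pairs.  The default pattern is the
anxiety-circuit finding: +0.25 on amygdala–hippocampus,
amygdala–mesencephalon, amygdala–thalamus, frontal lobe–hippocampus,
frontal lobe–thalamus and hippocampus–thalamus, and −0.25 on
hippocampus–mesencephalon, patients only.

Behaviour scores are generated from a Gaussian copula: the patient's named
network feature is rank-transformed to Blom normal scores z, mixed with
independent noise as v = ρ_P z + √(1−ρ_P²) ε where ρ_P = 2 sin(πρ_S/6)
converts the requested Spearman ρ_S to the bivariate-normal Pearson value,
and squashed monotonically to the C-BARQ range as 5Φ(v).  This attains the
target rank correlation in expectation in closed form, with no calibration
loop.  Unlinked scales are uniform on [0, 5].

The scan length is not derivable from the acquisition protocol, so T = 180
volumes (6 min at TR = 2 s) is the default — enough for stable 30 × 30
correlations while keeping whole-cohort simulations cheap.

### What the generator does not emulate

No head motion, scanner drift, physiological nuisance signals, anesthesia
depth effects, spatial-smoothing-induced dependence between neighbouring
ROIs, breed or age heterogeneity, or voxel-space artefacts of any kind.
Passing tests therefore demonstrate that the *pipeline* is correct and
calibrated under its own assumptions — not that those confounds would be
handled gracefully in real acquisitions, where they are the dominant
failure modes.

## Calibration and recovery checks

* **Type-I error**: on 500 cohorts with no implanted effect, the vermis
  control region survives nodal FDR in ≤ 7% of runs at nominal α = 0.05.
* **Power / sign**: with the default ±0.25 deltas, each of the seven
  implanted connections is recovered with the correct direction in ≥ 80%
  of 50 cohorts (in practice near 100%).
* **Small-world**: both groups' density-averaged σ (100 nulls) exceeds 1
  on default cohorts; σ of the null model applied to its own draws
  concentrates at 1.
* **Behaviour links**: a configured ρ_S = 0.9 at n = 13 patients is
  recovered at ρ ≥ 0.6 in ≥ 90% of 100 cohorts.

Problem sizes used throughout (500 null cohorts, 50 recovery cohorts, 100
behaviour seeds, 100 rewired nulls per graph, 200 random graphs per oracle
sweep) were chosen as the smallest sets at which the binomial tolerances
above are meaningful.

## Known limitations

* The exact edge-count convention of the original toolbox (round vs floor
  at the density cutoff, disconnected-node handling) is not recoverable;
  the package's conventions are fixed and documented above.
* σ is computed per density then averaged; computing it once on a
  density-averaged network is a defensible alternative that was not
  chosen.
* Edge-level FDR is applied across the ten circuit pairs; whether homotopic
  connections belonged to the original family is unknown, so they are
  excluded from the comparison family by default and available by flag.
* The approximate Mann–Whitney path relies on the normal approximation at
  n = 13 + 25 with many zero ties in edge-level data; the tie-corrected,
  continuity-corrected form is accurate to ~0.01 there, which is small
  against the 0.05 decision threshold but not zero.
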