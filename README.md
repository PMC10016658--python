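# caninet

Graph-theoretical analysis of resting-state functional brain networks in
dogs, built for studies comparing anxious patients with healthy controls
on a 30-region canine parcellation.

Anxiety in dogs, as in humans, is thought to involve an "anxiety circuit"
— amygdala, frontal lobe, hippocampus, mesencephalon and thalamus — whose
functional coupling can be measured with resting-state fMRI.  `caninet`
takes per-subject ROI time series, builds weighted functional networks,
quantifies their topology, and asks two questions: *do patients and
controls differ*, at the global, nodal and connection level, and *do
network features track behaviour*, as rated by the 13-scale C-BARQ owner
questionnaire?

## What it computes

For each subject with a T × 30 time-series matrix:

1. **Connectivity** — the 30 × 30 Pearson matrix; at each network density
   d ∈ {20%, 25%, …, 50%} the top k = round(d·435) positive correlations
   are kept and Fisher-transformed, z = atanh(r).  Negative weights are
   discarded.
2. **Graph metrics** per density, then density-averaged: strength
   (weighted degree), characteristic path length Lp, global efficiency
   Eglob, Onnela weighted clustering Cp, local efficiency Eloc, and
   small-worldness σ = (Cp/Cp_rand)/(Lp/Lp_rand) against 100
   Maslov–Sneppen degree-preserving rewired surrogates.  Path lengths use
   1/w edge lengths.
3. **Statistics** — Mann–Whitney U (reported as min(U₁,U₂)) with
   Benjamini–Hochberg FDR per family: the 6 global metrics; the 5 nodal
   metrics across circuit regions + vermis control (left/right averaged);
   the 10 circuit region-pair connection strengths (intra- and
   interhemispheric z averaged, sub-threshold = 0).
4. **Behaviour** — Spearman ρ between network features and C-BARQ scales
   across patients, pairwise deletion for missing ("ND") scores, exact
   permutation p for n ≤ 9, FDR within the connection-strength family.

Because no public scan data exist for such cohorts, the package ships a
synthetic-cohort generator (`caninet.synthetic`) producing band-limited
(0.01–0.1 Hz at TR = 2 s) signals with a modular target correlation
structure, implanted circuit-edge group effects, and behaviour scores with
configurable rank correlation to network features.  The published C-BARQ
score table of the 13 patients is packaged verbatim
(`caninet.cbarq_patient_scores()`).

## Worked example

```bash
caninet simulate --out cohort --seed 1          # 25 controls + 13 patients
caninet analyze  --cohort cohort --out results --seed 1   # ~2.5 min
caninet report   --results results
```

The report lists every FDR-significant finding.  With seed 1 the
edge-level block recovers exactly the implanted anxiety-circuit pattern —
six hyper-connections and the hippocampus–mesencephalon hypo-connection:

```
| level | target                      | U    | p (FDR) | direction          |
|---|---|---|---|---|
| edge  | amygdala - hippocampus      | 0.0  | 0.0000  | higher in patients |
| edge  | amygdala - mesencephalon    | 14.0 | 0.0000  | higher in patients |
| edge  | amygdala - thalamus         | 11.0 | 0.0000  | higher in patients |
| edge  | frontal lobe - hippocampus  | 15.0 | 0.0000  | higher in patients |
| edge  | frontal lobe - thalamus     | 3.0  | 0.0000  | higher in patients |
| edge  | hippocampus - mesencephalon | 22.0 | 0.0000  | lower in patients  |
| edge  | hippocampus - thalamus      | 5.0  | 0.0000  | higher in patients |
```

U is min(U₁,U₂) out of n₁n₂ = 325, so 0 means complete group separation of
that connection's strength.  The behaviour block recovers the configured
symptom links, e.g. hippocampal degree vs touch sensitivity (ρ = 0.709,
p = 0.0067, n = 13) and the amygdala–thalamus connection vs
attachment/attention-seeking.  Per-subject global metrics land in
physically sensible ranges (e.g. subject `ctrl01`: mean degree 3.48,
Lp 6.28, Eglob 0.21, Cp 0.30, σ 1.51).

The same analysis runs on real data laid out as one TSV per subject
(T rows × 30 columns, header = atlas region names), a `manifest.csv` with
subject_id and group, and an optional `behavior.csv` with the C-BARQ
columns; see `caninet atlas` for the region table.

## Layout

```
src/caninet/
  atlas.py         30-region parcellation, hemispheres, circuit membership
  synthetic.py     cohort generator + published score table
  connectivity.py  Pearson -> density threshold -> Fisher z
  metrics.py       weighted graph measures, rewired-null small-worldness
  stats.py         Mann-Whitney / FDR / L-R and edge averaging / 3-level comparison
  behavior.py      Spearman correlations with C-BARQ scales
  pipeline.py      end-to-end orchestration
  io.py, cli.py    TSV/CSV readers-writers and the command line
docs/methods.md    modelling choices, conventions and limitations
```
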