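# cpibind

Tools for tracking checkpoint-inhibitor (CPI) drug–target occupancy in
single-cell and spatially resolved transcriptomics, built for the analysis
patterns of anti-PD-1-treated gut tissue (e.g. CPI-colitis vs ulcerative
colitis vs healthy controls):

* **Hashtag demultiplexing** of pooled CITE-seq reactions: CLR
  normalization, k-medoids initialization, per-tag negative-binomial count
  thresholds (99th percentile), singlet/doublet/negative calls.
* **Drug-occupancy calling**: anti-PD-1 therapeutic antibodies (nivolumab,
  pembrolizumab) compete with the detection antibody for the PD-1 epitope,
  so occupied cells show suppressed PD-1 antibody-derived-tag (ADT) signal
  while *PDCD1* mRNA is unaffected.  A quantile regression forest trained on
  untreated cells predicts each cell's full conditional PD-1 tag
  distribution from drug-blind features; treated cells whose measured
  signal falls in the lower tail (`u = F̂(measured | x) < α`) are called
  CPI-bound at confidence α ∈ {0.01, 0.05, 0.10, 0.15}.
* **Spatial receptor–ligand co-localization**: a distance-weighted,
  neighborhood-smoothed product score
  `S_i = (Σ_j d_j L_j / n)·(Σ_j d_j R_j / n)` per spot or cell, with a
  profile-shuffling permutation null, empirical p-values, Benjamini–Hochberg
  FDR (< 5% ⇒ positive) and GLM region/condition enrichment blocking on gene
  detection rate.
* **Spatial niches and tissue networks**: niches clustered from
  adjacent-neighbor cell-type composition; crypt-top cluster adjacency
  networks (0 < dist < 4, self-loops kept); per-condition cell-type
  co-occurrence networks (Pearson r ≥ 0.15, p < 0.01, positive only).
* **Synthetic data generators** with ground truth for every stage, so all
  statistical guarantees are testable without access to patient data.

## Worked example: calling drug-bound T cells

```python
import numpy as np
from cpibind import SimCiteSeqConfig, simulate_citeseq, PdOccupancyModel

# 7000 T cells, 30% of donors CPI-treated; on bound cells the drug blocks
# 87.5% of ADT detection (blocking factor 0.125)
ds, truth = simulate_citeseq(
    SimCiteSeqConfig(n_cells=7000, frac_treated=0.3, n_donors=10, seed=2))

model = PdOccupancyModel.from_dataset(ds)
res = model.fit(seed=2)          # selection + quantile regression forest
print(res.summary())

treated = np.where(model.treated)[0]
calls = res.call_bound(treated)  # u and bound flags per confidence level
frac = res.cluster_fractions(truth.cells["cluster"].to_numpy()[treated])
print(frac)
```

Output (abridged):

```
PD-1 occupancy model (quantile regression forest)
====================================================
training cells (untreated):   2773
random hold-out cells:        1366
held-out donor:               9 (709 cells)
selected features (10): embed_0, embed_4, embed_7, embed_9, embed_12,
embed_16, embed_19, embed_21, embed_23, pdcd1_norm

validation (predicted median vs measured):
  random_holdout   n=  1366  r=0.841
  heldout_donor    n=   709  r=0.822

decision rule: one-sided lower (u < alpha); epitope blocking can only
suppress the measured tag signal

           n  fraction  ci_low  ci_high    ci_method
cluster
1        431     0.297   0.032    0.070  conditional
4        467     0.296   0.030    0.066  conditional
...
```

The validation correlations (~0.84) show the forest predicts the measured
CLR PD-1 tag signal of *untreated* hold-out cells well.  Per-cluster bound
fractions (here ~0.27–0.30, matching the simulated 30% occupancy) are
reported next to a Monte-Carlo interval drawn from each cell's model
conditional distribution — the band of fractions expected if the cluster's
cells behaved like untreated cells (~α), so a fraction far above the band
indicates genuine occupancy.  Against ground truth this run recovers bound
cells with sensitivity 0.83 and specificity 0.95 at α = 0.05.

## Scoring spatial receptor–ligand co-localization

```python
from cpibind import (SimSpatialConfig, PlantedPair, simulate_spatial,
                     RlColocalization, WeightScheme)

smap, truth = simulate_spatial(SimSpatialConfig(
    lattice="hex", n_rows=100, n_cols=100,
    planted_pairs=[PlantedPair("G0", "G1", (50.0, 43.3), 1.05, 5.0)],
    seed=1))
res = RlColocalization(smap, [("G0", "G1")],
                       WeightScheme.from_pitch(1.0)).fit(n_perm=100, seed=1)
print(res.summary())             # positive locations at FDR < 5%
```

A command-line interface mirrors the library:
`cpibind simulate|demux|call-bound|rl-score|niches|adjacency-net|cooccurrence-net`.

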