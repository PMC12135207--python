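# cytoqot

Cohort-level comparison of single-cell mass cytometry (CyTOF) samples with
quantized optimal transport (QOT).

Conventional CyTOF analysis gates or clusters cells *within* a sample and
compares cohorts only through subpopulation proportions, which discards
expression-level differences. `cytoqot` instead treats each sample — an
`n_cells x n_markers` matrix of transformed intensities — as a
high-dimensional probability distribution and measures distances *between
samples* directly:

1. **Quantization.** Each sample `G_k` is summarized by a Gaussian mixture
   `w_k = sum_h alpha_{k,h} N(mu_{k,h}, Sigma_{k,h})` (EM-fitted; component
   count chosen by BIC or fixed).
2. **Transport.** The distance between two samples is the exact optimal
   transport cost between their mixtures,

   `MW2^2(w_i, w_j) = min_T sum_pq T_pq C_pq`, with `T 1 = alpha_i`,
   `T' 1 = alpha_j`, `T >= 0`,

   where `C_pq = W2^2(N(mu_{i,p}, Sigma_{i,p}), N(mu_{j,q}, Sigma_{j,q}))`
   is the closed-form squared 2-Wasserstein distance between Gaussians
   (`||mu_p - mu_q||^2` plus the Bures covariance term). The square root of
   the objective is reported, so the result is a metric on mixture space.
   A scalable variant uses the cosine distance between component means.

On top of the distance sit the two cohort analyses this package exists for:

- **Leave-one-out marker instability** (`cytoqot.perturbation`): for each
  subject, distances from the baseline draw to each later draw are computed
  with the full panel (`D_t_full`) and with each marker excluded
  (`D_t_excl`); `delta_total = sum_t |D_t_full - D_t_excl|` ranks markers
  from least to most temporally perturbing, and per-subject rankings
  aggregate into a cohort rank-frequency table (Rank 1 = most perturbing).
- **Fingerprint marker-subset search** (`cytoqot.fingerprint`): every
  marker subset of sizes 2–6 is scored by the silhouette of the subject
  partition on the pairwise QOT distance matrix; the best-scoring subsets
  are marker combinations under which a subject's timepoints cluster
  together — an immune "fingerprint".

A built-in simulator (`cytoqot.synthetic`) generates multi-subject,
multi-timepoint cohorts of Gaussian cell-type blobs moving along branched,
curved or Y-shaped trajectories (3 subjects x 3 timepoints, 2/3/2 cell
types, 7,000 cells per subject by default) for benchmarking.

## Worked example

```python
import cytoqot as cq

study = cq.generate_benchmark_study(seed=0)            # 9 samples, 21,000 cells
dm = cq.pairwise_distances(study, config=cq.QotConfig(seed=0))
score = cq.cluster_and_score(dm, n_clusters=3)

print(f"d(S1_T1, S1_T2) = {dm.values[0, 1]:.3f}")      # within-subject drift
print(f"d(S1_T1, S2_T1) = {dm.values[0, 3]:.3f}")      # between subjects
print(f"ARI = {score.ari:.2f}  silhouette = {score.silhouette_true:.3f}")
```

prints

```
d(S1_T1, S1_T2) = 1.705
d(S1_T1, S2_T1) = 12.352
ARI = 1.00  silhouette = 0.764
```

Within-subject distances (temporal drift, ~1.7) are an order of magnitude
smaller than between-subject distances (~12), so the 9x9 matrix is
block-diagonal by subject; average-linkage clustering into 3 clusters
recovers the subjects exactly (adjusted Rand index 1.0) and the subject
partition has a clearly positive silhouette.

The same workflows are available from the shell:

```bash
cytoqot simulate  --out runs/sim --seed 0          # write the benchmark study
cytoqot distance  --manifest runs/sim/manifest.tsv --out runs/dist
cytoqot loo       --manifest runs/sim/manifest.tsv --out runs/loo --plots
cytoqot fingerprint --manifest runs/sim/manifest.tsv --out runs/fp --sizes 2:4
cytoqot benchmark --out runs/bench --seed 0        # metrics.json with ARI
```

Real studies are described by a manifest (`sample_id, subject_id,
timepoint, path`) pointing at FCS 3.0/3.1 files (arcsinh transform with
cofactor 5 applied by default) or delimited text (assumed pre-transformed).

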