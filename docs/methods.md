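# Methods

## Model

A cytometry sample is an `n_k x m` matrix of transformed marker intensities,
treated as `n_k` draws from an unknown distribution on `R^m`. Each sample is
quantized as a Gaussian mixture `w_k = sum_h alpha_{k,h} N(mu_{k,h},
Sigma_{k,h})` fitted by EM. The distance between two samples is the optimal
transport cost between their mixtures: mass `alpha_{i,p}` at component `p`
must be routed to the components of the other mixture, paying per unit mass
the squared 2-Wasserstein distance between the two Gaussians,

    W2^2(N_a, N_b) = ||mu_a - mu_b||^2
                     + Tr(S_a + S_b - 2 (S_a^{1/2} S_b S_a^{1/2})^{1/2}).

The transport problem is a small exact linear program (component counts are
at most ~10), solved with the HiGHS LP solver through
`scipy.optimize.linprog`; entropic/Sinkhorn smoothing is deliberately not
used. The reported distance is the square root of the optimal objective,
which makes the construction a metric on mixture space (nonnegativity,
symmetry, identity and the triangle inequality are enforced by the test
suite on random mixtures). The raw objective remains available on the
returned transport plan. A scalable alternative cost — `1 - cos(mu_p,
mu_q)` between component means, treating mixtures as point clouds — is
exposed as `cost_mode="cosine"`; there the raw objective is reported (it is
not a squared quantity). A zero-norm mean makes the cosine cost undefined
and raises rather than adopting a 0-or-1 convention, since it can only arise
from pathological preprocessing.

Modeling assumptions worth keeping in mind: the GMM is a *summary*, not a
claim that cell populations are Gaussian; transport is between mixture
components, not individual cells, so the distance is exact for the fitted
mixtures but approximate for the raw clouds; and all markers enter the
ground cost with equal weight, so the scale of the input transform matters.

## Quantization choices

- **Component count.** Default: BIC over `H = 1..10`. The sweep stops after
  two consecutive BIC increases (`bic_patience=2`); the BIC curve for these
  mixtures is near-unimodal, and pruning the tail roughly halves fit cost
  with no effect on the selected model in practice. Set
  `bic_patience=None` for the exhaustive sweep, or `selection="fixed"` for
  a fixed `H`.
- **Covariance structure.** Full covariances by default (the Gaussian-W2
  ground cost uses the whole matrix); `"diag"` is available for stability
  at high marker counts. A jitter of `reg_covar=1e-6` on covariance
  diagonals guards the matrix square root.
- **Determinism.** EM is seeded, and cell rows are put in lexicographic
  order before fitting, making fits bit-identical under any permutation of
  cells in the input file (k-means++ initialization is otherwise sensitive
  to row order). Components are sorted by descending weight (ties broken by
  the first mean coordinate) for stable serialization.
- **Numerics.** Matrix square roots use symmetric eigendecomposition with
  negative eigenvalues clamped to zero. `W2^2` values below `1e-12` times
  the problem scale (mean gap plus covariance traces) are floored to zero:
  eigendecomposition noise is ~1e-15 of scale, and without the floor the
  square-root convention would inflate that noise to ~1e-7 "distances"
  between identical mixtures. Values more negative than `-1e-8` of scale
  raise instead of being clamped.
- **Caching.** GMM fits are memoized by (matrix content hash, marker
  subset, fit settings), in memory and optionally on disk, so the
  leave-one-out sweep and repeated subset searches reuse fits where valid.
  Marker-subset refits use the same seed as the full-panel fit, isolating
  the exclusion effect from fit stochasticity.

## Preprocessing

Raw CyTOF intensities are arcsinh-transformed, `x -> asinh(x / 5)`, when
read from FCS files; delimited input is assumed already transformed. Both
defaults are overridable — the transform is community convention, not a
requirement of the method. Cells with non-finite values are rejected with a
location report rather than imputed, since silent imputation would bias
distribution distances. Marker panels are harmonized across samples to the
sorted intersection of names, a deterministic column order independent of
per-file channel order.

## Leave-one-out instability

Per subject, the baseline is the earliest observed timepoint; every later
draw contributes. `delta_t = |D_t_full - D_t_excl|` is an absolute value at
both the per-timepoint and the total level, so `delta_total` sums
magnitudes and cannot cancel. Subjects are ranked least-to-most perturbing
with lexicographic tie-breaking; the cohort table counts ranks from the
most-perturbing end (Rank 1 = most perturbing), and each rank column sums
to 1 across markers by construction.

## Fingerprint search

Candidate subsets default to all shared markers at sizes 2–6; the search is
exhaustive, with a guard at 20,000 subsets (override with `force=True`).
Silhouette labels are subject identities directly — no clustering step —
matching the question "do a subject's timepoints sit together?"; samples in
singleton classes contribute 0, the common convention. Hierarchical
clustering (average linkage on the precomputed distance matrix; complete
and single selectable) plus the adjusted Rand index is used only for
benchmark evaluation, and both the true-label and the induced-assignment
silhouettes are reported since either convention is defensible. The 2-D
UMAP embedding and the same-label/threshold-0.8 connection graph are
illustrative visual aids: UMAP is stochastic across library versions, so no
quantitative claim rests on them.

## Synthetic benchmark

The simulator emulates a cohort of three subjects sampled at three
timepoints, with 2, 3 and 2 Gaussian cell-type blobs at T1/T2/T3 and 7,000
cells per subject. Subject 1 follows a branched trajectory (types diverge
T1→T2 and again T2→T3) with disproportionately sized types — 60/40, then
40/35/25, then 55/45 of per-timepoint totals 2,000/3,000/2,000 — subject 2
a smooth circular arc, subject 3 a Y-shaped split from a common lineage
point; subjects 2 and 3 use 1,000 cells per type. Defaults: `m = 10`
markers; trajectory geometry in markers 1–2; subject identity offsets at
the corners of an equilateral triangle (side 12) in markers 3–4; blob
standard deviation 1; drift magnitude 1.5. These place between-subject
distances roughly an order of magnitude above within-subject temporal
drift, the regime in which sample-level clustering should be — and is —
exact (ARI 1.0 across seeds), while the drift remains well above the
sampling-noise floor.

What the simulator does *not* model: marker-specific biology, heavy-tailed
or zero-inflated intensity distributions, batch or acquisition effects,
doublets, or uneven draws per subject. Passing benchmarks therefore
demonstrate that the pipeline recovers block structure and injected
perturbation signals under clean Gaussian conditions, not that it is robust
to real-data artifacts. Cell-type proportions for the unequal subject are a
documented default (only "disproportionate, 7,000 total" is externally
constrained), so the simulator's clustering geometry — e.g., its exact
silhouette value — is a property of these defaults, not a universal
constant.

## Problem sizes

The default test and benchmark configurations use the full 7,000-cell
subjects for the 9-sample benchmark (a BIC-selected fit per sample, 36
transport LPs) and smaller single-blob samples (100–300 cells, fixed
`H = 1..2`) for the property and analysis tests, which keeps the whole
suite and the 20-seed benchmark reproduction comfortably within a few
minutes on one CPU.

## Known limitations

- Mixture-level transport can underestimate differences that EM absorbs
  into wider covariances rather than separate components; the BIC default
  trades fidelity for parsimony.
- The cosine cost ignores covariances and weights direction only; it is a
  dissimilarity, not a metric on mixtures.
- The LOO score conflates a marker's instability with its leverage on the
  GMM fit; Shapley-style attribution would disentangle this but is out of
  scope.
- Exhaustive subset search scales combinatorially; beyond ~20,000 subsets
  a screening strategy (e.g., restricting the candidate pool) is the
  intended use.
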