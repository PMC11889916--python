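# Methods

## The screening problem

A media-optimization screen asks which combinations of growth factors,
added to a chemically defined basal medium (CDBM), make cultured cells
(e.g. mesenchymal stromal cells) proliferate faster while driving a
distinct, reproducible morphological state. Each 96-well plate carries
two negative controls — serum-containing medium (SCM) and plain CDBM —
a positive control (SCM plus FGF), and a set of candidate formulations
at 4 replicate wells each. Cells are stained and imaged; a
CellProfiler-style table of per-cell morphological features is the
analysis input. This package implements everything downstream of that
table.

## Design

`enumerate_full_factorial` builds all 2^k level combinations of k
two-level factors in lexicographic order (low before high, first factor
slowest); each factor is at its high level in exactly 2^(k−1) rows.
`assign_plate_layout` distributes formulations over plates. The per-plate
well budget defaults to 12 + 12 negative-control and 4 positive-control
wells, leaving ⌊(96 − 28)/4⌋ = 17 treatments per plate — 16 plates for a
256-formulation screen, the last one partially filled. "Semi-random"
layout means every assigned well position is shuffled by a seeded RNG,
controls included; an optional `edge_exclusion` flag keeps treatment
wells off the outer ring (a standard precaution against evaporation-edge
effects), capping the plate at ⌊60/4⌋ = 15 treatments. Identical seeds
give byte-identical plate maps.

## Synthetic screens

The generator produces per-cell tables with known ground truth so the
pipeline can be validated without imaging data. Its model:

- **Counts.** The cell count of a well under condition *t* is negative
  binomial with mean `baseline × m_t` and size (dispersion) parameter
  `count_dispersion` (variance `μ + μ²/size`). Defaults:
  `baseline = 120` cells/well (roughly two days of growth from a
  1563 cells/cm² seed in a 96-well), `size = 200`, giving a replicate
  count CV of ≈ 10–12% — the reproducibility of a well-controlled
  screen, and the reference scale against which the CV < 0.2 hit
  criterion is meaningful. Negative-binomial rather than Poisson because
  replicate well counts in real screens are overdispersed, and the CV
  criterion needs tunable replicate noise.
- **Features.** A cell's feature vector is
  `Λz + μ_base + δ_t·u_t + w + p + ε`: a latent standard-normal vector
  `z` (default 10 latent blocks over 200 features) mapped through a
  block-sparse loading matrix `Λ` to induce correlated feature families;
  a fixed per-condition unit direction `u_t` scaled by the planted
  phenotype-shift magnitude `δ_t`; a per-well offset `w` acting through
  the same latent loadings (sd 0.3 per latent dimension, plus an
  independent per-feature term, sd 0.1) so that *well profiles* inherit
  the correlated block structure real profiles show; a per-plate
  per-feature offset (sd 0.25); and independent cell noise (sd 1). The
  well-noise scale is set so that a planted shift of δ ≈ 5 is a clearly
  separated phenotype relative to control well scatter — i.e. "strong
  hit" has a fixed meaning in the generator's units.
- **Controls.** SCM is the reference (m = 1, δ = 0). CDBM grows cells
  poorly and looks different (m = 0.6, δ = 2); the FGF positive control
  boosts growth and shifts morphology (m = 1.5, δ = 2.5). All are
  overridable per run.

Shift directions are drawn once per condition from a seeded isotropic
distribution keyed by (seed, condition name), so distinct treatments
occupy distinct phenotype directions regardless of iteration order.

What the generator does **not** emulate: image-level artifacts
(illumination, segmentation errors), spatial plate gradients beyond an
additive plate offset, heavy-tailed or skewed feature marginals, and
count-dependent feature noise. Passing tests therefore demonstrate the
pipeline's statistical behaviour under its stated model, not robustness
to every real-data pathology.

## Profiling

Fixed order: aggregate → normalize → select → PCA.

- **Aggregation**: per-well feature medians (even cell counts average
  the two central order statistics); wells with zero cells are kept with
  count 0 and a missing profile, excluded from normalization statistics
  and PCA but retained in count analyses.
- **MAD normalization**: per plate and feature,
  `x' = (x − median_ref)/(MAD_ref + ε)` over the plate's reference wells
  (default: pooled SCM + CDBM; configurable to a single control). The
  MAD is the raw median absolute deviation — no 1.4826 Gaussian
  consistency constant — and `ε = 1e-12` only guards the division.
  Features with zero reference MAD on any plate carry no control
  variation and are dropped (not inflated).
- **Feature selection**: greedy correlation filter at |r| > 0.9,
  applied to |r| since anticorrelated duplicates are equally redundant.
  Determinism: zero-variance features go first; then the pair with the
  largest |r| is resolved by dropping its member with the larger mean
  |r| against all remaining features; exact ties keep the
  lexicographically smaller name. The result records every removal with
  its partner and triggering correlation.
- **PCA**: correlation-mode (features standardized to unit variance
  first); `n_retained` is the smallest m whose cumulative
  explained-variance ratio reaches the target (default 0.9).

## Statistics

- **Replicate CV** = sample sd (n−1) / mean of a treatment's replicate
  well counts.
- **Mahalanobis distance** between group centroids uses the covariance
  of the *pooled* scores — label-invariant, which both keeps the
  permutation test honest (the covariance is fixed across permutations)
  and lets the permutation loop factor the covariance once. A `ridge`
  added to the diagonal regularizes small-sample covariances; at
  ridge = 0 a singular covariance falls back to the Moore–Penrose
  pseudoinverse.
- **mp-value**: retained PC scores are multiplied by their
  explained-variance ratios (down-weighting minor components), the
  observed distance is computed, and group labels are permuted. With
  n_treatment = 4 vs n_control = 12 wells there are only C(16,4) = 1820
  distinct splits, so the test is exhaustive by default (the pipeline
  default `n_permutations = 2000` exceeds 1820); larger groups fall back
  to seeded random permutations.
  `mp = (1 + #{D_perm ≥ D_obs})/(N + 1)` never returns 0. The default
  ridge is `1e-6 ×` the mean covariance diagonal — needed because 16
  wells with tens of components make the covariance singular; it is a
  documented deviation knob, not a tuning parameter.
- **Dunnett many-to-one**: per plate and per control, all treatments
  form one family; adjusted two-sided p-values come from the
  multivariate-t distribution (scipy), with a seeded RNG for its
  integration so results are reproducible to ~1e-3. "Significantly
  higher" additionally requires the treatment mean to exceed the control
  mean.

## Hit calling

Potential hit ⇔ CV < 0.2 **and** Dunnett-significantly higher counts
than every required control **and** mp < α against every required
control; each failed criterion is recorded by name. PCA is then *refit*
on the potential-hit replicate wells, Ward linkage runs on Euclidean
distance in the retained-PC space (raw, unweighted scores by default),
and the cluster count, when not given, is chosen by the largest relative
gap in merge heights over k ∈ [2, min(15, #hits)] — a reproducible
stand-in for a by-eye dendrogram cut, overridable with `k`. Per cluster,
among treatments whose replicates all fall in that cluster and whose CV
passes, the highest mean count wins. Clustering operates on replicate
wells (not group means) because replicate coherence is defined on wells.
Representative wells minimize the Euclidean distance to the hit's mean
profile over standardized cell-shape (`*_AreaShape_*`) features, ties
broken by well name.

Two optional modes mirror screen practice: a *similarity-hit* selector
(treatments indistinguishable from a named control in both count and
mp-value) can be expressed by querying the statistics tables directly,
and forced inclusion of a condition bypasses selection but not
statistics.

## Numerical and degenerate-input choices

- Permutation ties: squared distances within 1e-9 of the observed one
  count as ≥, so identical point sets give mp = 1 exactly.
- All-identical cluster input (degenerate merge heights) yields a single
  cluster; a single potential hit clusters trivially with a warning.
- Zero-variance features: dropped with reason before correlation
  analysis; fewer than 2 non-constant features is an error for PCA.
- CSV outputs use '.' decimals, UTF-8, `\n` line endings and stable
  column order, so pipeline determinism is testable as byte-identity.
- Seeds: layout, simulation, and permutation seeds are independent and
  recorded in the run manifest.

## Problem sizes used in validation

The test suite and the acceptance script validate at the screen's native
scale where that is what is being claimed — 256-formulation screens on
16 plates (~180k cells × 200 features per screen) for planted-hit
recovery, 2000 exhaustive permutation tests for null calibration, 1000
simulated plates for the Dunnett family-wise error rate — and at small
fixture scale (1–2 plates, 40–100 features) everywhere the property
under test is scale-free. The acceptance script reports one planted
screen and 200 Dunnett plates, its own choice of a representative
problem size.

## Known limitations

- The Ward cluster-count heuristic is a heuristic; when hit phenotypes
  form a continuum rather than separated clusters, `k` should be set
  explicitly.
- mp-value calibration assumes exchangeable wells within a plate; plate
  layouts with strong spatial artifacts violate this (use
  `edge_exclusion` and inspect plate heatmaps of PC1/count).
- The Dunnett step assumes approximately normal within-group counts;
  with very low counts a variance-stabilizing transform upstream would
  be more appropriate.
- Multi-donor designs (two-way layouts) are out of scope; each screen is
  analyzed independently.
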