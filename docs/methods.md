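# Methods

## Scope and data model

The package operates on per-cell spatial tables (cell id, sample, FOV,
x/y in µm, cell-type label), sparse cell × gene count matrices (AnnData /
Matrix Market trio), per-cell marker-intensity tables, sample-level count
tables with group labels and severity scores, GMT gene sets and
(ligand, receptor, pathway) lists. All spatial statistics are FOV-local:
neighbourhoods never cross FOV boundaries, which avoids artefacts at tile
stitching seams; coordinates are continuous µm with the origin at each FOV's
lower-left corner.

## Synthetic synovium generator

The generator exists to give every downstream statistic a dataset with known
truth. It emulates the *structure* of multiplexed synovial data — a layered
tissue whose lining layer faces the joint cavity, compositionally distinct
sublining niches, marker-driven expression and IF intensities, cohort count
tables and Krenn-scale severity scores — not its histology. Spatial point
patterns are uniform within niche regions; real synovium is clustered at
several scales, so passing tests demonstrate statistical correctness on
recoverable structure, not performance on real tissue.

- **Tissue.** `bands` stacks horizontal strata with niche 0 at the top edge
  (the cavity-facing lining layer); `blobs` assigns cells to the nearest of
  randomly placed niche centres (vascular/adipose analogues); `mixed` keeps
  the top band and fills the rest with blobs. Cell types are drawn from the
  niche's row of a row-stochastic composition matrix. The default scenario
  scales the study-sized geometry down to 20,000 cells over a 4 × 4 grid of
  500 µm FOVs, 7 niches × 30 cell states, each niche dominated by a disjoint
  type block over a 20% shared background — chosen so planted labels are
  recoverable but boundaries remain ambiguous.
- **Doublets.** For each planted (A, B, fraction) pair, the given fraction
  of A cells gets a same-FOV B cell relocated to a uniform 0.1–1 µm offset,
  so planted partners always sit within the 2 µm contact range.
- **Expression.** Counts are gamma-Poisson (negative binomial): per-gene
  type means (baseline for unlisted genes) are rescaled per cell to a
  library size drawn uniformly from a configured range, then multiplied by a
  unit-mean gamma variable with shape = `dispersion`. Large dispersion
  recovers Poisson noise; the NB choice is the standard single-cell noise
  model. No batch effects, ambient RNA or doublet transcriptomes are
  simulated.
- **IF intensities.** Intensity = signature value + Gaussian noise with
  per-marker sd = (signature dynamic range)/snr, clamped at 0. The default
  panel has 21 markers × 12 synovial cell types (lining/sublining
  fibroblasts, SPP1+/LYVE1+ macrophages, S100A8+ monocytes, lymphocyte and
  plasma-cell states, CD146-hi and SMA-hi vessels, lymphatics, mast cells)
  with distinct rows.
- **Cohorts and severity.** Per-sample counts are multinomial draws from the
  group's true proportions (sample sizes uniform in a configured range).
  Severity = clamp(baseline + Σ coefᵢ·realized proportionᵢ + N(0, σ), 0, 3)
  on the Krenn inflammatory-infiltrate sub-score scale. Defaults: baseline
  1.5 (mid-scale, so clamping is not one-sided), noise sd 0.2 (sub-point
  scoring error), link coefficients ±15 per unit proportion — a ±0.02 swing
  in a niche's share moves the score by ±0.3, i.e. strong but not saturating
  association; ±30 drove half the samples into the clamp.

## Statistical procedures

- **Differential abundance.** Cells are pooled across samples within each
  group (no hierarchical modelling). The permutation null shuffles group
  labels over cells with group sizes fixed; it is sampled by sequential
  conditional hypergeometric draws of per-type counts, which is
  distributionally identical to materializing label permutations but
  vectorizes over all 10,000 permutations. p = (1 + #{|log2FD*| ≥
  |log2FD|})/(n_perm + 1), ties counted as ≥. The Haldane 0.5 correction is
  applied to both groups only when either count is zero, keeping log2FD
  finite for near-absent populations without biasing common ones. BH runs
  over the permutation p-values; the Fisher exact p is reported alongside.
  Thresholds (FDR < 0.01, |log2FD| > 0.58) are strict inequalities.
- **Niche detection.** Composition-only clustering: gene expression never
  enters the partition, which keeps the method testable with label-only
  fixtures; expression enters post hoc through the rank-sum confirmation
  test. k = 20 resolves a lining-layer band roughly two cells deep at
  typical imaging densities. k-means uses 10 seeded restarts; cells in FOVs
  with < k+1 cells stay unassigned (label −1). kNN ties are broken by
  (distance, input order), making results independent of KD-tree internals.
- **Proximity.** Because the null permutes labels with positions fixed,
  nearest-neighbour indices are computed once and each permutation only
  re-tabulates label pairs — 1,000 permutations on 5,000 cells take well
  under a second. The p-value is one-sided (co-localization enrichment);
  signed z is retained for depletion inspection. The directional matrix is
  only symmetrized for hierarchical grouping ((z + zᵀ)/2, distance
  max(S) − S, average linkage). Pairs with null sd = 0 are degenerate and
  carry p = 1; rows with fewer than `min_cells` = 20 cells are masked.
- **Annotation.** Cosine similarity after per-marker affine scaling
  (z-score default) fitted on the pooled rows of data and signatures and
  applied to both — identical transforms guarantee that a cell equal to a
  signature row scores exactly 1 and make scores invariant to per-marker
  gain/offset changes in the raw measurements. Argmax ties break
  alphabetically; an optional top-minus-second margin gates low-confidence
  cells to "unassigned".
- **Gene mapping.** "Average expression" is CP10K + log1p averaged within
  state (the field's de facto convention; recorded in output metadata since
  displays rarely define it). Ranking ties break lexicographically. The
  Fisher enrichment statistic is generic over user-supplied GMT sets; no GO
  database ships with the package.
- **Association.** Pearson requires *both* vectors to pass Shapiro–Wilk at
  α = 0.05 (the conservative reading of a per-variable normality gate);
  otherwise Spearman with average ranks. Correlation p-values are
  deliberately unadjusted, matching the reporting convention |r| > 0.5,
  P < 0.05; a BH option exists on the output frame if needed. Constant
  vectors yield an explicit "undefined" result.
- **Signaling.** Strength is the product of min-max-scaled state means of
  ligand and receptor — a closed-form surrogate for mass-action
  communication scores that preserves rankings and is zero whenever either
  scaled mean is zero. Permutation significance shuffles state labels
  (n_perm = 100 default). With few states the p-value is conservative for
  saturated strengths: a pair whose scaled product is exactly 1.0 ties the
  null whenever the shuffled argmax states coincide (probability ≈ 1/S²),
  so with S = 3 such a pair cannot reach p < 0.05 even though it ranks
  first; rankings are unaffected. Multi-subunit receptors are out of scope.
  Within-niche restriction keeps (s→t) for niche N iff both states hold
  ≥ 2% (`membership_min`) of N's cells.

## Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; given a seed every generator and permutation
  test is bit-reproducible.
- BH is `statsmodels.multipletests(method="fdr_bh")`, verified against the
  textbook step-up rule; Fisher exact tests are `scipy.stats.fisher_exact`,
  verified against exhaustive hypergeometric enumeration (max deviation
  < 1e-15 over every 2×2 table with margins ≤ 30).
- Permutation p-values use the add-one estimator and therefore never
  return 0; their floor is 1/(n_perm + 1).
- kNN distance ties are rounded at 1e-9 µm before lexicographic
  tie-breaking.

## Benchmark problem sizes

The planted-truth benchmarks in `synovniche.benchmarks` (run by the test
suite and `scripts/acceptance.py`) use desk-scale versions of the study
conditions: 20,000 cells / 16 FOVs / 30 states for niche recovery, 5,000
cells for proximity calibration, 2,000 cells per group × 10,000 permutations
for abundance, 8 samples for severity links, a 21-marker × 12-type panel at
snr ∈ {1, 2, 3, 5} for annotation. These sizes were chosen as the smallest
at which the planted effects are comfortably identifiable.

## Known limitations

- Niches are defined purely by local composition; transcriptome-space
  clustering, spatial HMMs and cross-sample niche alignment are out of
  scope, and the composition-based definition is recorded in the output
  metadata of the `niches` command.
- The abundance test ignores per-sample correlation (pooled cells), so its
  p-values are anti-conservative when samples differ strongly within a
  group.
- The signaling score reproduces rankings and within-niche membership
  logic, not any calibrated interaction-strength scale.
- The generator's uniform spatial point process understates the clustering
  of real tissue; proximity power estimates on synthetic data are therefore
  optimistic relative to sparse real FOVs.
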