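# Methods

## Model and procedure

The pipeline treats a gene-by-sample expression matrix `x_ij` (N genes, M
samples) or a 3-mode tensor `x_ijk` (N genes, M samples, K conditions) as
follows.

1. **Standardization.** Every sample column (matrix) or (sample, condition)
   fiber (tensor) is centered and scaled over genes so that
   `sum_i x_ij = 0` and `sum_i x_ij^2 = N`. Columns with zero variance are
   an error (the offending sample/fiber is named). Counts are used on the
   raw scale by default; a `log2(x + pseudocount)` transform is available
   behind a flag (pseudocount 1). On the raw scale the component scores
   weight absolute count differences, which favors highly expressed genes;
   on the log scale they weight fold changes. Both are legitimate analyses
   of the same data and the package defaults to the raw scale, the least
   destructive choice for curated count benchmarks.

2. **Decomposition.** Matrices: PCA, defined through the N × N gene-side
   gram matrix `sum_j x_ij x_i'j` but computed via thin SVD of the N × M
   matrix — mathematically identical scores/eigenvalues at O(N·M) memory, so
   genome-scale N is fine. Sample-side loadings are `v_lj = sum_i x_ij u_li`
   with `||v_l||^2 = lambda_l`. Tensors: higher-order SVD; each factor
   matrix holds the left singular vectors of the corresponding mode
   unfolding, and the core is the tensor contracted with the factor
   transposes. Full unfolding ranks are kept by default (the decomposition
   then reconstructs the input exactly); per-mode truncation is an optional
   convenience. Sign ambiguity is fixed deterministically: each score/factor
   column is flipped so its largest-magnitude entry is positive, and the
   paired loading column inherits the flip. P-values are sign-invariant, so
   this is purely a reproducibility device. Degenerate (repeated)
   eigenvalues are reported as-is; no rotation disambiguation is attempted,
   since selection consumes one component at a time.

3. **Axis selection.** The sample-mode component (and, for tensors, the
   condition-mode component) is chosen as the factor column with the largest
   absolute Pearson correlation to a user-supplied target vector (e.g. a
   ±1 class contrast). For tensors the gene-mode component `l1` is then the
   one maximizing `|G(l1, l2, l3)|` in the core; ties break toward the
   smallest index. Explicit component indices bypass the correlation rule.
   With very short condition modes (K ≈ 3) the correlation rule is noisy —
   see Limitations.

4. **P-value attribution.** With a null SD `sigma`, each gene gets
   `P_i = sf_chi2((u_i / sigma)^2, df = 1)` — the two-sided Gaussian tail of
   a single score. Raw P is clamped at the smallest positive normal double
   so log-scale diagnostics never see 0. BH step-up correction is applied
   over exactly the genes retained after row filtering, and genes with
   adjusted P ≤ threshold (default 0.01; 0.1 is the convention for the
   tensor analyses) are selected.

## The SD calibration

The pooled (population, divisor N) SD of the scores is inflated by true
signal, which makes all P-values conservative and can empty the selected
set. The calibration picks `sigma` by a histogram-flatness criterion:

- For a candidate `sigma`, compute raw P, BH-adjust, and flag genes with
  adjusted P ≤ p0 (default 0.01) as selected.
- Histogram `1 − P_i` on `n_bins` (default 100) equal-width bins spanning
  [0, 1]. Let `t = min(1 − P_i)` over selected genes (`t = 1` when nothing
  is selected) and keep the bins whose **left edge lies below `t`**. The bin
  containing the selection boundary is therefore kept: at a well-calibrated
  `sigma` the selected genes concentrate in that single boundary bin while
  the remaining bins are uniform, whereas an overscaled `sigma` spreads null
  mass unevenly and an underscaled one lets nulls leak into the boundary
  region. Keeping the boundary bin is what makes the objective's minimum sit
  slightly above the true null SD on contaminated data, which is exactly the
  conservative behavior that yields clean separation of the outlier block.
- The objective `sigma_h` is the population SD of the kept bin counts
  (divisor = number of kept bins). Fewer than 2 kept bins is inadmissible.
- The trivial `sigma -> 0` minimum (everything flagged, almost no bins
  left) is excluded by an admissibility guard: a candidate is discarded if
  fewer than half the genes remain unselected or fewer than 10 bins are
  kept.
- Minimization is deterministic: `sigma_h` is evaluated on a log-spaced grid
  of 200 points spanning `[sigma_naive / 50, 2 * sigma_naive]`
  (`sigma_naive` = pooled SD), inadmissible points are dropped, and the grid
  minimum is refined by bounded scalar minimization between its neighbors
  (absolute tolerance `1e-4 * sigma_naive`; inadmissible points get a large
  finite penalty because Brent steps cannot handle infinities). The
  objective is self-referential — the bin set depends on `sigma` through the
  selection — so every evaluation recomputes P, BH, the cutoff and the
  histogram from scratch. Whether candidates above the pooled SD should be
  admissible is not obvious a priori; the grid allows up to `2 *
  sigma_naive` so the scan can reject the pooled value on evidence rather
  than by construction.

The **recomputed SD** — the pooled SD restricted to genes *not* selected at
the optimum — is reported as a diagnostic. When the calibration cleanly
separates signal from null it approaches the true null SD (≈ 1.0 on the
canonical mixture below). When nothing is selected it equals the pooled SD
exactly.

On the canonical contamination scenario (1000 standard-normal scores plus
100 outliers at 5) the pooled SD is ≈ 1.72–1.73: the mean-centered
population SD of that mixture, commonly quoted as ≈ 1.75. At that scale no
point reaches adjusted P ≤ 0.01. The calibrated SD averages ≈ 1.17 across
repetitions, recovering all 100 outliers with ≈ 0.1 false positives per
repetition, and the recomputed SD averages ≈ 1.00. These numbers are
computed live by `tests/test_acceptance.py` and `scripts/acceptance.py`.

## Synthetic data: what it emulates, and what it does not

- `gaussian_with_outliers(n_null=1000, n_out=100, out_value=5)` — the
  calibration stress test: a pure Gaussian null plus a constant outlier
  block, the minimal setting in which the pooled SD fails.
- `two_class_counts(n_genes=2000, n_per_class=7, deg_fraction=0.1,
  lfc_scale=2, baseline_log_mean=5, baseline_log_sd=2)` — a two-class count
  benchmark in the style of reference-vs-brain comparisons: per-gene
  baselines are log2-normal (median ≈ 32 counts, heavy right tail), a 10%
  DEG share receives a signed log2 fold change of magnitude
  `|N(0, lfc_scale)|` applied to one class, and counts are Poisson around
  the class mean. Poisson — not negative-binomial — is the deliberate
  default, because the method under test makes no NB assumption; a
  gamma-Poisson (NB) option with an explicit dispersion exists for
  robustness checks, as does a per-sample library-size factor.
- `planted_tensor(n_genes=1000, n_samples=6, n_conditions=3,
  signal_genes=50, effect=3)` — Gaussian background with a treated-vs-control
  mean shift planted in 5% of genes under a single condition, emulating
  condition-specific contrasts in multi-condition designs.
- `uniform_ma_demo` — two independent uniforms mapped to MA coordinates;
  the flagged fraction at raw-difference threshold 0.5 is the area of two
  corner triangles, 0.25, and `Delta = y (2^LFC − 1)` holds identically.

All generators are pure functions of parameters and seed. What they do *not*
model: batch effects, gene–gene correlation, varying sequencing depth beyond
a scalar factor, zero inflation, and annotation artifacts. Passing tests
demonstrate the statistical machinery under its stated assumptions, not
performance on any particular organism or platform.

## Evaluation conventions

- Confusion matrices cross-tabulate ground-truth labels against selection.
- Rank-coincidence AUC: the top-k (default 1000) genes of a reference
  P-vector are positives; the other method's P ranks them. Computed by the
  rank-sum identity (average ranks on ties), hence invariant under monotone
  transforms of the predictor.
- MA plots use `A = mean_j log2(x_ij + 1)` and
  `M = mean_A log2(x + 1) − mean_B log2(x + 1)`; the pseudocount (default 1,
  configurable) keeps zero counts finite. Selection categories use the 0.01
  and 0.1 adjusted-P cutoffs.

## Problem sizes in tests

The repeated calibration experiment uses 100 repetitions of n = 1100; count
simulations use 2000–3000 genes with 2–16 samples per class; tensors are
1000 × 6 × 3. These sizes give stable averages while keeping the whole suite
near half a minute; the stability and MA-plot checks pool 3–4 seeds for the
same reason.

## Known limitations

- The flatness objective is a noisy staircase in `sigma`; per-seed optima on
  the canonical mixture scatter over roughly [1.05, 1.3] even though the
  average is stable. The objective curve is exported precisely so users can
  inspect how sharp their minimum is.
- With K ≈ 3 conditions, correlation-based condition-axis selection picks
  the wrong column in a noticeable minority of random instances (the
  indicator target has only 3 entries). Median-over-seeds recovery is
  unaffected, but single tensor analyses with very short modes should
  consider explicit component indices.
- The calibration assumes the null dominates (the admissibility guard
  requires ≥ half of genes unselected); data with a majority of true signal
  violates its premise.
- Raw-scale PCA underranks low-expression DEGs (this is the flip side of the
  expression-dependent selection property); use the log2 flag when fold
  change at low counts is the quantity of interest.
- BH is applied per run over the retained genes; there is no cross-dataset
  or hierarchical correction, and no alternatives to BH (BY, q-values) are
  provided.
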