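# Methods

This note describes the statistical procedures implemented in `ptprmeth`,
every tunable parameter with its default and rationale, what the synthetic
cohort generator does and does not emulate, and the package's numerical
conventions and limitations.

## 1. Data model

A **beta matrix** is a probes × samples table of methylation fractions
β ∈ [0, 1] with unique probe and sample identifiers. A **manifest** maps each
probe to a chromosome (`chr1`–`chr22`, `chrX`, `chrY`), a base-pair position,
and optionally a promoter gene. A **bin profile** holds non-overlapping,
sorted genomic bins per chromosome and a bins × samples table of copy-number
log2 ratios. A **sample sheet** carries per-sample clinical columns,
including `pfs_months`/`pfs_event` and `os_months`/`os_event`.

Cross-platform integration (`integrate_by_probe_name`) keeps the
intersection of probe names across all input matrices, in the probe order of
the first input; sample identifiers must be globally unique. An empty
intersection or duplicated samples raise `IntegrationError` with per-matrix
probe counts.

## 2. Subtype discovery

The chain in `subtype_pipeline` is:

1. Optional sample exclusion, then probe filtering: sex chromosomes are
   dropped by default, further chromosomes on request, then probes with any
   missing value.
2. **Top-variable probe selection** — the `n_top = 10,000` probes with the
   largest per-probe standard deviation (ties broken by probe identifier,
   lexicographically ascending).
3. **PCA** on the column-centered beta matrix (samples × probes), without
   scaling, via singular value decomposition. Variance fractions are
   eigenvalues of the sample covariance over their sum. A constant matrix
   yields zero fractions and a warning rather than an error.
4. **Parallel analysis** (Horn's method): in each of
   `n_permutations = 1,000` rounds, every probe's values are independently
   permuted across samples, destroying inter-probe correlation while keeping
   each probe's marginal distribution; eigenvalues come from the
   samples × samples Gram matrix of the centered permuted data. A component
   is non-trivial while its observed eigenvalue exceeds the
   `quantile_level = 0.95` quantile of the null eigenvalues at the same rank;
   selection stops at the first failure. A `full_matrix` scheme (permuting
   the flattened matrix) is available for comparison.
5. **Ward hierarchical clustering** (`scipy` linkage on Euclidean distances)
   of the samples in the space of the retained components (at least one),
   cut at `k = 3`. Cluster labels are renamed deterministically: descending
   cluster size, ties by smallest member sample identifier.
6. Optional **UMAP** embedding (`n_neighbors = 15`, `min_dist = 0.1`, fixed
   `random_state`) for visualization only; it never feeds the clustering.

## 3. Differential methylation

`rank_sum_test` computes the two-sided Wilcoxon–Mann–Whitney test with three
regimes (`mode="auto"`):

- no ties and both groups ≤ 25: SciPy's exact method;
- ties present and C(n, n₁) ≤ 50,000: exact enumeration over all group
  assignments, with U counting 0.5 per tie and
  p = min(1, 2·min(P(U ≤ u), P(U ≥ u)));
- otherwise: the tie-corrected normal approximation.

`call_dmps` contrasts two groups (orientation by first appearance in the
label mapping, or an explicit `groups` tuple; each group needs ≥ 2 samples).
A probe is significant when **p < 0.05 and |Δβ| > 0.2**, where
Δβ = mean(group 1) − mean(group 2); the direction is `hypo`/`hyper` for
group 1 by the sign of Δβ. P-values are raw by default; Benjamini–Hochberg
adjustment is available (`fdr_correction=True`) but off, matching the
probe-level rule above. When one group exceeds 25 samples the asymptotic
test is vectorized across probes.

`aggregate_promoters` calls a promoter hyper- or hypomethylated when **more
than two** (`min_sig_probes = 3`) of its probes are significant in one
direction **and none** in the opposite direction.

## 4. Copy-number analysis

Each chromosome of each sample is segmented by **recursive binary
segmentation**: the split minimizing the residual sum of squares is accepted
while its SSE gain exceeds a penalty, recursing into both halves. The default
penalty is `max(penalty_scale · σ̂² · ln n, 1e-10)` with `penalty_scale = 2`
(a BIC-like per-breakpoint cost), where σ̂ is a robust noise estimate from
the median absolute deviation of within-chromosome first differences divided
by √2 · 0.67449. The `1e-10` floor prevents spurious splits from float
rounding on noiseless piecewise-constant input. Chromosomes shorter than
`min_bins = 5` bins are left unsplit with a warning.

A chromosome is called **gained/lost** when the length-weighted mean of its
segment means exceeds `cutoff = +0.1` / falls below −0.1 (rule
`weighted_mean`; a `majority_length` alternative calls the state covering
the largest altered length). **CNV load** is the fraction of binned autosomal
genome length inside altered segments (|mean| > cutoff). Frequency contrasts
use SciPy's two-sided Fisher exact test; CNV-load contrasts use the rank-sum
test above. `write_seg` exports IGV `.seg` files with 1-based inclusive
coordinates.

## 5. Survival

Kaplan–Meier curves are fit with `lifelines` (log-log / exponential-Greenwood
confidence intervals); the median and its CI are `None` where the curve never
reaches 0.5. Group comparison uses the k-sample log-rank test
(χ², k − 1 degrees of freedom). `pfs_analysis` first excludes samples with
PFS **strictly greater than** `exclude_over = 150` months as long-term
outliers, then fits per-group curves and the log-rank test.

## 6. Synthetic cohort generator

All randomness flows from a single `numpy` generator seeded by
`CohortConfig.seed`; identical configurations are byte-identical.

| Parameter | Default | Rationale |
|---|---|---|
| `n_per_subtype` | A: 20, B1: 24, B2: 31 | a 75-sample three-subtype cohort, the package's reference problem size |
| `global_mean_shift` | −0.03 β | PTPR-A global hypomethylation, detectable by rank-sum on per-sample means at n = 75 |
| `n_dmp_probes`, `dmp_delta` | 200, 0.30 β | A-vs-B probes; 0.30 clears the 0.2 call threshold with logit noise |
| `n_dmp_b1b2`, `dmp_delta_b1b2` | 300, 0.25 β | B1-vs-B2 separation; chosen by a spiked-covariance calculation so the B1/B2 factor's eigenvalue clears the Marchenko–Pastur bulk edge (≈0.95 at 10,000 probes × 75 samples, entry variance ≈0.006) and parallel analysis retains it. Deliberately exaggerated relative to a real cohort, where B1/B2 separation is weaker |
| `frac_hypo_in_a` | 0.75 | net hypomethylation of PTPR-A among planted DMPs |
| `n_probes_total` | 20,000 | large enough for realistic selection/multiplicity behavior, small enough for fast tests |
| `n_genes` | 500 | promoters with 1–8 probes each, disjoint, randomly placed |
| `cnv_freq` | see `default_cnv_freq()` | per-(subtype, chromosome, gain/loss) event probabilities; chosen so cohort-wide expectations are chr3 loss 45.3%, chr10 loss 93.3%, chr8 gain 49.3%, with B1-specific chr3/chr14 losses absent from B2 |
| `cnv_gain_shift`, `cnv_loss_shift` | +0.25, −0.30 | log2-ratio magnitudes of whole-chromosome events |
| `bin_size_mb`, `bin_noise_sd` | 2.5 Mb, 0.15 | ≈1,163 autosomal bins; noise keeps single-bin state ambiguous but chromosome-level calls reliable |
| `beta_noise_sd` | 0.4 (logit scale) | per-entry noise added to logit(mean), back-transformed and clipped to [0.001, 0.999] |
| `pfs_median` | A: 178, B1: 63, B2: 29 months | exponential PFS per subtype |
| `os_median` | A: 178, B1: 95, B2: 77 months | exponential OS per subtype |
| `censor_rate`, `os_censor_rate` | 0.5, 0.7 | expected censored fraction; the uniform administrative-censoring horizon τ is solved numerically from (1 − e^(−λτ))/(λτ) = rate, keeping Kaplan–Meier estimates unbiased at any requested rate |

Planted DMP shifts are applied on whichever side of the contrast keeps the
probe mean inside (0, 1). Copy-number events are whole-chromosome only; bins
receive independent Gaussian noise. DMP probes are scattered uniformly, so
promoter-level calls are rare on default cohorts by construction.

**Emulated:** bimodality of beta values, subtype-specific global and
probe-level methylation differences, chromosome-scale aneuploidy at
subtype-specific frequencies, exponential survival with administrative
censoring, mixed array platforms (EPIC/EPICv2 labels).

**Not emulated:** probe-to-probe spatial correlation along the genome,
CpG-island/context structure, batch effects, sub-chromosomal (focal) copy
number events, tumor purity, covariate-dependent or informative censoring,
and missing data (generated matrices are complete).

## 7. Numerical conventions and degenerate inputs

- Probe/sample identifiers must be unique; out-of-range beta values raise
  `ValidationError` listing offenders.
- Top-variable ties break by ascending probe identifier; segmentation split
  ties break toward the smallest split index; cluster labels order by size
  then smallest member identifier.
- Mean genomic methylation excludes missing values pairwise and logs the
  exclusion count.
- A constant beta matrix warns and yields zero variance fractions; k = 1
  clustering returns one cluster; k greater than the number of samples
  raises; empty survival input raises; `censor_rate = 1` yields all-censored
  data at time 0.
- Seeds are non-negative and kept below 2³¹ where derived programmatically.

## 8. Limitations

- Exact rank-sum enumeration is capped at C(n, n₁) ≤ 50,000 assignments;
  larger tied problems fall back to the tie-corrected asymptotic test,
  which is anticonservative for very small samples with heavy ties.
- Recursive binary segmentation is a greedy approximation to optimal
  penalized segmentation; with the default penalty it recovers
  chromosome-scale events reliably but is not tuned for focal events.
- Parallel analysis assumes exchangeability of samples within a probe; it is
  calibrated for the per-probe permutation scheme, and the `full_matrix`
  scheme is stricter on heteroskedastic data.
- Stochastic recovery characteristics quoted for the generator (ARI,
  sensitivity, frequency and median recovery) are averages over replicate
  seeds at the documented problem sizes; single small cohorts vary.
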