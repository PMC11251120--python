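# ptprmeth

Methylation-based subtyping, copy-number and survival analysis for papillary
tumors of the pineal region (PTPR), with a calibrated synthetic-cohort
generator for end-to-end validation.

PTPR is a rare neuroepithelial tumor whose clinically relevant subgroups —
PTPR-A, PTPR-B1 and PTPR-B2 — are defined by genome-wide DNA methylation
profiles rather than histology. Real multi-center cohorts of this tumor are
small, heterogeneous across array platforms, and not freely redistributable.
`ptprmeth` therefore packages the complete analysis chain used for such
cohorts **together with** a generator that produces synthetic cohorts with
known ground truth, so that every step of the chain can be tested for
parameter recovery rather than merely for "it runs".

The intended audience is computational biologists and biostatisticians
working with Illumina-style methylation arrays (beta values in [0, 1]) and
bin-level copy-number profiles.

## What the package does

- **Cohort simulation** (`ptprmeth.simulate`): samples per-probe baseline
  methylation from a bimodal logit-normal mixture (unmethylated mode near
  β = 0.2, methylated near β = 0.8), plants a global hypomethylation offset
  in PTPR-A, probe-level differential methylation for the A-vs-B and
  B1-vs-B2 contrasts, whole-chromosome copy-number events at configurable
  per-subtype frequencies, and exponential progression-free survival with
  calibrated uniform administrative censoring. Everything planted is
  returned in a `GroundTruth` object.
- **I/O and integration** (`ptprmeth.io`): validated beta matrices, probe
  manifests and sample sheets; cross-platform integration by probe-name
  intersection; mean genomic methylation; chromosome-based probe exclusion.
- **Subtype discovery** (`ptprmeth.subtyping`, `ptprmeth.pipeline`): top-*k*
  most-variable probe selection, PCA on centered beta values, Horn-style
  parallel analysis (per-probe permutations, 95th-percentile null eigenvalue
  quantiles, stop at the first non-exceeding component) to choose the number
  of non-trivial components, Ward hierarchical clustering on the retained
  components, and UMAP embedding for visualization.
- **Differential methylation** (`ptprmeth.diffmeth`): two-sided
  Wilcoxon–Mann–Whitney rank-sum tests (exact enumeration for small samples,
  including tied data; tie-corrected normal approximation otherwise). A probe
  is a DMP when p < 0.05 **and** |Δβ| > 0.2; a promoter is called
  hyper-/hypomethylated when more than two of its probes are significant in
  one direction and none in the other.
- **Copy-number analysis** (`ptprmeth.cnv`): penalized recursive binary
  segmentation of bin-level log2 ratios per chromosome; chromosome-level
  gain/loss calls from the length-weighted mean segment value against a
  ±0.1 cutoff; CNV load as the altered fraction of the binned autosomal
  genome; Fisher exact tests for frequency comparisons; IGV-compatible
  `.seg` export.
- **Survival** (`ptprmeth.survival`): Kaplan–Meier estimation with
  log-log confidence intervals and median survival times (via `lifelines`),
  the k-sample log-rank test, and a PFS analysis that first excludes
  long-term outliers (> 150 months by default).

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from ptprmeth import CohortConfig, generate_cohort, subtype_pipeline

beta, manifest, profile, sheet, truth = generate_cohort(CohortConfig(seed=0))
res = subtype_pipeline(beta, manifest=manifest, n_permutations=200, seed=1)
true = [truth.true_labels[s] for s in res.labels.index]
print(res.parallel.n_selected, adjusted_rand_score(true, res.labels))
```

Running the scripts in `examples/` against the default 75-sample cohort
(seed 0) prints, among others:

```
non-trivial PCs selected: 2
PC1 / PC2 variance: 10.3% / 5.8%
ARI vs planted subtypes: 1.000
ARI with chr3/9/12/14 probes excluded: 1.000

significant probes: 201 (155 hypo / 46 hyper in PTPR-A)
planted A-vs-B probes recovered: 200/200

chr3 loss: 44.0% of the cohort
chr10 loss: 96.0% of the cohort
chr8 gain: 46.7% of the cohort
chr3 loss, B1 (23/24) vs B2 (0/31): Fisher p = 1.29e-14
CNV load A=0.41 vs B1=0.16 (p=3.2e-08), vs B2=0.13 (p=3.3e-09)

excluded 6 samples with PFS > 150 months
  PTPR-B2: median PFS 31.4 months (95% lower limit 19.4)
log-rank: chi2 = 13.81, df = 2, p = 0.0010
```

The three planted subtypes are recovered exactly (adjusted Rand index 1.0),
all 200 planted A-vs-B probes are detected with a single additional call
among the remaining 19,800 probes, chromosome-arm alteration frequencies and survival
medians match the generating parameters, and PTPR-A shows a significantly
higher CNV load than either B subtype.

Each script in `examples/` demonstrates one capability and prints computed
numbers with a short interpretation:

- `examples/simulate_cohort.py` — generate a cohort, inspect what was planted
- `examples/subtype_discovery.py` — full subtyping chain and label recovery
- `examples/differential_methylation.py` — DMP and promoter calls
- `examples/cnv_analysis.py` — segmentation, chromosome calls, CNV load
- `examples/survival_analysis.py` — PFS Kaplan–Meier curves and log-rank test

A thin CLI mirrors the library (`ptprmeth simulate | integrate | subtype |
diffmeth | cnv | survive`); run `ptprmeth --help` for details.

## Documentation

See `docs/methods.md` for the statistical methods, all tunable parameters
with defaults and rationale, what the synthetic generator does and does not
emulate, and known limitations.
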