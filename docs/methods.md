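# Methods

This note documents the statistical model behind `lmsdiag`, the choices made
where the procedure admitted more than one reasonable reading, and what the
synthetic-cohort experiments do and do not demonstrate.

## Problem and model

Uterine leiomyosarcoma is distinguished from leiomyoma / normal myometrium
not by a consistent mean expression shift but by *loss of expression
control*: a set of genes whose levels are tightly regulated in non-malignant
tissue becomes heterogeneous across malignant samples. The pipeline
therefore scores genes by a variance ratio computed on centered data rather
than by differential expression of means.

Let `x_si` be the log2(FPKM + c) expression of gene *i* in sample *s* after
subtracting the sample's reference-gene (GAPDH) value and then the sample's
mean over the NDEG gene set ("zero-sum transformation"). For a sample group
G of size n,

    MSS_G(gene_i) = (1/n) * sum_{s in G} x_si^2

Because each sample is centered, MSS is an empirical second moment around
zero: for a gene whose standardized level sits at the NDEG-average it
estimates the within-group variance plus the squared gene-level offset.
The selection statistic is

    MSS ratio(gene_i) = MSS_LMS(gene_i) / MSS_normal(gene_i)

Large values flag genes conserved in normal tissue but dispersed in
leiomyosarcoma. Under the synthetic generative model (below), a planted
marker with noise SD inflated by a factor r has expected MSS ratio close to
r² when its gene-level offset is small relative to its normal-tissue
variance.

## Pipeline stages and conventions

1. **Gene intersection** across cohorts is exact ID matching; the result is
   ordered lexicographically so all downstream tie-breaking is
   deterministic.
2. **Log transform**: `log2(v + c)` with pseudo-count `c = 0.001` applied to
   every gene, including the reference gene.
3. **Reference standardization** subtracts the per-sample GAPDH log2 value;
   the GAPDH row becomes identically zero. For FPKM ≥ 1 the result is
   invariant to per-sample multiplicative scaling to about 1e-3 (exactly so
   in the zero-pseudo-count limit).
4. **Stratified 4:1 split**: per class, the validation side receives
   `floor(n_class / 5)` samples (uniformly at random, seeded). This floor
   convention is the unique one that maps a 114 + 31 cohort to 92/25
   training and 22/6 validation. An epsilon (1e-9) guards the floor against
   binary round-off.
5. **Expression filter**: the `floor(0.30 × n_genes)` genes with the highest
   mean *raw FPKM* across training samples; ties break lexicographically.
   The filter deliberately uses pre-transform means — the transformed scale
   would reweight low-expression genes.
6. **NDEG filter**: gene retained iff both the two-sided variance-ratio
   F-test (R's `var.test` convention, `p = 2·min(P[F'≤F], P[F'≥F])`) and the
   two-sided Welch t-test between training normals and the benign leiomyoma
   reference give p ≥ α (default 0.05). A gene differing in either mean or
   variance is excluded. No multiple-testing correction is applied: the
   filter is intentionally conservative about what counts as "not
   differentially expressed", and α is a knob, not an inference. Degenerate
   cases: two zero-variance groups → p = 1 (equal) or the t-test decides;
   exactly one zero-variance group → variance p = 0.
7. **Zero-sum transformation** restricts to the NDEG set and centers each
   sample to mean zero over it. Applied to held-out cohorts with the
   *training-derived NDEG list* but means computed on the new cohort.
8. **MSS table**: genes with normal-group MSS below 1e-12 are dropped with a
   warning — an unbounded ratio would make gap detection degenerate.
9. **Gap selection**: ratios are sorted descending (ties lexicographic) and
   the top 20 are inspected. The cut is placed at the largest *relative*
   drop between consecutive ratios (equivalently, the largest gap on the log
   scale); every gene strictly above it is selected. The relative form is
   used because MSS ratios live on a multiplicative scale: per-gene MSS over
   n malignant samples is chi-square distributed with coefficient of
   variation ≈ sqrt(2/n) (≈ 28 % at n = 25), so the absolute spread between
   the first few ranked genes grows with their magnitude and frequently
   exceeds the marker/background boundary, whereas the boundary (a ~5-fold
   drop at the default effect size) dominates on the fold-change scale. If
   the maximal gap is tied or the inspected curve is flat, the top
   `fallback_k = 17` genes are taken.
10. **Leakage containment.** The benign reference cohort used by the NDEG
    filter is a first-class input, separate from any evaluation set. The
    original study protocol reused test-set leiomyomas for this filter; the
    CLI permits that (it only warns on sample-ID overlap between the benign
    reference and an evaluation set) because the design is reproducible,
    but disjoint sets are the documented recommendation.

## Classifiers

* **Feedforward network** (implemented in numpy): `L` hidden layers of `w`
  units, each Linear → BatchNorm → ReLU → Dropout, one sigmoid output;
  binary cross-entropy minimized by Adam at a fixed learning rate of 0.001.
  He initialization; batch-norm momentum 0.9, eps 1e-5; minibatches are
  reshuffled every epoch; any trailing 1-sample minibatch is skipped
  (batch statistics need ≥ 2 samples). All randomness flows from one seeded
  generator, so training is reproducible to 1e-6 on a platform under
  single-threaded execution.
* **Baselines**: scikit-learn `SVC` (probability outputs), 
  `RandomForestClassifier`, `GradientBoostingClassifier`, with library
  defaults except for the tuned parameters below.
* **Decision rule**: probability ≥ 0.5 → leiomyosarcoma. The boundary case
  classifies positive; some convention is required and `≥` favors
  sensitivity, the clinically costlier error side.

## Hyperparameter search

A Gaussian-process Bayesian optimizer (Matern-5/2 kernel, expected
improvement, 256-candidate acquisition sampling, seeded): the first
`max(4, trials/4)` trials are random, later proposals maximize EI.
Duplicate configurations are never re-evaluated, so small discrete spaces
are swept exhaustively. Search spaces:

| family | parameters searched | objective (validation) |
|---|---|---|
| dnn | dropout 0.1–0.7, layers 2–8, width 2–32, batch 8–64, epochs 30–200 | binary cross-entropy (min) |
| svm | kernel {linear, rbf, poly, sigmoid}, C 1e-2–1e2 (log), gamma 1e-4–10 (log) | accuracy (max) |
| rf | trees 50–500, depth 1–16, max_features {sqrt, log2, all} | accuracy (max) |
| gb | learning rate 0.01–0.3 (log), trees 50–500, depth 1–8, max_features | accuracy (max) |

The desk-scale default is 25 trials (the study-scale protocol used 500;
both are a config knob). On the default synthetic cohort the search surface
is benign — 25 trials reliably reach validation AUC ≈ 1.

## Evaluation

Leiomyosarcoma is always the positive class. AUC is the tie-aware
Mann–Whitney pair statistic (computed via midranks); the ROC curve
thresholds at every distinct score, so its trapezoidal integral equals the
pair statistic to machine precision — the test suite checks the two
independent routes against each other. Reports round to 3 decimals for
display only.

## Synthetic cohort generator

On the log2 scale, sample `s` of class `c` has

    value(g, s) = b_g + delta_g(c) + e_gs + L_s

* `b_g`: per-gene baseline, Uniform(4, 12); low-expression genes (default
  400 of 2,000) Uniform(−6, 0); the reference gene fixed at 10.
* `delta_g(c)`: +2 log2 units for the benign-DE genes (default 100) in
  leiomyoma samples only — these are what the NDEG filter must remove.
* `e_gs`: Normal(0, σ_normal = 0.4), except planted markers in
  leiomyosarcoma samples, Normal(0, σ_LMS = 2.0), and the reference gene,
  Normal(0, σ_normal/10).
* `L_s`: Normal(0, 0.3), a per-sample multiplicative library factor shared
  by all genes — removed by GAPDH standardization.

The emitted matrix is `2^value` (FPKM scale, strictly positive). Default
sample geometry mirrors the targeted study design: 92 + 25 training,
22 + 6 validation, 8 benign reference, 9 + 9 and 8 + 9 test samples;
17 planted markers at a 5× noise-SD inflation (expected MSS ratio ≈ 25).

Two generator-design details matter for interpretation:

* **Planted baselines are mid-stratum.** Markers are drawn with SD 0.15
  around the mean baseline of the top-30 % expression stratum. A marker far
  from the NDEG average would carry its squared offset into *both* MSS
  terms and dilute the ratio toward 1; placing markers near the stratum
  center makes the ratio ≈ σ²-ratio identity hold, which is also the regime
  in which the method is informative. This encodes the assumption that
  usable markers are well-expressed genes, not a claim about real data.
* **Expected NDEG attrition.** A planted marker faces the same two α = 0.05
  tests as any gene, so on average ~1.7 of 17 markers are lost to chance
  rejections (binomial, p ≈ 0.0975); recovering 15–17 of 17 is the
  expected outcome, not a deficiency.

What the generator does **not** emulate: read-count noise, batch effects
beyond the single multiplicative factor, correlated gene modules, bimodal
or skewed malignant heterogeneity (the heterogeneity is symmetric Gaussian
— a stand-in, since the targeted phenomenon is described only as "greater
variability"), and benign tumors that genuinely resemble the malignancy.
Passing the synthetic experiments therefore shows the machinery is correct
and well-calibrated under its own assumptions; it does not certify
real-data performance.

## Results that require external data

Published real-data quantities — clinical test-set AUCs
(0.926/0.938/0.975/0.975 and 0.792/0.792/0.819/0.806 for SVM/RF/GB/DNN),
the 3,122-gene NDEG count, the identity of the 17 selected genes, and the
top marker's (PGR) MSS ratio of 22.655 — depend on the UCSC Xena
TCGA/TARGET/GTEx matrices and the GSE222045 clinical cohort. They are
documented here for orientation but are deliberately outside the test
suite, which exercises only computations reproducible from this repository.
(The published abstract quotes 1st-test specificity as 8/8 while the
published confusion table implies 9/9; this package's worked examples
follow the confusion table.)

## Numerical and degenerate-input conventions

* Floors/fractions: `floor` with a 1e-9 epsilon where binary representation
  of ratios could flip a count.
* Empty gene intersections, empty NDEG results (with per-test rejection
  counts), single-class training labels, and missing reference/selected
  genes are hard errors that name the offending items.
* Matrix round trips through TSV are exact to < 1e-12 (values serialized at
  full repr precision).
* Problem sizes in the test suite: unit tests run a 300-gene reduced
  cohort; the end-to-end checks run the full 2,000-gene default study.
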