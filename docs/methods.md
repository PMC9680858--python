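# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data models the test suite relies on, and the
known limitations.

## Expression scales and transformation

Matrices are genes-in-rows, samples-in-columns, with an explicit `scale`
flag (`tpm` or `log2`); nothing is auto-detected. The log transform is
log2(TPM + 0.25), so zero TPM maps to −2 and the transform is exactly
invertible. All correlation, clustering and PCA operate on the log2 scale.
Sample QC filtering drops samples whose supplied `qc_value` (e.g. mapping
rate) is below a threshold, default 0.5; samples without a QC value are
retained, since missing metadata is not evidence of failure. QC values are
always supplied, never computed here.

Group summaries (mean/SD/n per gene and replicate group) use the
population SD (ddof = 0) so a single-sample group reports SD 0 rather than
NaN; `ddof=1` is a parameter for the sample convention.

## Exploratory analysis

Hierarchical clustering of samples uses Ward linkage on the Euclidean
metric over the full gene vector (no variance pre-filtering — a deliberate
simplification; a variance filter changes the tree only when low-variance
genes dominate the distance, which log2 scaling makes unlikely). PCA
mean-centers per gene, applies no unit-variance scaling, and fixes the
sign of each component by making its largest-magnitude gene loading
positive so that results are deterministic across runs and platforms.

## Co-expression scores

For n samples, the PCC p-value uses the exact t-transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided (evaluated
through the equivalent regularized incomplete beta form). Ranks are per
row, by descending PCC excluding self; self-rank is 0. Ties receive
fractional (average) ranks — deterministic and stable under gene
relabeling — so HRR/MR may be non-integer, which their formulas permit.
Genes with zero variance yield missing correlations and are ranked below
every finite value; a gene with no finite correlations at all is an error.
Correlations over a condition subset require at least 3 samples.

Dense n × n matrices are the contract to roughly 2×10⁴ genes (a 20k × 20k
float64 matrix is ~3.2 GB; four of them — PCC, p, rank, MR — fit an
ordinary workstation). Beyond that a chunked computation would be needed;
it is not implemented here.

## Networks

Edges exist where MR is strictly below the cutoff, matching the
conventional "MR < 30" notation. Defaults: 30 for drawn networks (the
tightest threshold in common use), with looser values (1000, 2000)
appropriate for rank-table-style exploration; every cutoff is a flag.
Neighborhoods are breadth-first distances from the query set; the induced
subgraph keeps all edges among retained nodes. Functional networks
traverse first (distance ≤ 10 from the nearest bait) and keyword-filter
second: non-bait nodes whose concatenated annotation text (curated name
plus KOG/KEGG/Pfam/GO descriptions) lacks a case-insensitive substring
match are dropped, baits are always kept, and filtering never re-routes
distances. Multiple keywords combine as OR; there is no stemming. Node
attributes carry the KOG category (the conventional "shape class" in
network drawings); exports are GraphML, TSV edge list, and node-link JSON,
the first and last round-tripping losslessly.

## Enrichment

For study size n from background N, a term with K background and k study
genes is tested on the 2×2 table [[k, n−k], [K−k, N−K−(n−k)]] with the
two-sided Fisher's exact test; the direction label is "over" when
k/n > K/N ("over" also on equality, where p = 1 anyway). One BH family per
namespace per run. The default background is every gene with at least one
annotation in the tested namespace; this changes N and K relative to a
whole-genome universe, so callers comparing studies should pass an
explicit background. GO annotations are propagated to all ancestors via
is_a/part_of before counting (standard GO enrichment semantics; a flag
disables it); KEGG/KOG/Pfam are flat. OBO parsing validates acyclicity and
rejects dangling parent references. The word-frequency summary tokenizes
significant term names on non-alphanumeric boundaries, lowercases, and
removes a fixed stop-word list shipped with the package so counts are
reproducible across versions.

## Differential expression

A deliberately simplified DESeq2-style stage, not a clone: no dispersion
trend or MAP shrinkage, no outlier replacement, no independent filtering,
no LFC shrinkage. Validation is calibration and parameter recovery on
simulated counts, not numerical parity with any other package.

- **Size factors**: median-of-ratios against the geometric-mean reference
  over genes with positive counts in all samples; a `pseudo_reference`
  flag falls back to positive-count-only geometric means when no such gene
  exists. Factors are not renormalized (the doubled-sample toy gives
  exactly (1/√2, √2)).
- **Dispersion**: per gene, a single α shared by both groups from the
  method of moments on normalized counts, α̂ = max((v − m)/m², 10⁻⁸),
  where v pools the within-group variances (df-weighted, ddof 1) and m is
  the grand mean. Closed-form and deterministic; adequate at desk scale.
- **GLM**: per gene, log μ = β₀ + β₁·group + log s with α̂ fixed, fitted by
  IRLS with Fisher-information weights w = μ/(1 + αμ), vectorized across
  genes (shared 2-column design, closed-form 2×2 solve). Max 50
  iterations, relative coefficient tolerance 10⁻⁸; non-converged genes
  (e.g. a group with all-zero counts, whose MLE is infinite) are flagged
  with missing p and excluded from the BH family rather than crashing.
  The fit agrees with an independent NB GLM implementation to ~10⁻⁵ on
  test fixtures.
- **Test**: Wald z = β₁/SE from the expected information, referred to a
  **t distribution with n₁ + n₂ − 2 degrees of freedom** rather than the
  normal. The dispersion entering the SE is estimated from exactly those
  residual degrees of freedom, and at triplicate scale the normal
  reference is visibly anticonservative (empirical null false-positive
  rate ≈ 0.125 at the 0.05 level in our simulations) while the t reference
  is calibrated (≈ 0.045). This is the classic small-sample Wald
  correction; for large replicate numbers the two references coincide.
- Both groups must have ≥ 3 biological replicates; size factors and
  dispersions are computed on the selected samples only. log2FC = β₁/ln 2.
  Classes: up if padj < α and log2FC > threshold, down symmetrically,
  otherwise ns.

## Set relations

Exclusive regions are computed by a per-gene membership scan; the partition
property (regions disjoint, union reconstructed) is checked by the tests
on every instance. IDs are deduplicated within each input list and no
universe validation is applied — inputs are bare ID lists.

## Synthetic data

The generators define the conditions every statistical claim in the test
suite is made under.

- **Expression** (`simulate_expression`): a latent-factor module model.
  Each module's latent profile is a unit-step random walk across samples;
  members are latent + N(0, noise_sd), background genes are independent
  N(baseline, 1) with gene-specific baselines. A random walk across 24
  samples has much larger spread than noise_sd = 0.5, so within-module
  PCC is high by construction regardless of sample count — chosen over a
  multivariate-normal covariance specification for exactly that
  guarantee. Default conditions used throughout: 500 genes, 24 samples,
  one 20-gene module, noise_sd 0.5.
- **Counts** (`simulate_counts`): NB with mean = baseline × 2^(lfc·group)
  × depth and variance μ + αμ²; baselines log-normal around 100, α = 0.1,
  ≥ 3 replicates per group — values typical of bulk RNA-seq experiments.
  Calibration runs use 2000 null genes at 3 vs 3; recovery runs plant
  log2FC ∈ {−2, −1, 1, 2} on 500 genes each at 5 vs 5.
- **Annotations** (`simulate_annotations`): a layered random DAG under a
  single root (1–2 parents per term from the level above), leaf-term
  annotation probability 0.05 per gene, planted terms annotating a chosen
  subset with a chosen probability; serializable to OBO 1.2 and re-read by
  the parser.
- **Demo** (`oil_body_demo`): 400 genes, a 29-gene module (4 baits + 25
  "terpenoid"-annotated enzymes), a 4 vs 4 knockout comparison planting
  log2FC = −2 on the module, and a planted GO term covering the module.

What the generators do **not** emulate: compositional TPM constraints,
sample-size-dependent correlation noise across heterogeneous studies,
batch effects, correlated null genes, annotation bias toward
well-studied genes, or realistic GO DAG topology. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
stated models, not performance on any particular real atlas.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1] before the p-transform; zero-variance
genes are flagged rather than dropped. Ranks use average ties everywhere.
BH is computed by the standard step-up with cumulative minima; the family
excludes genes or terms with undefined p. Ward heights are non-decreasing
by construction; tie behavior in clustering follows SciPy's ordering.
Sizes and budgets of the simulation-based checks (matrix sizes, gene
counts, seed counts) were chosen so the whole suite runs in well under a
minute while keeping Monte-Carlo bands comfortably away from their
thresholds.

## Known limitations

- Single-factor, two-group DE only; no covariates or time courses.
- No multiple-testing correction of co-expression table p-values (raw p
  is emitted; correction is the caller's choice).
- Dense correlation matrices bound practical atlas size (~2×10⁴ genes).
- The OBO writer emits is_a edges only (sufficient for the synthetic
  DAGs, which carry no part_of relations); the parser accepts both.
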