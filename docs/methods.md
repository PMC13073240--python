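# Methods

## Model and rationale

`scposition` treats positional inference as multinomial classification of
single cells into anatomical compartments. The underlying biological
assumption is that long-resident immune cells integrate microenvironmental
cues (osmolarity, oxygen tension, metabolite gradients) into their
transcriptome over time, so that a cell's compartment is decodable from
expression alone; for motile cells the residence time is too short and the
problem is ill-posed. The pipeline therefore (a) restricts, when
configured, to one cell type (`cell_type` block in the pipeline config),
(b) selects candidate genes by expression variability rather than by
differential expression, and (c) validates strictly across datasets, never
within one.

### Preprocessing

Counts are QC-filtered per cell on detected genes (count of genes with ≥ 1
UMI, default range 200–4000 inclusive) and mitochondrial count fraction
(default ≤ 0.20; cells at exactly 20% are kept — the cut is read as
"remove above 20%"). Mitochondrial genes are matched by case-insensitive
symbol prefix (`mt-`), which covers both mouse (`mt-Nd1`) and human
(`MT-ND1`) conventions. Detected genes — not total UMIs — are counted
because a 200–4000 range matches detected-gene scales.

Normalization is `ln(1 + count / cell_total × 10⁴)`. Standardization uses
the sample (n−1) standard deviation, clips z-scores at ±10, maps zero-sd
genes to 0, and — crucially — is always recomputed from the *training*
data and reused at prediction time, so the model never sees test-set
statistics.

### HVG selection

Dispersion is variance/mean of log-normalized expression (genes with zero
mean are ineligible). Genes are assigned to 20 equal-frequency bins by
mean expression (ties in mean ordered by symbol), and dispersion is
z-scored within each bin using the sample sd; bins with one member, or
zero spread, yield z = 0. The top-n genes by z are returned in descending
order; the ranking key is rounded to 10 decimals before the lexicographic
tie-break so that exact ties are not reordered by floating-point summation
order. Binning by mean is what makes the statistic mean-independent:
without it, highly expressed genes dominate any variance ranking.
Equal-frequency (quantile) bins are used because they are well defined for
any expression distribution; dispersion is computed on the log-normalized
layer, consistent with the rest of the pipeline. Per-dataset top lists are
merged by order-preserving union so downstream gene order is
deterministic.

### Comparison selectors

* **Marker genes (one-vs-rest DE):** two-sided Wilcoxon rank-sum per gene
  against all other compartments pooled (exact null for small tie-free
  groups, tie-corrected normal approximation otherwise), BH adjustment
  within each compartment, keep adjusted p ≤ 0.05 and natural-log fold
  change (difference of mean log-normalized expression) ≥ 0.25; defaults
  are exposed because marker thresholds are conventions, not laws.
* **RFE:** iteratively drops the ⌈10%⌉ of genes with smallest aggregate
  |coefficient| of an L2 multinomial logistic model on standardized
  features until the target size remains; ties drop lexicographically, so
  the path is deterministic.
* **Mutual information:** expression is cut into ≤ 8 equal-frequency bins
  (duplicate quantile edges merged); MI with the label is computed from
  the empirical joint in natural-log units.
* **Random control:** uniform draw without replacement from the genes
  detected in ≥ 1% of cells, reproducible by seed.

### Classifier

The gated-attention MLP learns an elementwise input gate
`g = sigmoid(x·W_g + b_g)` over the gene dimension and feeds `x ⊙ g` into
a ReLU trunk. The gate is the minimal form of feature attention for
tabular expression input: it lets the network softly silence genes whose
variability is not positional, at the cost of a G×G parameter block.
Setting `attention=False` yields the plain MLP for comparison.

Defaults: hidden sizes (128, 64), dropout 0.2, Adam at learning rate
1e-3, batch 64, at most 200 epochs, early stopping on a stratified 10%
validation split with patience 10 (best weights restored), optional
inverse-frequency class weights (off by default). These are ordinary
choices for a small tabular network; no hyperparameter search is done,
and all of them are recorded in the model archive. Every random step —
initialization, shuffling, dropout, the validation split — draws from a
single generator seeded from the config, so training is bit-reproducible
given (data, config).

The trained bundle stores gene order, class order, per-gene training
mean/sd, all weights, the config and a training fingerprint. The archive
is a JSON header plus raw little-endian float64 blocks in manifest order,
so saving the same model twice produces byte-identical files.

Prediction aligns any matrix by gene symbol, zero-fills missing genes
(error below 50% coverage, warning below 80%), and ties in the argmax
resolve to the first class in sorted class order.

### Evaluation

Accuracy is correct/total; per-compartment AUC is one-vs-rest on that
class's probability (or decision-function) column, computed as the
Mann–Whitney statistic with ties counted ½. Repeated internal validation
uses stratified random 80/20 holdouts with derived seeds (base + repeat
index); the report carries the pooled confusion/accuracy plus the repeat
distribution (accuracies, median, SEM = sd/√n). The "100-fold" internal
validation of the original study design is read as 100 repeated holdouts,
not leave-out folds, because compartment classes are imbalanced and
repeats keep every split stratified. Group comparisons (e.g. male vs
female accuracy distributions) use the equal-variance two-sample t-test
with BH adjustment across the submitted batch; two degenerate equal
groups return p = 1 by convention.

The seven classical baselines are logistic regression, k-nearest
neighbors, Gaussian naive Bayes, a decision tree, a random forest,
histogram gradient boosting, and a linear SVM (AUC from decision-function
scores), all under the identical preprocessing and split protocol.

### Cross-species harmonization

Signatures cross species only through an explicit source→target homology
table; symbols are never case-mapped to guess homologs. Unmapped genes
are dropped and reported; many-to-one homologies collapse to the first
source in set order (a convention, stated because curated homology tables
do contain many-to-many entries). Matrix harmonization translates the
matrix's symbols, then re-indexes to the model's gene order with
zero-fill, erroring below 50% coverage.

### Downstream readouts

Compartment composition per group is reported either as fractions (rows
sum to 1; empty compartments report 0 so kinetic series stay complete) or
relative to a declared baseline group (baseline rows are exactly 1;
division by an empty baseline compartment is an error). Gene-set module
scores are the mean over present member genes of per-gene z-scored
log-normalized expression — deterministic and control-free; the
binned-control-subtraction variant used by some toolkits is a possible
extension, not implemented. Scores are computed per cell and then
averaged per group (not on pseudobulk); groups under 10 cells are flagged
low-confidence. Compartment-wise DE reuses the rank-sum/BH machinery and
sorts by (adjusted p, −|logfc|, symbol) for deterministic output.

## Simulator

The generator emulates the statistical skeleton of compartment-labeled
immune-cell scRNA-seq:

| Parameter | Default | Meaning |
|---|---|---|
| `n_compartments` / labels | 3 (cortex, OM, IM) | class structure |
| `cells_per_compartment` | 500 | per dataset |
| `n_genes` | 2000 | gene universe |
| `n_signature_per_compartment` | 30 | disjoint planted signature genes |
| `effect_logfc` (δ) | 1.5 | natural-log mean shift in the home compartment |
| `nb_dispersion` (φ) | 0.5 | NB overdispersion, variance = μ + φμ² |
| `base_mean_range` | (0.1, 5) | per-gene base mean, log-uniform |
| `n_datasets` | 2 | independent batches |
| `batch_logfc_sd` | 0.3 | per-gene, per-dataset log offset |
| `sex_effect` | 20 genes at logfc 1.0 | sex covariate, Bernoulli(½) per cell |
| `library_size_sd` | 0.3 | per-cell log-normal scaling |
| `motility_attenuation` (m) | 0 | scales the signature shift by (1−m) |
| `residence_ramp` | none | per-timepoint attenuation map |

Counts are gamma–Poisson draws. The truth (base means, signature and sex
gene assignments) is drawn from a child generator keyed only by (seed,
gene-level config), while each dataset's batch offsets and cell-level
noise come from separately keyed streams — so a training simulation and a
timecourse simulation at the same seed share the planted truth but no
noise, which is what makes cross-simulation experiments (e.g. the
residence-time ramp) well-posed transfer tests. Sex is assigned
independently of compartment, so the two are unconfounded by
construction.

What the simulator does **not** model: gene–gene correlation beyond the
planted block structure, doublets, ambient RNA, cell-type mixtures,
zero-inflation beyond the NB, or realistic gene-symbol vocabularies.
Passing the simulated property suite therefore shows that the pipeline's
mechanics are sound (selection finds planted variability, the classifier
transfers across independent batch shifts, erased signal yields chance
accuracy, reruns are bit-identical); it does not certify accuracy levels
on real tissue, where effect sizes are far smaller and nuisance structure
far richer.

Two scale effects of the defaults are worth stating explicitly. First, at
δ = 1.5 the planted compartments are strongly separable, so transfer
accuracies saturate near 1.0 — much higher than is realistic for tissue
data. Second, the 2000-gene universe holds 90 signature genes (4.5%), so
a uniform random 100-gene control set contains ~4–5 planted genes in
expectation (the chance of none is ≈ e^{-4.5} ≈ 1%), and those few strong
markers alone support above-chance transfer (~0.6). In a real ~20k-gene
transcriptome a random set is effectively signature-free and performs at
chance; at this simulation scale the random control retains residual
signal, and `scripts/acceptance.py` reports the measured value as-is.

## Numerical conventions

* Sample (n−1) variance everywhere a spread is estimated.
* All ties that affect output order break lexicographically by symbol.
* HVG ranking keys rounded at 1e-10 before tie-breaking (see above).
* Sigmoid computed in the numerically stable split form; softmax shifted
  by the row max; cross-entropy clamps probabilities at 1e-12.
* Zero-sd genes standardize to 0; all-zero cells produce a valid
  probability vector (the model's response to an all-(−μ/σ, clipped)
  input), never NaN.
* Seeds derived for repeats are `base + index`; simulator streams are
  keyed generators `[seed, purpose, dataset]`.

## Problem sizes used in the checks

The property suite and the reproduction script run at the simulator
defaults (1500 cells per dataset, 2000 genes) with 3–20 seeds per
property, chosen as the smallest replication that makes the medians
stable; unit tests use 60–300-cell fixtures.

## Known limitations

* The dense in-memory matrix is simple and adequate for ~10⁴-cell
  compartment datasets but not for atlas-scale data; a sparse backend
  would be the first extension.
* The gate's G×G weight block grows quadratically in the gene-set size;
  for sets ≫ 10³ genes a low-rank gate would be preferable.
* The HVG dialect implemented here (dispersion z-scored in equal-frequency
  mean bins) is one of several in circulation; rankings from other
  toolkits' variants will overlap strongly but not exactly.
* Homology mapping is only as good as the supplied table; no ortholog
  inference is attempted.
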