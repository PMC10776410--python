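# Methods

`leukimm` quantifies anti-leukemia immunity from two data arms: bulk TCRβ
repertoires (clonotype tables) and single-cell RNA-seq count matrices with
hashtag multiplexing. This note records the models, the defaults and why,
the numerical choices, what the synthetic-data generators do and do not
emulate, and known limitations.

## TCR repertoire layer

A repertoire is a table of clonotypes (unique CDR3β amino-acid rearrangements)
with read counts; frequencies `p_i = count_i / total` are recomputed on every
operation. Three table dialects are read (AIRR rearrangement TSV, immunoSEQ
export, VDJtools), detected by required header columns; VDJtools-style TSV is
written.

**Productive filtering.** A clonotype is removed when its CDR3β contains a
stop (`*`) or frame-shift marker (`_`, `~`), is empty, or its nucleotide
junction length is not a multiple of three. Frequencies are renormalized.

**Depth normalization.** Samples are subsampled to a common read depth
(default 40,000 reads) by a multivariate-hypergeometric draw — sampling reads
*without replacement*, the semantics of read-resampling in repertoire
toolchains. Samples at exactly the target depth pass unchanged; clones drawn
to zero are dropped.

**Diversity.** With frequencies `p_i` over `R` clones:
Shannon–Wiener `H = −Σ p_i ln p_i` (natural log), normalized Shannon
`H / ln R`, clonality `1 − H / ln R`, Simpson `Σ p_i²` and its inverse.
A single-clone repertoire takes normalized Shannon 0 and clonality 1 by
convention (resolving `ln 1 = 0`). These formulas are implemented directly;
the test suite cross-checks them against scikit-bio's alpha-diversity
functions and a brute-force recomputation.

## Motif grouping

Antigen-sorted TCRs recognizing a shared epitope often share short local
motifs. The grouping is a Fisher-enrichment + similarity-network procedure:

1. **k-mer extraction** (k ∈ {3, 4} by default) from the flank-trimmed CDR3β
   (trim (3, 2): the conserved `C...F` junction flanks and adjacent germline
   residues carry little specificity information).
2. **Enrichment**: per k-mer, a one-sided Fisher exact test on presence
   counts in positives vs a large unsorted reference repertoire,
   Benjamini–Hochberg adjusted over all tested k-mers. Fold change is the
   positive presence rate over the reference rate, with a 0.5 pseudocount
   when the reference count is zero. Groups are kept at fold ≥ 10,
   adjusted p < 0.05, ≥ 3 members from ≥ 2 subjects.
3. **Similarity network**: nodes are unique CDR3β; edges join members of an
   enriched group, or sequences of equal length within Hamming distance 1.
4. **Selection**: TCRs in connected components with ≥ 3 members spanning
   ≥ 2 subjects form the shared-motif subset used as classifier positives.

This is a functional equivalent of web-server motif-grouping tools whose
exact parameters are not reproducible; the contract is recovery of planted
motif families (≥ 95% recall, ≤ 5% background admission on simulations with
known truth), not bit-level parity with any specific tool.

## CDR3β specificity classifier

A binary Gaussian-process classifier maps a CDR3β sequence to the probability
that it recognizes the target antigen.

**Encoding.** Sequences are center-gapped to a fixed frame of 22 positions —
the first ⌈L/2⌉ residues left-aligned, the rest right-aligned, central gaps as
zero vectors — and each residue is mapped to its unit-L2-normalized BLOSUM62
row, giving x ∈ R^440. Center gapping keeps the conserved flanks in fixed
positions while aligning the antigen-contacting loop apex across lengths.

**Model.** `f ~ GP(0, k)` with the squared-exponential kernel
`k(x, x') = σ_f² exp(−‖x − x'‖² / 2ℓ²)` and a Bernoulli-logit likelihood.
Inference is variational: with `K = k(X, X) + 10⁻⁶ I` and `L = chol(K)`, the
latent vector is whitened as `f = Lv` with a mean-field posterior
`q(v) = N(m, diag(s))`. The ELBO's expected log-likelihood is evaluated with
20-node Gauss–Hermite quadrature (no Monte Carlo — the fit is deterministic),
and the KL term is the standard-normal KL, independent of the kernel
hyperparameters.

**Optimization.** Adam, learning rate 0.005, 2000 iterations on the
variational parameters. Hyperparameters (log ℓ, log σ_f², both initialized at
0) enter only through the expected log-likelihood; they are updated every
10th iteration with an integrated step size (10 × 0.005) so cumulative
movement matches a dense schedule while Cholesky refactorizations stay ~1 per
10 iterations and every other step is O(n²). The log-σ_f² gradient is
analytic (the whitened latent scales with σ_f); the log-ℓ gradient is a
central finite difference of the expected log-likelihood (step 10⁻³), which
avoids differentiating through the Cholesky factor. A non-finite ELBO raises
immediately rather than being swallowed.

**Prediction.** The predictive latent distribution at `x*` follows from the
whitened posterior (`μ* = a᷀ᵀm`, `σ*² = k** − ‖a‖² + Σ s_i a_i²` with
`a = L⁻¹ k*`); the class probability is the Gauss–Hermite average of the
logistic function. Class imbalance is handled by the natural prior of the
1:2 positive:control training design — no reweighting — so with
uninformative inputs predictions shrink toward 1/3.

**Cross-validation and repertoire scoring.** Stratified 10-fold CV reports
held-out AUROC per fold (AUROC computed by the rank/Mann–Whitney statistic,
ties at 1/2) and the mean. `predict_repertoire` scores every clonotype and
reports the read-weighted specific fraction (the sum of clone frequencies
with probability ≥ 0.5, i.e. percent of the total repertoire) plus the clone
count; clonotypes that cannot be encoded (length > 22 or non-standard
letters) score 0.

A consequence of full-ELBO hyperparameter learning worth knowing: at small
training sizes (tens of sequences) the posterior is honestly underconfident
— probabilities compress toward the class prior even when ranking is
perfect. Thresholded quantities (specific fraction at 0.5) are therefore
meaningful at realistic training sizes (hundreds of TCRs, as in the
231-positive / 462-control benchmark design) and should not be expected from
toy-sized fits.

## Single-cell quantification

**QC.** Cells are kept inside closed bounds: mitochondrial UMI fraction
≤ 0.15 (genes prefixed `MT-`), ribosomal fraction ≤ 0.50 (`RPS`/`RPL`),
100 ≤ detected genes ≤ 4500, housekeeping-gene UMI fraction in [0.25, 0.60]
(configurable panel; a default panel of 20 broadly expressed genes is
bundled since no canonical list exists), and depth in [500, 30000]. Bounds
are inclusive for keeping — exclusion is on strict violations, so a cell at
exactly 30,000 reads survives. The report counts removals per criterion
(a cell can fail several).

**Normalization.** Counts are scaled to 10,000 per cell and log1p-transformed
before scoring and differential expression — the standard convention of the
single-cell toolchains this layer is interoperable with.

**Module scores** follow the binned-control scheme of Tirosh et al. (via
scanpy's `score_genes`): the mean log-normalized expression of the set genes
minus the mean over control genes drawn per set gene from the same
average-expression bin (25 bins, 100 controls per gene, seeded). The score
measures cell-level deviation relative to expression-matched genes; a shift
common to all cells is largely absorbed by the matched controls, so scores
are interpreted across cells, not as absolute expression. The registry
bundles the cytotoxicity (7 genes), exhaustion (5), HLA class I (3), HLA
class II (13), BCR-ABL1 pathway (39) and PR1 (PRTN3, ELANE) sets. The
BCR-ABL1 list stores its published symbols verbatim, including several that
match no current HGNC symbol (ANZA2, RXCFP1, PTPBP3, LOP2); callers wanting
corrections should rename matrix genes explicitly rather than have the
registry guess.

**Quantile bins** rank scores into q equal-count bins (default 5) with ties
broken by stable input order; a constant score vector degenerates to a single
bin, by decision.

**Differential expression** is a per-gene Welch t-test on log-normalized
expression with Bonferroni adjustment, plus log2 fold-change of group means
(pseudocount 10⁻⁹) and the fraction of cells detecting each gene. Genes with
zero variance in both groups get p = 1 when means agree (t = 0/0).

## Ligand–receptor permutation test

Clusters are first subsampled to equal cell numbers (without replacement,
seeded; smaller clusters dropped with a warning) so no cluster dominates the
null. For a pair (ligand, receptor) and ordered clusters (source, target)
the score is `½(mean ligand in source + mean receptor in target)` on
log-normalized expression. The null permutes the cluster-label vector
(n_perm = 1000, shared across pairs) and
`p = (1 + #{permuted ≥ observed}) / (n_perm + 1)` — the add-one estimator,
so p ≥ 1/(n_perm+1) always. A pair is only scored as expressed when each
gene is detected in > 10% of its cluster's cells; otherwise p = 1. Only
simple single-subunit pairs are supported, and no curated interaction
database is bundled — users supply the pair list.

## Hashtag demultiplexing

Counts are CLR-normalized per cell: `clr_i = ln(x_i + 1) − mean_j ln(x_j + 1)`.
For each tag a background distribution of CLR values is assembled from cells
that are *not* candidate positives for that tag: cells whose maximal tag is
that tag are excluded, and, when the tag's CLR distribution is bimodal, the
high cluster of a deterministic 1-D 2-means split is excluded too. The second
exclusion is essential in the presence of doublets: a doublet's second signal
tag is never the cell's maximum yet is clearly no background, and leaving it
in inflates the background quantile past the doublet signal level (measured
doublet recall collapses from ~1.0 to ~0.27 without it). Bimodality requires
the cluster means to be > 2.8 pooled within-cluster standard deviations apart
— a unimodal normal yields ≈ 2.65 under 2-means, so clean tags fall back to
the argmax-only rule instead of truncating their noise tail.

A Gaussian KDE is fit to the background with a biased-cross-validation (BCV)
bandwidth, minimizing the Scott–Terrell objective

    BCV(h) = (2 n h √π)⁻¹ + (64 n² h √π)⁻¹ Σ_{i<j} g(d_ij/h),
    g(u) = e^{−u²/4} (u⁴ − 12u² + 12)

over h ∈ [0.1, 1] × 1.144 · sd · n^{−1/5} (validated against R's `bw.bcv`).
When the minimum sits at the search boundary — common for unimodal data —
Scott's rule is used instead and the fallback is logged. The positivity
cutoff is the 0.99 quantile of the fitted density (by root-finding on the
KDE mixture CDF). A cell is a singlet iff exactly one tag exceeds its
cutoff, a doublet at ≥ 2, negative at 0; only singlets are retained
downstream. With a q-quantile cutoff each of a singlet's `n_tags − 1`
non-signal tags is falsely positive with probability ≈ 1 − q, so the
false-doublet floor is ≈ (n_tags − 1)(1 − q); raise q for many-tag panels.
A comparator demuxer using the empirical background quantile (no KDE) is
bundled for concordance checks.

## Group statistics

Mann–Whitney (two-sided) is exact — the full null distribution of U — for
tie-free groups under 50 observations each, the convention of R's
`wilcox.test` (the toolchain these analyses standardize on); larger or tied
samples use the normal approximation with tie and continuity corrections.
The exact test's attainable size at n = 7 vs 7 and α = 0.05 is 0.0379.
Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) p-value; all-identical
observations return (0, 1) by convention. Fisher's exact test is two-sided
by hypergeometric mass summation; odds ratios are the sample estimate ad/bc
with the Haldane 0.5 correction on every cell when any cell is zero.
Multiplicity adjustment is Benjamini–Hochberg step-up or Bonferroni.
Effect sizes are log2 fold-changes of group medians, with signed infinity
(and a warning) for non-positive medians. Differential abundance tests
per-sample cell-type proportions between groups (MWU, BH across cell types)
and flags |log2FC| > 1 with adjusted p < 0.05. Cluster-enrichment odds
ratios default to cell-level counting; clonotype-level counting is the
caller's choice of inputs.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the pipeline assumes, with
truth labels, so every stage is testable without restricted-access data.

* **Repertoires**: Zipf clone sizes (`rank^{−a}`, default a = 1.3, a
  moderately clonal antigen-experienced repertoire) renormalized to the
  target read total by largest-remainder rounding with every clone kept at
  ≥ 1 read; CDR3β of uniform random amino acids with `C...F` flanks, lengths
  uniform on [11, 17]; a planted family of `n_specific` clones carrying a
  3–5-mer core near the junction midpoint with positional jitter and
  per-residue mutation. Background sequences containing the core verbatim
  are rejected, so planted labels coincide with the substring test at
  mutation rate 0. Not emulated: V(D)J recombination statistics, germline
  segments, non-uniform amino-acid usage, sequencing error. Classifier
  results on this background therefore show that the model learns planted
  sequence structure at realistic sample sizes — not that it matches any
  particular biological background distribution.
* **Count matrices**: negative-binomial counts (size parameter = 2 by
  default, i.e. substantial overdispersion) around lognormal gene baselines,
  with planted cluster-specific programs and ligand–receptor boosts as mean
  multipliers. Not emulated: batch effects, ambient RNA, zero inflation
  beyond NB, gene–gene correlation.
* **HTO mixtures**: per-cell Poisson counts, one signal tag at μ_signal
  (default 200) and background tags at μ_background (default 5); a
  doublet fraction (default 8%, a typical 10x loading rate) carries two
  signal tags. Not emulated: tag cross-talk, cell-size-dependent staining.

All generators take explicit integer seeds; there is no global random state.

## Problem sizes used by the test suite and acceptance script

The classifier benchmark mirrors a 231-positive / 462-control training
design (10-fold CV, 2000 iterations per fold, plus a label-permutation
null); interaction calibration uses 2000 independent null pairs over two
150-cell clusters at 1000 permutations; demultiplexing accuracy uses a
2000-cell, 4-tag mixture at 10% doublets; subsampling calibration averages
10,000 seeded draws. These sizes make the Monte-Carlo error small relative
to every asserted tolerance while keeping the full suite inside a few
minutes of CPU time.

## Known limitations

* The GP classifier is full-rank in the training set (no inducing points);
  training cost is O(n³) per Cholesky and practical to a few thousand
  sequences, beyond which a sparse approximation would be needed.
* Only CDR3β is modelled — no V/J gene or CDR3α features, no multi-epitope
  multiclass support.
* The motif layer tests k-mers marginally; positionally-split or
  discontinuous motifs are only captured indirectly through the Hamming
  edges.
* The interaction test treats clusters as exchangeable under the null;
  strong cluster-size or depth confounding should be removed (the equal-size
  subsampling step) before testing.
* Demultiplexing assumes at most two signal tags per droplet; triplets are
  called doublets.
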