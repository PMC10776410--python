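# leukimm

Quantifying anti-leukemia immunity from TCRβ repertoires and single-cell
RNA-seq.

In chronic myeloid leukemia (CML), patients who stop tyrosine-kinase
inhibitor therapy can remain in treatment-free remission when their immune
system controls the residual leukemic cells. Two measurable arms of that
control are (i) T cells whose receptors recognize leukemia-associated
antigens such as PR1 (an HLA-A\*02:01-restricted peptide from *PRTN3* and
*ELANE*), detectable in bulk TCRβ sequencing, and (ii) NK-cell activity and
its inhibitory ligand–receptor crosstalk with leukemic stem cells (e.g.
*LGALS9*–*HAVCR2*, *PVR*–*TIGIT*), detectable in single-cell RNA-seq.
`leukimm` implements the computational pipeline for both arms, end to end,
with synthetic-data generators that plant known ground truth so every stage
is testable without access to patient data.

## What is in the box

**TCR arm**

- `leukimm.repertoire` — clonotype-table I/O (AIRR / immunoSEQ / VDJtools
  TSV), productive filtering, depth normalization by hypergeometric read
  subsampling (default 40,000 reads), and diversity indices
  (Shannon–Wiener H = −Σ pᵢ ln pᵢ, clonality 1 − H/ln R, Simpson Σ pᵢ²).
- `leukimm.motif` — grouping of antigen-sorted CDR3β by enriched k-mers
  (one-sided Fisher exact vs a reference repertoire, BH-adjusted, fold ≥ 10)
  and a similarity network (shared motif or Hamming distance ≤ 1); selects
  the shared-motif subset used as classifier positives.
- `leukimm.classifier` — a variational Gaussian-process classifier on
  center-gapped, BLOSUM62-encoded CDR3β with a squared-exponential kernel
  and Bernoulli likelihood (Adam, learning rate 0.005, 2000 iterations),
  exposed as a scikit-learn estimator (`TCRSpecificityClassifier`), with
  stratified 10-fold cross-validation (AUROC) and repertoire-level
  quantification: the read-weighted fraction of a repertoire predicted
  antigen-specific.

**Single-cell arm**

- `leukimm.scquant` — QC at fixed bounds (mitochondrial ≤ 15%, ribosomal
  ≤ 50%, 100–4500 genes, housekeeping 25–60%, depth 500–30,000), Tirosh-style
  module scores with the published gene sets (cytotoxicity, exhaustion,
  HLA I/II, BCR-ABL1, PR1), quantile binning, and per-gene Welch-t
  differential expression with Bonferroni adjustment.
- `leukimm.interactions` — ligand–receptor scoring between clusters on
  equal-size subsamples with a cluster-label permutation null
  (p = (1 + #{null ≥ obs}) / (n_perm + 1)).
- `leukimm.htodemux` — hashtag demultiplexing: CLR normalization, per-tag
  KDE background with a biased-cross-validation bandwidth, 0.99-quantile
  positivity cutoffs, singlet/doublet/negative calls.

**Shared**

- `leukimm.stats` — Mann–Whitney (exact for small tie-free samples),
  Kruskal–Wallis, two-sided Fisher exact, BH/Bonferroni adjustment, log2
  fold-change of medians, differential abundance of cell-type proportions,
  enrichment odds ratios (Haldane-corrected).
- `leukimm.simulate` — generators for power-law repertoires with planted
  motif families, negative-binomial count matrices with planted programs and
  ligand–receptor co-expression, and Poisson HTO mixtures with known
  singlet/doublet truth.
- `leukimm` CLI — `simulate`, `repertoire-stats`, `motif-group`,
  `train-classifier`, `cross-validate`, `predict-repertoire`, `sc-qc`,
  `score`, `de`, `interactions`, `demux`, `abundance`; every run writes its
  effective config and a log with seeds and parameters.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

Simulate a repertoire that mirrors a realistic training design — 231
antigen-specific TCRs sharing a planted core motif (5% per-residue mutation,
±1 position jitter) among 693 clonotypes — then summarize its diversity and
cross-validate a specificity classifier (a quick 400-iteration fit; the
full 2000-iteration benchmark lives in `scripts/acceptance.py`):

```python
import numpy as np
from leukimm.simulate import RepertoireSimConfig, make_repertoire
from leukimm.repertoire import diversity_stats, subsample_reads
from leukimm.classifier import ClassifierConfig, cross_validate

cfg = RepertoireSimConfig(n_clones=693, total_reads=40_000, n_specific=231,
                          mutation_rate=0.05, core_position_jitter=1, seed=1)
rep, labels = make_repertoire(cfg)
d = diversity_stats(subsample_reads(rep, 40_000, seed=1))
print(f"clones={d.richness} shannon={d.shannon:.3f} clonality={d.clonality:.3f}")

seqs = np.array(rep.cdr3s(), dtype=object)
report = cross_validate(list(seqs[labels]), list(seqs[~labels]),
                        ClassifierConfig(iterations=400, seed=0))
print(f"mean 10-fold CV AUROC = {report.mean_auroc:.3f}")
```

prints

```
clones=693 shannon=3.650 clonality=0.442
mean 10-fold CV AUROC = 0.933
```

The clonality of 0.442 says the simulated repertoire is strongly skewed
toward its largest clones (0 = perfectly even, 1 = monoclonal), as expected
for a Zipf clone-size law. The held-out AUROC is the probability that a
random planted TCR outscores a random background TCR — well above chance,
because the planted family shares learnable sequence structure.

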