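# Methods

## The model

Severe, surgery-requiring Crohn's disease is stratified from peripheral
CD3+ T-cell expression into two subtypes. PBT profiles resemble non-IBD
blood; PBmu profiles are shifted toward the mucosal T-cell compartment in
the *direction* of the mucosal signature (not its full magnitude). The
pipeline treats subtype structure as a latent two-class label recoverable
three ways: unsupervised (correlation-distance clustering), supervised
(multi-classifier consensus), and via orthogonal scores (TRS, subset
enrichment, serology) that should co-vary with the label if the biology is
coherent.

## Synthetic cohorts

The generator is first-class, tested code: it is the substrate for every
downstream test, so its structural assumptions matter more than its
realism.

- **Counts.** Negative binomial (gamma–Poisson) with variance
  m + α·m², a single dispersion α (default 0.1, a typical bulk RNA-seq
  value). Per-gene relative abundances are log-normal(0, 1) normalized to
  the mean library size (default 2×10⁷ reads over 10,000 genes — ordinary
  bulk sequencing depth); library sizes are log-normal with CV ≈ 0.3 to
  exercise normalization.
- **Cohort layout.** Default 100 peripheral CD samples at a 37/63
  PBmu/PBT split, 17 non-IBD subjects, and one mucosal sample per subject,
  mirroring the study design the analysis targets.
- **Planted differential expression.** 1,500 of 10,000 genes shifted by
  `de_log2fc` (default 1.0, i.e., twofold) in PBmu, 92% up. Mucosal
  samples (CD and non-IBD) receive a shift of the same sign on the same
  genes, which is what makes PBmu "mucosal-like" directionally.
- **Subset composition.** Each cell subset (NKT, TH1, CD4/CD8
  memory/naive) owns a 50-gene signature block; each sample draws a latent
  subset activity (log2 units, SD 0.3) centred on the subset's PBmu shift
  (+1.0 for NKT, −0.8 for the others; the source analysis reports
  directions, not effect sizes, so these are free defaults chosen to be
  comfortably detectable at n≈40 — documented, not calibrated to any
  deposited dataset). Signature genes shift by the sample's activity;
  truth tables record the activities for correlation tests.
- **Clinical covariates.** Bernoulli with logits linear in NKT activity
  (stricture, perianal) or in CD4/CD8 depletion (perianal-penetrating,
  recurrence), reproducing the reported association structure
  qualitatively.
- **Post-operative samples.** The first `n_postop_pairs` (default 30)
  peripheral CD subjects, split across subtypes proportionally, gain a
  postop draw. PBT subjects are re-drawn from their surgery distribution;
  PBmu subjects have every planted shift multiplied by
  (1 − reversion_strength), so strength 1 is full reversion to the PBT
  distribution.
- **eQTL table / serology / references.** The risk table samples eGenes
  from planted up-genes with direction +1 (fraction `frac_risk_up`,
  default 0.9) and down-genes with −1, so the polarized sum separates
  subtypes by construction. Titers are log-normal with a shared latent
  location rising in NKT activity and falling in CD4/CD8 activity; ANCA is
  carried uncoupled; resection length is re-drawn coupled to the latent
  titer sum. Reference profiles are the mucosal mean log2 profile plus
  gene-permuted decoys.

What the generator does **not** emulate: batch effects, gene–gene
correlation beyond the planted blocks, isoform structure, count outliers,
or genotypes (the risk table is generated directly). Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the planted model, not robustness to those real-data artifacts.

## Normalization

Size factors follow the median-of-ratios definition: the geometric mean is
taken over genes with strictly positive counts in all samples, each
sample's factor is the median count/geometric-mean ratio over those genes,
and factors are rescaled to geometric mean 1 (identifiability). The log2
transform uses pseudocount 1 (unstated in the source; documented
assumption). A caveat the tests make visible: with 15% of genes shifted
almost all upward, the median ratio in shifted samples moves a few percent,
shrinking estimated fold changes by ~0.1 log2 units — an inherent
composition bias of ratio-based normalization, which is why recovery tests
with the fold ≥ 2 filter use planted effects of log2FC 1.5, safely away
from the knife edge at exactly 1.0.

## Differential expression

Welch t (unpaired) or paired t on log2 values, vectorized per gene;
log2FC is the mean difference; BH FDR across all tested genes; the joint
filter (fold ≥ 2 AND p < 0.001 AND FDR < 0.002 cross-sectionally;
p < 0.001, FDR < 0.013 for the paired post-operative contrast) is applied
jointly because the ordering of fold vs FDR gating is unstated in the
source. Zero-variance genes get t = 0, p = 1 and a flag (conservative).
The paired postop contrast is reported as postop − surgery, so a
post-surgical decrease has negative log2FC and its post/pre fold is
2^log2FC, directly consumable by the kinase filter.

## Consensus classification

Seven classifiers vote per test sample; features are Welch-t-selected at
p < 0.001 strictly inside the training data (and inside each bootstrap
replicate — no selection leak, verified by a label-permutation test).

- **BCC**: compound covariate c = Σ t_g x_g with a pooled-variance
  Gaussian class-conditional model of c and equal priors (the
  Wright–Simon formulation; the source names the method without defining
  it).
- **DLDA**: gene-wise pooled variances, equal priors.
- **kNN (k = 1, 3)**: Euclidean distance on selected genes.
- **Nearest centroid**: Euclidean.
- **SVM**: linear kernel, C = 1.
- **NMF**: matrix shifted non-negative by subtracting the global minimum,
  rank-2 factorization (nndsvda init, multiplicative updates, 300
  iterations, seeded), samples assigned by larger loading, factors mapped
  to classes by training-set majority.

The call is the majority vote (ties, impossible with seven voters unless a
classifier abstains, fall to DLDA — deterministic and documented).
Bootstrap cross-validation resamples with replacement stratified by class,
trains on the bag, scores the out-of-bag samples, and redraws (logged)
any replicate with an empty out-of-bag set.

## Single-sample enrichment

GSVA variant for continuous log2 data: per-gene Gaussian-kernel CDF with
bandwidth sd/4 (floored at 1e-12 for constant genes), per-sample ranking
of the statistics, symmetrized rank weights |p/2 − rank|, and a KS-like
walk with weight exponent τ = 1; the score is max positive + max negative
deviation. A set equal to the whole universe (or empty after matching) has
no contrast and scores exactly 0. ssGSEA uses weight exponent 0.25 on
expression ranks and the running-sum area, optionally min-max normalized
cohort-wide. Scores are rank/CDF-based, hence invariant to gene order and
to per-gene monotone shifts.

## Gated two-group testing

Shapiro–Wilk at α = 0.05 per group; both normal → Welch t; otherwise
Mann–Whitney. For groups of ≤8 the Mann–Whitney p is permutation-exact by
full enumeration of assignments (valid under ties); larger groups use the
tie-corrected normal approximation. Constant pooled data returns p = 1
with a degenerate-test flag. Note the gate means small *regular-looking*
samples (e.g., 4 equally spaced values) legitimately route to Welch; the
exact branch is reachable only when normality is rejected.

## TRS

Per present eGene: z-score across samples using the population (n) SD —
the n vs n−1 choice is unstated in the source; population SD is fixed here
and makes the output invariant exactly (mean 0, SD 1 to 1e-8). Direction
−1 genes are sign-flipped ("low expression is risk"), the polarized
z-scores summed per sample, and the sums re-standardized. Missing and
zero-variance eGenes are skipped and reported; the run errors if fewer
than `min_fraction_present` (default 0.5) of the table is usable. The
sample universe for z-scoring is whatever matrix is passed (all samples by
default); restrict the matrix to restrict the universe.

## Serology

Quartile cut-points are type-7 sample quantiles; titers bin 1–4 by ≤
comparisons (ties bin low); the QSS sums the four microbial analytes
(range 4–16). Binning is rank-based, hence invariant to strictly
increasing per-analyte transforms. Whether the source computed quartiles
on CD-only or all subjects is unstated; the cohort passed in defines the
universe.

## Panel refinement

ARCHS4-style co-expression matching is replaced by Pearson similarity
against a local reference-profile matrix; the testable claim is that
refinement preserves mucosal-signature similarity, not any external
service's internal score. The query profile is the absolute PBmu mean
log2 profile — absolute, because the reference holds absolute mean
expression profiles and a PBmu-minus-PBT difference vector carries no
baseline-abundance signal to correlate with them. Refinement is greedy
backward elimination (exhaustive subset search is intractable): each step
deletes the gene maximizing target similarity, tie-broken by smallest |t|
then gene id, subject to the target profile keeping rank ≤
`min_target_rank` (default 1); it stops at the target size or when every
deletion would break the rank constraint. The full similarity and rank
trajectories are recorded. The panel is then scored as a single GSVA gene
set and reported against the TRS and subset scores; the NMF 2-cluster
accuracy is reported, not asserted.

## Problem sizes and numerical choices

Tests run the generator at two scales: a shared medium cohort (40
peripheral CD samples, 3,000 genes, 300 DE at log2FC 1.5) for module
tests, and the full default cohort (100 samples, 10,000 genes) for the
end-to-end checks; both complete in seconds per test. Recovery assertions
for the paired post-operative contrast use log2FC 2 (the strong-separation
condition also used for bootstrap-error checks) because at ~11 PBmu pairs
the paired t at p < 0.001 is otherwise underpowered for effects near the
filter boundary. Tolerances: oracle equivalence at 1e-8 or tighter;
TRS standardization at 1e-8; all tie-breaks (consensus votes, deletion
order) are deterministic and documented above. Degenerate inputs (constant
genes, empty gene sets, unpaired samples, zero margins) raise errors or
flagged conservative values rather than propagating NaNs.

## Known limitations

- The generator's subset-shift and serology effect sizes are free
  parameters; association tests verify directions, not magnitudes.
- Median-of-ratios composition bias under heavily one-sided DE is
  reproduced, not corrected.
- The kinase universe is a user-supplied gene list; no drug or kinome
  database is bundled.
- The modified pre-operative severity index is not implemented (its
  weights are not fully published); severity enters only through the
  simulated clinical covariates.
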