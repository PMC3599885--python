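# Methods

## Scope and model

`hicdyn` analyses genome-wide chromatin-interaction dynamics between two
conditions (a control, labelled T0, and a stimulated condition, labelled T1 —
the motivating system is an estrogen-treated breast-cancer cell line) from
binned Hi-C contact maps.  The pipeline has four stages:

1. **Binning and contact matrices.**  The genome is tiled into fixed-width
   windows (default W = 1 Mb); each chromosome contributes `ceil(length/W)`
   bins, the last bin possibly short.  Read pairs are canonically ordered
   (lower chromosome, then lower position first), optionally deduplicated by
   exact coordinate identity, and accumulated into a symmetric bin-pair count
   matrix per condition.  The total bin count is a property of the supplied
   chromosome-size file, never a constant of the package.

2. **Observed/expected Z-scores.**  Each cell's raw count is divided by an
   expected level: for intra-chromosomal cells the genome-wide mean count at
   the same bin separation (contact probability decays with genomic
   distance), for inter-chromosomal cells the global inter mean.  A
   `uniform` mode (single global mean) exists for comparison.  The resulting
   ratios are standardized to Z-scores with the *population* standard
   deviation over *observed* cells (count > 0), separately for the intra and
   inter classes — the two classes live on incomparable ratio scales, and
   including the vast sea of unobserved zeros would make the statistics
   depth-dependent rather than structure-dependent.  Unobserved cells carry
   the sentinel Z = 0 alongside an explicit boolean mask; every downstream
   rule consults the mask, so an observed cell whose Z happens to equal 0
   still counts as an interaction.  Whether standardization should be
   per-chromosome instead of genome-wide is genuinely open; genome-wide was
   chosen because hot-region calling compares bins across chromosomes.

3. **Interaction frequency and hot/cold regions.**  A bin's interaction
   frequency is the number of bins it contacts (observed mask, self-pair
   excluded by default, toggleable) divided by the total bin count — a
   breadth measure.  Bins at or above a high threshold (default 30%) are
   *hot regions*, bins at or below a low threshold (default 0.5%) *cold
   regions*; calls are ranked by frequency with ties broken by genome order
   and truncated to a top-N (default 10).  At genome scale the
   self-pair convention shifts frequencies by under one part in two
   thousand, which is why it is a documented flag rather than a branch
   of the science.

4. **Differential statistic.**  On each cell define the exponential
   interaction strength E = exp(Z) if observed, 0 if not.  The relative
   ratio

       r = (E1 − E0) / ((E1 + E0)/2) = 2 (k − 1)/(k + 1),   k = E1/E0

   is antisymmetric under condition swap, bounded in [−2, 2], equals 0.67 /
   1.33 / 18·11⁻¹ ≈ 1.63 at 2- / 5- / 10-fold changes, and saturates at ±2
   exactly when the contact exists in only one condition.  The sentinel must
   map to strength 0 (not exp(0) = 1): that is the only choice under which
   condition-exclusive contacts reach the ±2 endpoints.  For the same
   reason the denominator is the mean of the exponential strengths, not of
   the raw Z-scores.  A *strong* differential call requires |r| at the
   saturation bound and the observed condition's Z strictly above 1
   (defaults `ratio_cut = 2`, `z_cut = 1`); calls are typed gain/loss (sign
   of r, gain = treated-specific) × intra/inter (chromosome equality).  A
   relaxed mode (|r| ≥ 0.67, cell observed in at least one condition, no Z
   cutoff) reproduces the weaker secondary criterion.  Per-bin gain/loss
   profiles increment both endpoint bins of each call (a within-bin call
   increments once).

### Integration with annotations

Genes are split, strand-aware, into 5 kb upstream of the 5' TSS, gene body,
and 5 kb downstream *anchored at the TSS* (the downstream flank runs from
the TSS into the gene; anchoring at the 3' end is a plausible alternative
and the anchor is a function argument).  Reads and peaks are assigned by
midpoint.  Per-gene read counts are log-transformed (log2, pseudocount 1 —
both recorded in the output) and averaged per bin over genes assigned by
TSS; bins with no gene are excluded, and the excluded set depends only on
the annotation, not on the mark or condition.  Condition contrasts use a
paired t-test per (mark, gene part, interaction class), statistic sign
positive iff the treated mean exceeds the control mean, with a Mann-Whitney
U alternative; Benjamini-Hochberg q-values are attached alongside raw
p-values.  Peak-density association with interaction frequency is Spearman
rank correlation.  Break-point enrichment in hot regions uses the exact
upper binomial tail with success probability hot-bins/total-bins, summed in
log space so tails far below 1e-300 in magnitude remain representable via
their log10 (a hypergeometric variant is available).  Expression agreement
across conditions is Pearson correlation over shared genes; differential-
expression enrichment per interaction class is a 2×2 chi-square without
continuity correction by default, with degenerate margins reported as
statistic 0 / p 1 and low expected counts flagged as warnings.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with exact
planted ground truth; all generators are pure functions of (config, seed).

* **Contacts.**  Intra-chromosomal pairs follow a truncated discrete power
  law on bin separation, P(d) ∝ (d+1)^(−α) with α = 1 (canonical contact
  decay) up to 20 bins; the truncation keeps every sampled distance stratum
  deep enough (λ ≳ 6 pairs/cell at the default 60,000 pairs per condition)
  that single-condition background observations with high Z — the failure
  mode that would contaminate differential calls — are rare.
  Inter-chromosomal background is Poisson at 0.02 pairs per bin pair.  Ten
  hot bins (interior chromosome positions — edge bins have one-sided intra
  neighborhoods and systematically lower frequency) carry a 20× trans-rate
  boost, which places their interaction frequencies in the ≈35–55% band the
  hot-region caller targets while typical bins sit near 20–25%.
* **Planted differentials.**  20 gain and 20 loss cells (half intra at
  separations 5–20 bins, half inter; never on hot bins) receive exactly 60
  pairs in the treated or control condition respectively; background
  sampling skips planted cells, so gains are observed only in T1 and losses
  only in T0 and the planted truth saturates r at ±2 exactly.
* **Tracks.**  Per-gene-part counts are negative binomial (dispersion 10;
  Poisson in the large-dispersion limit) around a log-normal per-gene
  propensity shared between conditions; in the treated condition genes
  whose TSS bin anchors a planted differential cell shift by the mark's
  configured log2 effect (+0.5 for H3K4me3, H3K27me3, H3K9ac, H3K14ac;
  −0.5 for H3K9me3 and Pol-II; 0 for H3K4me1 and FAIRE, mirroring the
  reported direction pattern).
* **Annotations.**  1,000 genes with uniform starts and log-normal lengths;
  peak counts per bin Poisson around base·(1 + coupling·f̂) where f̂ is a
  normalized frequency proxy (pass the measured profile to couple peaks to
  realized frequency); 314 break-points placed in hot bins with probability
  0.22, uniformly elsewhere; expression with shared per-gene signal
  (SD 1) plus small independent noise (SD 0.1), giving cross-condition
  correlation ≈ 0.99.

**What the generator does not emulate:** restriction-fragment structure,
aneuploid/rearranged karyotypes, copy-number-driven coverage waves,
correlated background between conditions, or A/B-compartment plaid
patterns.  Passing recovery tests therefore demonstrates that the
estimators identify the signals they define under the stated noise model —
not that real tumor-line Hi-C is free of the confounders above.

## Numerical choices

* Population (not sample) SD in Z standardization; a class with zero ratio
  spread gets Z = 0 throughout with the mask preserved.
* Saturation comparisons use |r| ≥ cut − 1e-12; exclusive cells evaluate to
  ±2 exactly in IEEE arithmetic (the halving and the division are exact),
  so the epsilon only guards pathological rounding of near-saturated cells.
* Fold-change round-trip k = (2+r)/(2−r) is accurate to 1e-12 relative for
  k within a few orders of magnitude of 1; near the ±2 endpoints the
  (2−r) cancellation caps float64 accuracy, which the tests acknowledge by
  restricting the tight-tolerance property to k ∈ [1e-3, 1e3].
* Matrix text round-trips write floats with `%.17g`, which reproduces
  float64 bit-for-bit; the observed mask is persisted next to Z because the
  sentinel makes Z = 0 ambiguous on its own.
* Zero-variance rows in correlation maps, empty peak sets, sub-minimal gene
  sets and degenerate contingency margins are flagged (NaN / `undefined` /
  warnings), never silently coerced to 0.

## Problem sizes

Default test and example runs use a 4 × 50 Mb genome (200 bins of 1 Mb) at
60,000 pairs per condition — small enough that a full two-condition
pipeline runs in well under a second, while leaving every distance stratum
and the inter background in the statistical regime the estimators assume.
Recovery properties are evaluated over 20 seeds (50 for the null
calibration of the enrichment test, whose p < 0.05 fraction stays within
binomial noise of 5%).
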