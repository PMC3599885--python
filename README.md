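# hicdyn

Differential chromatin-interaction analysis from binned Hi-C contact maps.

Hi-C read pairs capture which genomic loci touch in the nucleus.  Given two
conditions — a control (T0) and a stimulated one (T1, e.g. estrogen-treated
breast-cancer cells) — `hicdyn` quantifies how the contact landscape
changes: which megabase-scale regions interact with much of the genome
("hot regions"), which individual region pairs gain or lose contact on
stimulation, and how those changes line up with histone marks, transcription-
factor binding peaks, rearrangement break-points and gene expression.  It is
a library for Python users (with a thin `hicdyn` CLI for shell pipelines)
aimed at analysts reworking binned Hi-C comparisons without the original
raw sequencing data: a first-class synthetic-data module generates inputs
with planted, recoverable ground truth.

## The statistics at the core

For bins *i, j* with raw contact count *C<sub>ij</sub>* and expected count
*E<sub>ij</sub>* (genome-wide mean at the same separation for intra-
chromosomal pairs; global inter mean otherwise), the normalized strength is
a Z-score of the observed/expected ratio over observed cells of the same
class; unobserved cells carry a sentinel Z = 0 plus an explicit mask.

A bin's **interaction frequency** is the fraction of all genome bins it has
at least one observed contact with; bins ≥ 30% are hot regions, ≤ 0.5% cold.

Condition differences use the bounded **relative ratio** on exponential
strengths *E = e<sup>Z</sup>* (0 when unobserved):

    r = (E1 − E0) / ((E1 + E0)/2) = 2(k − 1)/(k + 1),  k = E1/E0 ∈ [0, ∞]

so 2-, 5- and 10-fold changes map to 0.67, 1.33 and 1.63, and contacts seen
in only one condition saturate at ±2.  A **strong differential call** is
|r| = 2 with the observed condition's Z > 1, typed gain/loss × intra/inter.

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/differential_calls.py` prints:

```
fold change  2  ->  relative ratio 0.6667
fold change  5  ->  relative ratio 1.3333
fold change 10  ->  relative ratio 1.6364
pure gain -> +2, pure loss -> -2

40 strong differential calls: {'gain-inter': 10, 'loss-inter': 10, 'gain-intra': 10, 'loss-intra': 10}
planted-cell recovery: precision 1.000, recall 1.000
```

The first block is the analytic calibration of the relative ratio.  The
second runs the full pipeline on a simulated two-condition experiment
(4 × 50 Mb genome, 1 Mb bins, 60k pairs per condition) in which 20 gain and
20 loss cells were planted: all 40 are recovered with no false calls.
`examples/hotspot_calling.py` likewise recovers all 10 planted hot regions
as the top-10 frequency ranks (35–52% vs ≈20–25% for typical bins), and
`examples/epigenomic_integration.py` reproduces the planted mark-shift
directions (positive mean T for H3K4me3/H3K27me3/H3K9ac/H3K14ac, negative
for H3K9me3/Pol-II), a Spearman ρ ≈ 0.97 between peak density and
interaction frequency, a break-point enrichment tail of log10 p ≈ −40, and
a cross-condition expression correlation of 0.99.

The same workflow is available from the shell
(`examples/cli_pipeline.sh`): `hicdyn simulate | zscore | frequency |
hotspots | differential | integrate | report`, all inputs and outputs plain
text (BEDPE, BED, TSV, chrom.sizes).

## Layout

- `src/hicdyn/` — library modules: `binning`, `contacts`, `zscores`,
  `frequency`, `differential`, `integration`, `simulate`, `io`, `config`,
  `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — the model, its assumptions, parameter defaults and
  limitations.
- `tests/` — pytest suite, including planted-signal recovery and
  property-based invariants.
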