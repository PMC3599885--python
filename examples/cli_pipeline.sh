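#!/usr/bin/env bash
# End-to-end shell workflow: simulate -> zscore -> frequency -> hotspots ->
# differential -> integrate -> report.  All outputs are plain text.
set -euo pipefail
OUT=${1:-./hicdyn_run}

hicdyn simulate --out "$OUT" --seed 1

for COND in T0 T1; do
  hicdyn zscore \
    --pairs "$OUT/pairs_$COND.bedpe" \
    --chrom-sizes "$OUT/chrom.sizes" \
    --condition "$COND" \
    --out-prefix "$OUT/$COND"
done

hicdyn frequency \
  --zscore-prefix "$OUT/T0" \
  --chrom-sizes "$OUT/chrom.sizes" \
  --out "$OUT/frequency_T0.tsv" \
  --table-out "$OUT/frequency_table_T0.tsv"

hicdyn hotspots \
  --frequency "$OUT/frequency_T0.tsv" \
  --chrom-sizes "$OUT/chrom.sizes" \
  --hot 30 --cold 0.5 --top-n 10 \
  --out "$OUT/hotspots.tsv" --bed-out "$OUT/hotspots.bed"

hicdyn differential \
  --zscore-t0 "$OUT/T0" --zscore-t1 "$OUT/T1" \
  --chrom-sizes "$OUT/chrom.sizes" \
  --ratio-cut 2 --z-cut 1 --mode strict \
  --out "$OUT/calls.bedpe" --profile-out "$OUT/gain_loss_profile.tsv"

hicdyn integrate \
  --calls "$OUT/calls.bedpe" \
  --genes "$OUT/genes.tsv" \
  --chrom-sizes "$OUT/chrom.sizes" \
  --tracks-t0 "$OUT/tracks_T0.tsv" --tracks-t1 "$OUT/tracks_T1.tsv" \
  --frequency "$OUT/frequency_T0.tsv" \
  --hotspots "$OUT/hotspots.tsv" \
  --peaks "$OUT/peaks.bed" \
  --breakpoints "$OUT/breakpoints.bed" \
  --expression "$OUT/expression.tsv" \
  --out "$OUT/integration"

hicdyn report --dir "$OUT"
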