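"""Integrate interaction calls with epigenomic tracks and annotations.

Runs the full downstream battery on one synthetic experiment: mark-shift
enrichment tests (paired t) over genes in the four differential interaction
classes, peak-density vs frequency association, break-point enrichment in
hot regions, and cross-condition expression correlation.
"""

import numpy as np

import hicdyn as hd
from hicdyn.integration import GENE_PARTS, summarize_gene_counts

config = hd.SimulationConfig()
genome = config.genome()
seed = 1
truth = hd.ground_truth(config, seed)

z0 = hd.contact_zscores(hd.simulate_pairs(config, "T0", seed), genome, "T0")
profile = hd.interaction_frequency(z0)
ann = hd.simulate_annotations(config, seed, frequency=profile.frequency)
tracks0 = hd.simulate_tracks(config, ann.genes, "T0", seed)
tracks1 = hd.simulate_tracks(config, ann.genes, "T1", seed)

gb = hd.gene_bins(ann.genes, genome)
gene_sets = {
    t: set(gb.index[gb.isin([b for ij in truth.cells_of_type(t) for b in ij])])
    for t in ("gain-intra", "loss-intra", "gain-inter", "loss-inter")
}
print("genes per interaction class:", {t: len(s) for t, s in gene_sets.items()})

results = []
for mark in sorted(config.mark_effects):
    for part in GENE_PARTS:
        s0 = summarize_gene_counts(tracks0[mark][part], ann.genes, genome, mark=mark, part=part)
        s1 = summarize_gene_counts(tracks1[mark][part], ann.genes, genome, mark=mark, part=part)
        results.extend(hd.enrichment_test(s1, s0, gene_sets, test="t"))
table = hd.enrichment_table(results)
signs = table.groupby("mark")["statistic"].mean().round(1)
print("mean T statistic per mark (positive = up in treated):")
print(signs.to_string())

rho, p = hd.rank_association(hd.peaks_per_bin(ann.peaks, genome), profile)
print(f"\npeak density vs interaction frequency: Spearman rho = {rho:.3f} (p = {p:.2g})")

res = hd.breakpoint_overlap(ann.breakpoints, [int(b) for b in truth.hot_bins], genome)
print(f"break-points in hot regions: {res.overlap}/{res.n_breakpoints}, "
      f"log10 p = {res.log10_pvalue:.1f}")

r, n = hd.expression_correlation(ann.expression["T0"], ann.expression["T1"])
print(f"expression correlation across conditions: r = {r:.3f} over {n} genes")
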