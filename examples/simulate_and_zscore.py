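"""Simulate a two-condition Hi-C experiment and normalize it to Z-scores.

Builds the default synthetic genome (4 x 50 Mb chromosomes, 1 Mb bins),
draws read pairs for control (T0) and estrogen-treated (T1) conditions,
bins them into contact matrices and standardizes observed/expected ratios.
"""

import numpy as np

import hicdyn as hd

config = hd.SimulationConfig()
genome = config.genome()
print(f"genome: {genome.n_chroms} chromosomes, {genome.n_bins} bins of {genome.window:,} bp")

for condition in ("T0", "T1"):
    pairs = hd.simulate_pairs(config, condition, seed=1)
    contacts = hd.build_contact_matrix(pairs, genome, condition=condition)
    expected, usable = hd.expected_matrix(contacts)
    z = hd.zscore_transform(contacts, expected, usable)
    intra = genome.intra_mask()
    print(
        f"{condition}: {len(pairs):,} pairs read, {contacts.total_pairs:,} retained after "
        f"dedup; {z.n_observed:,} observed bin pairs "
        f"({int((z.mask & intra).sum() // 2):,} intra cells, "
        f"max intra Z = {z.z[z.mask & intra].max():.2f}, "
        f"max inter Z = {z.z[z.mask & ~intra].max():.2f})"
    )

# the Z-score measures how many SDs a bin pair's observed/expected ratio sits
# above the mean of its class; unobserved pairs carry the sentinel Z = 0
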