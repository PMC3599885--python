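"""Observed/expected normalization and Z-score transform.

Raw bin-pair counts are divided by an expected level of interaction and the
resulting ratios are standardized to Z-scores.  Intra-chromosomal pairs are
compared against the genome-wide mean count at the same bin separation
(contact probability decays with genomic distance); inter-chromosomal pairs
against the global inter-chromosomal mean.  Standardization uses the
population standard deviation over *observed* cells (raw count > 0) of the
same class, intra and inter separately — the two classes live on
incomparable ratio scales.

Unobserved cells carry the sentinel Z = 0 together with ``mask = False``.
The mask, not the numeric value, is the ground truth for "no interaction":
an observed cell whose ratio happens to sit exactly at the class mean also
has Z = 0 but remains an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinnedGenome
from .contacts import ContactMatrix


@dataclass
class ZScoreMatrix:
    """Standardized observed/expected interaction strengths for one condition."""

    genome: BinnedGenome
    z: np.ndarray  # (n, n) float, 0 where mask is False
    mask: np.ndarray  # (n, n) bool, True where raw count > 0
    condition: str = ""

    def __post_init__(self) -> None:
        n = self.genome.n_bins
        if self.z.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("z / mask shape does not match genome")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("Z matrix is not symmetric")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("observed mask is not symmetric")
        if not np.all(self.z[~self.mask] == 0.0):
            raise ValueError("unobserved cells must carry the sentinel Z = 0")

    @property
    def n_observed(self) -> int:
        """Number of observed unordered bin pairs (diagonal included)."""
        m = self.mask
        return int((m.sum() + np.trace(m)) // 2)

    def intra_block(self, chrom: str) -> np.ndarray:
        s = self.genome.chrom_bins(chrom)
        return self.z[s, s]


def expected_matrix(
    contacts: ContactMatrix, mode: str = "distance"
) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts per bin pair, plus a usability flag matrix.

    Parameters
    ----------
    contacts
        Raw contact matrix.
    mode
        ``"distance"`` — intra-chromosomal expected at separation ``d`` is
        the genome-wide mean raw count over all intra bin pairs at that
        separation; inter-chromosomal expected is the mean over all inter
        bin pairs.  ``"uniform"`` — one global mean over all bin pairs.

    Returns
    -------
    (expected, usable)
        ``expected`` is real-valued; ``usable`` is False where the relevant
        contact class has zero mean (the cell cannot be normalized).
    """
    genome = contacts.genome
    counts = contacts.counts.astype(float)
    n = genome.n_bins
    if mode == "uniform":
        iu = np.triu_indices(n)
        mean = counts[iu].mean() if len(iu[0]) else 0.0
        expected = np.full((n, n), mean)
        return expected, expected > 0
    if mode != "distance":
        raise ValueError(f"unknown expected-model mode {mode!r}")

    intra = genome.intra_mask()
    expected = np.zeros((n, n))
    # distance-stratified intra expected, pooled across chromosomes
    max_nb = max(genome.bins_per_chrom)
    for d in range(max_nb):
        total = 0.0
        ncell = 0
        for chrom in genome.names:
            s = genome.chrom_bins(chrom)
            block = counts[s, s]
            if d < block.shape[0]:
                diag = np.diagonal(block, offset=d)
                total += diag.sum()
                ncell += diag.size
        if ncell == 0:
            continue
        mean_d = total / ncell
        for chrom in genome.names:
            s = genome.chrom_bins(chrom)
            nb = s.stop - s.start
            if d < nb:
                idx = np.arange(nb - d)
                expected[s.start + idx, s.start + idx + d] = mean_d
                expected[s.start + idx + d, s.start + idx] = mean_d
    # global inter expected
    inter = ~intra
    n_inter = int(inter.sum())
    if n_inter:
        expected[inter] = counts[inter].sum() / n_inter
    return expected, expected > 0


def zscore_transform(
    contacts: ContactMatrix,
    expected: np.ndarray,
    usable: np.ndarray | None = None,
) -> ZScoreMatrix:
    """Standardize observed/expected ratios into a Z-score matrix.

    Ratios ``count / expected`` are computed on observed cells only and
    standardized per class (intra vs inter) with the population SD over the
    observed cells of that class.  A class whose observed ratios have zero
    spread gets Z = 0 throughout (mask preserved).  Raises if any observed
    cell has an unusable expected value, naming the cell.
    """
    genome = contacts.genome
    counts = contacts.counts
    if usable is None:
        usable = expected > 0
    mask = counts > 0
    bad = mask & ~usable
    if bad.any():
        i, j = (int(x) for x in np.argwhere(bad)[0])
        raise ValueError(
            f"observed cell ({i}, {j}) = "
            f"({':'.join(map(str, genome.bin_location(i)))}, "
            f"{':'.join(map(str, genome.bin_location(j)))}) "
            "has no usable expected value"
        )
    ratio = np.zeros_like(counts, dtype=float)
    np.divide(counts, expected, out=ratio, where=mask)

    z = np.zeros_like(ratio)
    intra = genome.intra_mask()
    for cls in (intra, ~intra):
        obs = mask & cls
        if not obs.any():
            continue
        vals = ratio[obs]
        mu = vals.mean()
        sd = vals.std()  # population SD by design
        if sd > 0:
            z[obs] = (ratio[obs] - mu) / sd
        # sd == 0: all observed ratios identical -> Z stays 0, mask preserved
    return ZScoreMatrix(
        genome=genome, z=z, mask=mask, condition=contacts.condition
    )
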