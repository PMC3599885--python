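"""Read-pair ingestion and contact-matrix construction.

A Hi-C read pair is an unordered pair of genomic positions
(chrom1, pos1, chrom2, pos2), 1-based.  Pairs are canonically ordered
(lower chromosome index first, then lower position) so that duplicate
removal and bin assignment are orientation-independent.  PCR/optical
duplicates — pairs with identical coordinates after canonical ordering —
are collapsed to a single pair when ``dedup`` is on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedGenome

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


@dataclass
class ContactMatrix:
    """Symmetric raw contact counts over all bin pairs of one condition.

    ``counts[i, j]`` is the number of retained read pairs with one end in
    bin ``i`` and the other in bin ``j``; the matrix is symmetric and the
    diagonal holds within-bin pairs (counted once per pair).
    """

    genome: BinnedGenome
    counts: np.ndarray  # (n_bins, n_bins) int64, symmetric
    condition: str = ""

    def __post_init__(self) -> None:
        n = self.genome.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if (self.counts < 0).any():
            raise ValueError("negative contact counts")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("contact matrix is not symmetric")

    @property
    def total_pairs(self) -> int:
        """Number of retained read pairs (each unordered pair counted once)."""
        c = self.counts
        return int((c.sum() + np.trace(c)) // 2)


def canonicalize_pairs(pairs: pd.DataFrame, genome: BinnedGenome) -> pd.DataFrame:
    """Order each pair's two ends by (chromosome order, position).

    Raises on unknown chromosomes or out-of-bounds positions, naming the
    offending pair index.
    """
    df = pairs.reset_index(drop=True)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table lacks columns {missing}")
    cindex = genome.chrom_index
    for col in ("chrom1", "chrom2"):
        unknown = ~df[col].astype(str).isin(cindex)
        if unknown.any():
            i = int(np.flatnonzero(unknown)[0])
            raise ValueError(
                f"pair {i}: unknown chromosome {df[col].iloc[i]!r}"
            )
    c1 = df["chrom1"].astype(str).map(cindex).to_numpy()
    c2 = df["chrom2"].astype(str).map(cindex).to_numpy()
    p1 = df["pos1"].to_numpy(dtype=np.int64)
    p2 = df["pos2"].to_numpy(dtype=np.int64)
    lengths = np.asarray(genome.lengths, dtype=np.int64)
    for name, cc, pp in (("pos1", c1, p1), ("pos2", c2, p2)):
        bad = (pp < 1) | (pp > lengths[cc])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"pair {i}: {name}={pp[i]} outside chromosome "
                f"{genome.names[cc[i]]!r} (length {lengths[cc[i]]})"
            )
    swap = (c2 < c1) | ((c1 == c2) & (p2 < p1))
    out = pd.DataFrame(
        {
            "chrom1": np.where(swap, df["chrom2"], df["chrom1"]),
            "pos1": np.where(swap, p2, p1),
            "chrom2": np.where(swap, df["chrom1"], df["chrom2"]),
            "pos2": np.where(swap, p1, p2),
        }
    )
    return out


def build_contact_matrix(
    pairs: pd.DataFrame,
    genome: BinnedGenome,
    dedup: bool = True,
    condition: str = "",
) -> ContactMatrix:
    """Bin read pairs into a symmetric contact matrix.

    With ``dedup`` on, pairs with identical coordinates after canonical
    end-ordering count once.  Each retained pair increments exactly one
    unordered bin-pair cell (mirrored into both symmetric entries).
    """
    n = genome.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    if len(pairs) == 0:
        return ContactMatrix(genome=genome, counts=counts, condition=condition)
    canon = canonicalize_pairs(pairs, genome)
    if dedup:
        canon = canon.drop_duplicates(ignore_index=True)
    cindex = genome.chrom_index
    off = np.asarray(genome.offsets)
    w = genome.window
    c1 = canon["chrom1"].astype(str).map(cindex).to_numpy()
    c2 = canon["chrom2"].astype(str).map(cindex).to_numpy()
    b1 = off[c1] + (canon["pos1"].to_numpy(dtype=np.int64) - 1) // w
    b2 = off[c2] + (canon["pos2"].to_numpy(dtype=np.int64) - 1) // w
    # canonical ordering guarantees b1 <= b2, so accumulation stays in the
    # upper triangle (plus diagonal); mirror once at the end
    np.add.at(counts, (b1, b2), 1)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMatrix(genome=genome, counts=counts, condition=condition)
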