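"""Per-bin interaction frequency, hot/cold region calling and correlation maps.

The interaction frequency of a bin is the number of bins it has at least one
observed contact with, divided by the total number of bins in the genome —
a breadth measure, not a depth measure.  Bins whose frequency exceeds a high
threshold (e.g. >= 30%) are "hot regions"; bins below a low threshold
(e.g. <= 0.5%) are "cold regions".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedGenome
from .zscores import ZScoreMatrix


@dataclass
class FrequencyProfile:
    """Per-bin interaction frequency (fraction of all bins contacted)."""

    genome: BinnedGenome
    counts: np.ndarray  # observed partners per bin
    frequency: np.ndarray  # counts / n_bins, in [0, 1]
    condition: str = ""
    include_self: bool = False

    @property
    def percent(self) -> np.ndarray:
        return self.frequency * 100.0

    def to_frame(self) -> pd.DataFrame:
        locs = [self.genome.bin_location(i) for i in range(self.genome.n_bins)]
        return pd.DataFrame(
            {
                "chrom": [c for c, _, _ in locs],
                "start": [s for _, s, _ in locs],
                "end": [e for _, _, e in locs],
                "partners": self.counts,
                "frequency_pct": np.round(self.percent, 4),
            }
        )


@dataclass
class RegionCall:
    """A hot or cold region call for one bin."""

    bin: int
    chrom: str
    start: int
    end: int
    frequency_pct: float
    call: str  # "hot" | "cold"
    rank: int


def interaction_frequency(
    z: ZScoreMatrix, include_self: bool = False
) -> FrequencyProfile:
    """Fraction of genome bins each bin interacts with.

    Uses the observed-cell mask (an observed cell whose Z is numerically 0
    still counts).  By default the self-pair (diagonal) is excluded from the
    numerator; the denominator is always the total bin count.
    """
    mask = z.mask.copy()
    if not include_self:
        np.fill_diagonal(mask, False)
    counts = mask.sum(axis=1)
    return FrequencyProfile(
        genome=z.genome,
        counts=counts,
        frequency=counts / z.genome.n_bins,
        condition=z.condition,
        include_self=include_self,
    )


def frequency_table(
    profile: FrequencyProfile,
    thresholds: tuple[float, ...] = (1, 5, 10, 20, 30, 40, 50, 60),
) -> pd.DataFrame:
    """Number of bins at or above each percent threshold (non-increasing)."""
    thr = list(thresholds)
    if sorted(thr) != thr:
        raise ValueError("thresholds must be sorted ascending")
    pct = profile.percent
    return pd.DataFrame(
        {
            "threshold_pct": thr,
            "n_regions": [int((pct >= t).sum()) for t in thr],
        }
    )


def call_regions(
    profile: FrequencyProfile,
    hot_threshold: float = 30.0,
    cold_threshold: float = 0.5,
    top_n: int = 10,
) -> list[RegionCall]:
    """Call hot and cold regions from a frequency profile.

    Hot: frequency >= ``hot_threshold`` (percent), ranked descending,
    truncated to ``top_n``.  Cold: frequency <= ``cold_threshold``, ranked
    ascending, truncated to ``top_n``.  Ties broken by genome order.
    """
    if hot_threshold <= cold_threshold:
        raise ValueError("hot_threshold must exceed cold_threshold")
    pct = profile.percent
    calls: list[RegionCall] = []
    hot_bins = np.flatnonzero(pct >= hot_threshold)
    hot_order = hot_bins[np.lexsort((hot_bins, -pct[hot_bins]))][:top_n]
    cold_bins = np.flatnonzero(pct <= cold_threshold)
    cold_order = cold_bins[np.lexsort((cold_bins, pct[cold_bins]))][:top_n]
    for kind, order in (("hot", hot_order), ("cold", cold_order)):
        for rank, b in enumerate(order, start=1):
            chrom, start, end = profile.genome.bin_location(int(b))
            calls.append(
                RegionCall(
                    bin=int(b),
                    chrom=chrom,
                    start=start,
                    end=end,
                    frequency_pct=float(pct[b]),
                    call=kind,
                    rank=rank,
                )
            )
    return calls


def _row_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN (flagged undefined, not silently 0).
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ac @ bc.T) / np.outer(sa, sb)
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    return corr


def correlation_matrices(
    zA: ZScoreMatrix, zB: ZScoreMatrix, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within- and cross-condition row correlations of one chromosome's intra block.

    Entry (i, j) of the cross matrix is the Pearson correlation between row i
    of condition A's intra-chromosomal Z block and row j of condition B's.
    Within-matrix diagonals are 1 wherever the row has nonzero variance.
    """
    if zA.genome is not zB.genome and (
        zA.genome.names != zB.genome.names or zA.genome.lengths != zB.genome.lengths
    ):
        raise ValueError("conditions use different genomes")
    a = zA.intra_block(chrom)
    b = zB.intra_block(chrom)
    return _row_correlation(a, a), _row_correlation(b, b), _row_correlation(a, b)
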