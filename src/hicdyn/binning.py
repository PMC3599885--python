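"""Fixed-width genome binning.

The unit of analysis throughout the package is a fixed-width genomic window
("bin" or "region"), by default 1 Mb wide.  Bins tile each chromosome without
gap or overlap; the last bin of a chromosome may be shorter than the window.
All human-readable coordinates are 1-based inclusive (bin ``k`` of a
chromosome covers ``[(k-1)*W + 1, min(k*W, length)]``); BED export converts
to 0-based half-open at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class BinnedGenome:
    """A genome partitioned into fixed-width windows.

    Parameters
    ----------
    names
        Chromosome names, in input order.  Order is preserved everywhere:
        global bin index runs chromosome by chromosome, then by position.
    lengths
        Chromosome lengths in bp, parallel to ``names``.
    window
        Window (bin) width in bp.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    window: int
    # derived, filled in __post_init__
    bins_per_chrom: tuple[int, ...] = field(init=False, repr=False)
    offsets: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1 bp, got {self.window}")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.names, self.lengths):
            if length < 1:
                raise ValueError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
        nb = tuple(-(-length // self.window) for length in self.lengths)
        object.__setattr__(self, "bins_per_chrom", nb)
        object.__setattr__(
            self, "offsets", tuple(int(x) for x in np.cumsum((0,) + nb[:-1]))
        )

    # -- size -----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom)

    @property
    def n_chroms(self) -> int:
        return len(self.names)

    @property
    def chrom_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def chrom_ids(self) -> np.ndarray:
        """Per-bin chromosome index, shape ``(n_bins,)``."""
        return np.repeat(np.arange(self.n_chroms), self.bins_per_chrom)

    def intra_mask(self) -> np.ndarray:
        """Boolean ``(n_bins, n_bins)`` matrix, True where both bins share a chromosome."""
        cid = self.chrom_ids()
        return cid[:, None] == cid[None, :]

    # -- index <-> coordinates -----------------------------------------
    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of 1-based position ``pos`` on ``chrom``."""
        try:
            c = self.chrom_index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None
        if not 1 <= pos <= self.lengths[c]:
            raise ValueError(
                f"position {pos} outside chromosome {chrom!r} "
                f"(length {self.lengths[c]})"
            )
        return self.offsets[c] + (pos - 1) // self.window

    def bin_location(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index, 1-based inclusive."""
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} out of range")
        c = int(np.searchsorted(self.offsets, index, side="right")) - 1
        k = index - self.offsets[c]
        start = k * self.window + 1
        end = min((k + 1) * self.window, self.lengths[c])
        return self.names[c], start, end

    def bin_labels(self) -> list[str]:
        """Labels of the form ``chrom:start-end`` for every bin."""
        return [
            f"{chrom}:{start}-{end}"
            for chrom, start, end in (self.bin_location(i) for i in range(self.n_bins))
        ]

    def chrom_bins(self, chrom: str) -> slice:
        """Slice of global bin indices belonging to ``chrom``."""
        if chrom not in self.chrom_index:
            raise KeyError(f"unknown chromosome {chrom!r}")
        c = self.chrom_index[chrom]
        return slice(self.offsets[c], self.offsets[c] + self.bins_per_chrom[c])


def bin_genome(
    chrom_sizes: Iterable[tuple[str, int]] | Sequence[tuple[str, int]],
    window: int = 1_000_000,
) -> BinnedGenome:
    """Tile a genome into fixed-width windows.

    ``chrom_sizes`` is an ordered iterable of (name, length-in-bp) records,
    e.g. the rows of a ``chrom.sizes`` file.  Each chromosome contributes
    ``ceil(length / window)`` bins.
    """
    records = list(chrom_sizes)
    if not records:
        raise ValueError("empty chromosome list")
    names = tuple(str(name) for name, _ in records)
    lengths = tuple(int(length) for _, length in records)
    return BinnedGenome(names=names, lengths=lengths, window=int(window))
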