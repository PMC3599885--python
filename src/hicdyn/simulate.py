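"""Synthetic two-condition Hi-C experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes:
distance-decaying intra-chromosomal contacts (truncated power law on bin
separation), sparse uniform inter-chromosomal background, a small set of
"hot" bins whose trans-contact rate is boosted, condition-specific planted
gain/loss bin pairs, negative-binomial epigenomic track counts with planted
condition shifts, peak sets coupled to interaction frequency, break-point
lists enriched in hot bins, and near-identical cross-condition expression.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs.  Background contacts are never placed on planted
cells, so a planted gain cell is observed *only* in the treated condition
and a planted loss cell only in the control condition — the planted ground
truth saturates the relative ratio at exactly +/-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .binning import BinnedGenome, bin_genome
from .integration import GENE_PARTS, GeneModel

CONDITIONS = ("T0", "T1")

#: Condition shift (log2 units, treated vs control) per epigenomic mark.
#: Active-chromatin marks and H3K27me3 rise on estrogen stimulation, the
#: repressive H3K9me3 and Pol-II occupancy fall, H3K4me1 and FAIRE are flat.
DEFAULT_MARK_EFFECTS: dict[str, float] = {
    "H3K4me1": 0.0,
    "H3K4me3": 0.5,
    "H3K9me3": -0.5,
    "H3K27me3": 0.5,
    "H3K9ac": 0.5,
    "H3K14ac": 0.5,
    "PolII": -0.5,
    "FAIRE": 0.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults describe a compact genome (4 x 50 Mb chromosomes, 1 Mb bins,
    200 bins) deep enough that planted signals are recoverable at desk
    scale; see docs/methods.md for the reasoning behind each value.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 50_000_000),
        ("chr2", 50_000_000),
        ("chr3", 50_000_000),
        ("chr4", 50_000_000),
    )
    window: int = 1_000_000
    depth: int = 60_000  # read pairs per condition (before planting)
    alpha: float = 1.0  # intra contact decay exponent, P(d) ~ (d+1)^-alpha
    max_separation: int = 20  # truncation of the decay law, in bins
    inter_rate: float = 0.02  # background pairs per inter-chromosomal bin pair
    n_hot: int = 10
    hot_boost: float = 20.0  # trans-contact rate multiplier of hot bins
    hot_bins: tuple[int, ...] | None = None  # explicit override
    n_gain: int = 20  # planted treated-specific cells (half intra, half inter)
    n_loss: int = 20  # planted control-specific cells
    planted_strength: int = 60  # read pairs per planted cell
    min_planted_separation: int = 5  # bins, intra planted cells
    # epigenomic tracks
    mark_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARK_EFFECTS)
    )
    body_mean: float = 50.0  # baseline reads per gene body
    flank_mean: float = 15.0  # baseline reads per 5 kb flank
    gene_propensity_sd: float = 0.3  # log-normal sigma, shared across conditions
    nb_dispersion: float = 10.0  # NB size parameter; -> Poisson as it grows
    # annotations
    n_genes: int = 1000
    gene_length_median: int = 20_000
    gene_length_sigma: float = 0.8
    gene_length_range: tuple[int, int] = (2_000, 200_000)
    base_peak_rate: float = 80.0  # peaks per bin at zero coupling
    peak_coupling: float = 8.0  # strength of peak-frequency association
    n_breakpoints: int = 314
    breakpoint_hot_prob: float = 0.22
    expr_signal_sd: float = 1.0
    expr_noise_sd: float = 0.1

    def genome(self) -> BinnedGenome:
        return bin_genome(self.chrom_lengths, self.window)


@dataclass
class SimulationTruth:
    """Planted ground truth of one simulated experiment."""

    genome: BinnedGenome
    hot_bins: np.ndarray  # global bin indices
    gain_cells: list[tuple[int, int]]  # observed only in T1
    loss_cells: list[tuple[int, int]]  # observed only in T0

    def cells_of_type(self, call_type: str) -> list[tuple[int, int]]:
        kind, span = call_type.split("-")
        cells = self.gain_cells if kind == "gain" else self.loss_cells
        cid = self.genome.chrom_ids()
        want_intra = span == "intra"
        return [(i, j) for i, j in cells if (cid[i] == cid[j]) == want_intra]


def _seed_seq(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), *stream])


def ground_truth(config: SimulationConfig, seed: int) -> SimulationTruth:
    """Hot bins and planted gain/loss cells for (config, seed).

    Hot bins default to ``n_hot`` evenly spaced bins; planted cells are
    drawn from a dedicated random stream so the two conditions and the
    ground truth always agree.
    """
    genome = config.genome()
    n = genome.n_bins
    if config.hot_bins is not None:
        hot = np.asarray(sorted(config.hot_bins), dtype=int)
    elif config.n_hot > 0:
        # interior positions, spread round-robin over chromosomes: edge bins
        # have one-sided intra neighborhoods and systematically lower
        # interaction frequency, so they make poor hotspot prototypes
        per_chrom = [
            config.n_hot // genome.n_chroms + (c < config.n_hot % genome.n_chroms)
            for c in range(genome.n_chroms)
        ]
        picks = []
        for c, k in enumerate(per_chrom):
            nb = genome.bins_per_chrom[c]
            for j in range(k):
                picks.append(genome.offsets[c] + round((j + 1) / (k + 1) * (nb - 1)))
        hot = np.unique(np.asarray(picks, dtype=int))
    else:
        hot = np.array([], dtype=int)
    hot_set = set(int(b) for b in hot)

    rng = _seed_seq(seed, 701)
    cid = genome.chrom_ids()
    used: set[tuple[int, int]] = set()

    def draw_intra() -> tuple[int, int]:
        for _ in range(10_000):
            c = rng.integers(genome.n_chroms)
            nb = genome.bins_per_chrom[c]
            dmax = min(config.max_separation, nb - 1)
            if dmax < config.min_planted_separation:
                continue
            d = int(rng.integers(config.min_planted_separation, dmax + 1))
            i = genome.offsets[c] + int(rng.integers(nb - d))
            cell = (i, i + d)
            if cell in used or cell[0] in hot_set or cell[1] in hot_set:
                continue
            return cell
        raise RuntimeError("could not place planted intra cell")

    def draw_inter() -> tuple[int, int]:
        for _ in range(10_000):
            i, j = (int(x) for x in rng.integers(n, size=2))
            if cid[i] == cid[j]:
                continue
            cell = (min(i, j), max(i, j))
            if cell in used or i in hot_set or j in hot_set:
                continue
            return cell
        raise RuntimeError("could not place planted inter cell")

    def draw_cells(total: int) -> list[tuple[int, int]]:
        cells = []
        for k in range(total):
            cell = draw_intra() if k < total // 2 else draw_inter()
            used.add(cell)
            cells.append(cell)
        return cells

    return SimulationTruth(
        genome=genome,
        hot_bins=hot,
        gain_cells=draw_cells(config.n_gain),
        loss_cells=draw_cells(config.n_loss),
    )


def _background_rates(
    config: SimulationConfig, truth: SimulationTruth
) -> np.ndarray:
    """Upper-triangular expected background pair counts per cell."""
    genome = truth.genome
    n = genome.n_bins
    w = np.ones(n)
    w[truth.hot_bins] = config.hot_boost
    intra = genome.intra_mask()
    lam = np.zeros((n, n))
    # inter background, boosted at hot endpoints
    lam[~intra] = config.inter_rate * np.outer(w, w)[~intra]
    lam = np.triu(lam)
    # intra decay; remaining depth split across chromosomes by length
    inter_budget = lam.sum()
    intra_budget = max(config.depth - inter_budget, 0.0)
    total_len = sum(genome.lengths)
    for c, chrom in enumerate(genome.names):
        s = genome.chrom_bins(chrom)
        nb = genome.bins_per_chrom[c]
        dmax = min(config.max_separation, nb - 1)
        d = np.arange(dmax + 1)
        p = (d + 1.0) ** (-config.alpha)
        p /= p.sum()
        budget_c = intra_budget * genome.lengths[c] / total_len
        for dd in d:
            cells = nb - dd
            idx = np.arange(cells)
            lam[s.start + idx, s.start + idx + dd] = budget_c * p[dd] / cells
    # background never lands on planted cells
    for i, j in truth.gain_cells + truth.loss_cells:
        lam[i, j] = 0.0
    return lam


def _cells_to_pairs(
    genome: BinnedGenome, counts: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Expand per-cell pair counts into read pairs uniform within their bins."""
    iu, ju = np.nonzero(counts)
    reps = counts[iu, ju]
    b1 = np.repeat(iu, reps)
    b2 = np.repeat(ju, reps)
    if len(b1) == 0:
        return pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    locs = [genome.bin_location(i) for i in range(genome.n_bins)]
    chrom = np.array([c for c, _, _ in locs])
    start = np.array([s for _, s, _ in locs], dtype=np.int64)
    width = np.array([e - s + 1 for _, s, e in locs], dtype=np.int64)
    pos1 = start[b1] + rng.integers(0, width[b1])
    pos2 = start[b2] + rng.integers(0, width[b2])
    df = pd.DataFrame(
        {"chrom1": chrom[b1], "pos1": pos1, "chrom2": chrom[b2], "pos2": pos2}
    )
    return df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))).reset_index(drop=True)


def simulate_pairs(
    config: SimulationConfig, condition: str, seed: int
) -> pd.DataFrame:
    """Read pairs for one condition: background plus condition-specific plants.

    Background cell counts are Poisson around the decay/boost rate model;
    planted gain cells receive exactly ``planted_strength`` pairs in T1 only
    and loss cells in T0 only.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    truth = ground_truth(config, seed)
    rng = _seed_seq(seed, CONDITIONS.index(condition), 11)
    lam = _background_rates(config, truth)
    counts = rng.poisson(lam)
    planted = truth.gain_cells if condition == "T1" else truth.loss_cells
    for i, j in planted:
        counts[i, j] += config.planted_strength
    return _cells_to_pairs(truth.genome, counts, rng)


def simulate_tracks(
    config: SimulationConfig,
    genes: list[GeneModel],
    condition: str,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Per-gene-part read counts for every epigenomic mark, one condition.

    Counts are negative-binomial around a per-gene baseline (log-normal
    gene propensity shared between conditions); in the treated condition
    the log2 mean of genes lying in planted differential bins shifts by the
    mark's configured effect.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    truth = ground_truth(config, seed)
    genome = truth.genome
    affected_bins = {
        b for i, j in truth.gain_cells + truth.loss_cells for b in (i, j)
    }
    names = [g.name for g in genes]
    tss_bins = np.array([genome.bin_index(g.chrom, g.tss) for g in genes])
    affected = np.array([b in affected_bins for b in tss_bins])

    propensity = _seed_seq(seed, 21).lognormal(
        mean=0.0, sigma=config.gene_propensity_sd, size=len(genes)
    )
    size = config.nb_dispersion
    out: dict[str, pd.DataFrame] = {}
    for m, (mark, effect) in enumerate(sorted(config.mark_effects.items())):
        rng = _seed_seq(seed, CONDITIONS.index(condition), 31, m)
        cols = {}
        for part in GENE_PARTS:
            base = config.body_mean if part == "body" else config.flank_mean
            mean = base * propensity
            if condition == "T1":
                mean = mean * np.where(affected, 2.0**effect, 1.0)
            p = size / (size + mean)
            cols[part] = rng.negative_binomial(size, p)
        out[mark] = pd.DataFrame(cols, index=pd.Index(names, name="gene"))
    return out


@dataclass
class Annotations:
    """Synthetic gene models, peak/break-point intervals and expression."""

    genes: list[GeneModel]
    peaks: pd.DataFrame  # chrom, start, end (1-based inclusive)
    breakpoints: pd.DataFrame  # chrom, pos
    expression: pd.DataFrame  # index gene, columns T0 / T1


def simulate_annotations(
    config: SimulationConfig,
    seed: int,
    frequency: np.ndarray | None = None,
) -> Annotations:
    """Genes, ER-binding-style peaks, break-points and expression tables.

    ``frequency`` (per-bin fraction, e.g. a measured interaction-frequency
    profile) drives the peak-density coupling; when omitted, the hot-bin
    trans-weight profile stands in for it.  Break-points land in hot bins
    with probability ``breakpoint_hot_prob`` and uniformly elsewhere.
    """
    truth = ground_truth(config, seed)
    genome = truth.genome
    n = genome.n_bins
    rng = _seed_seq(seed, 41)
    lengths = np.asarray(genome.lengths, dtype=np.int64)

    # genes: uniform starts, log-normal lengths, random strands
    c = rng.integers(genome.n_chroms, size=config.n_genes)
    glen = np.clip(
        rng.lognormal(np.log(config.gene_length_median), config.gene_length_sigma,
                      size=config.n_genes),
        *config.gene_length_range,
    ).astype(np.int64)
    glen = np.minimum(glen, lengths[c] - 1)
    start = rng.integers(1, lengths[c] - glen + 1)
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    width = int(np.ceil(np.log10(config.n_genes + 1)))
    genes = [
        GeneModel(
            name=f"g{k:0{width}d}",
            chrom=genome.names[c[k]],
            start=int(start[k]),
            end=int(start[k] + glen[k]),
            strand=str(strand[k]),
        )
        for k in range(config.n_genes)
    ]

    # peaks coupled to the (supplied or proxy) frequency profile
    if frequency is None:
        proxy = np.ones(n)
        proxy[truth.hot_bins] = config.hot_boost
    else:
        proxy = np.asarray(frequency, dtype=float)
    norm = proxy / proxy.mean() if proxy.mean() > 0 else proxy
    rate = config.base_peak_rate * (1.0 + config.peak_coupling * norm)
    per_bin = rng.poisson(rate)
    bins = np.repeat(np.arange(n), per_bin)
    locs = [genome.bin_location(i) for i in range(n)]
    bstart = np.array([s for _, s, _ in locs], dtype=np.int64)
    bwidth = np.array([e - s + 1 for _, s, e in locs], dtype=np.int64)
    centers = bstart[bins] + rng.integers(0, np.maximum(bwidth[bins] - 200, 1))
    peaks = pd.DataFrame(
        {
            "chrom": np.array([c for c, _, _ in locs])[bins],
            "start": centers,
            "end": centers + 199,
        }
    )

    # break-points enriched in hot bins
    k = config.n_breakpoints
    in_hot = rng.random(k) < config.breakpoint_hot_prob
    uniform_bins = rng.integers(n, size=k)
    if len(truth.hot_bins):
        hot_draw = truth.hot_bins[rng.integers(len(truth.hot_bins), size=k)]
        bp_bins = np.where(in_hot, hot_draw, uniform_bins)
    else:
        bp_bins = uniform_bins
    bp_pos = bstart[bp_bins] + rng.integers(0, bwidth[bp_bins])
    breakpoints = pd.DataFrame(
        {"chrom": np.array([c for c, _, _ in locs])[bp_bins], "pos": bp_pos}
    )

    # near-identical expression across conditions
    signal = rng.normal(8.0, config.expr_signal_sd, size=config.n_genes)
    expression = pd.DataFrame(
        {
            "T0": signal + rng.normal(0, config.expr_noise_sd, config.n_genes),
            "T1": signal + rng.normal(0, config.expr_noise_sd, config.n_genes),
        },
        index=pd.Index([g.name for g in genes], name="gene"),
    )
    return Annotations(
        genes=genes, peaks=peaks, breakpoints=breakpoints, expression=expression
    )


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``config`` with all planted effects removed (fully null)."""
    base = config or SimulationConfig()
    return replace(
        base,
        mark_effects={m: 0.0 for m in base.mark_effects},
    )
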