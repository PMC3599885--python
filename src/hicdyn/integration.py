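"""Joint analysis of interaction calls with epigenomic and genomic annotations.

Covers: strand-aware partition of genes into 5 kb upstream / gene body /
5 kb downstream anchored at the 5' TSS; per-bin summaries of log read
counts over gene parts; condition-contrast enrichment tests (paired t or
Mann-Whitney U) of epigenomic marks over genes in the four differential
interaction classes; peak-density vs interaction-frequency rank
association; break-point enrichment in hot regions; expression correlation
across conditions; and differential-expression enrichment by chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .binning import BinnedGenome
from .frequency import FrequencyProfile, RegionCall

GENE_PARTS = ("upstream", "body", "downstream")


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand; the 5' TSS anchors the regulatory partition."""

    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GenePartition:
    """Strand-aware (upstream, body, downstream) intervals of one gene.

    Intervals are (start, end) 1-based inclusive, or None when clipping at
    the chromosome edge leaves them empty.
    """

    gene: GeneModel
    upstream: tuple[int, int] | None
    body: tuple[int, int] | None
    downstream: tuple[int, int] | None

    def interval(self, part: str) -> tuple[int, int] | None:
        if part not in GENE_PARTS:
            raise ValueError(f"unknown gene part {part!r}")
        return getattr(self, part)


def partition_gene(
    gene: GeneModel, flank: int = 5000, chrom_length: int | None = None
) -> GenePartition:
    """Split a gene into 5' flank, body, and TSS-anchored downstream flank.

    Both flanks are anchored at the 5' TSS: upstream covers the ``flank`` bp
    5' of the TSS, downstream the first ``flank`` bp from the TSS into the
    gene (mirrored on the minus strand).  Intervals are clipped to
    [1, chrom_length].
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    tss = gene.tss
    if gene.strand == "+":
        upstream = (tss - flank, tss - 1)
        downstream = (tss, tss + flank - 1)
    else:
        upstream = (tss + 1, tss + flank)
        downstream = (tss - flank + 1, tss)
    body = (gene.start, gene.end)

    def clip(iv: tuple[int, int]) -> tuple[int, int] | None:
        lo = max(iv[0], 1)
        hi = iv[1] if chrom_length is None else min(iv[1], chrom_length)
        return (lo, hi) if lo <= hi else None

    return GenePartition(
        gene=gene, upstream=clip(upstream), body=clip(body), downstream=clip(downstream)
    )


@dataclass
class SignalSummary:
    """Per-bin mean log read counts of one (mark, condition, gene part).

    ``bin_values`` holds NaN for excluded bins (bins containing no gene
    TSS); ``gene_values`` are the per-gene log-transformed counts the bin
    means were taken over, so gene-level tests need no re-aggregation.
    """

    mark: str
    condition: str
    part: str
    bin_values: np.ndarray  # (n_bins,), NaN where excluded
    excluded_bins: np.ndarray  # (n_bins,) bool
    gene_values: pd.Series  # index: gene name, value: log(count + pc)
    log_base: float = 2.0
    pseudocount: float = 1.0


def gene_bins(genes: Sequence[GeneModel], genome: BinnedGenome) -> pd.Series:
    """Bin index of each gene, assigned by TSS location."""
    return pd.Series(
        {g.name: genome.bin_index(g.chrom, g.tss) for g in genes}, dtype=int
    )


def count_reads_in_parts(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    part: str,
    flank: int = 5000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.Series:
    """Reads per gene part, a read assigned to the interval containing its midpoint.

    ``reads`` has 1-based inclusive columns (chrom, start, end).
    """
    mids: dict[str, np.ndarray] = {}
    for chrom, grp in reads.groupby("chrom", sort=False):
        m = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        mids[str(chrom)] = np.sort(m)
    counts = {}
    for g in genes:
        cl = None if chrom_lengths is None else chrom_lengths.get(g.chrom)
        iv = partition_gene(g, flank=flank, chrom_length=cl).interval(part)
        if iv is None or g.chrom not in mids:
            counts[g.name] = 0
            continue
        m = mids[g.chrom]
        counts[g.name] = int(
            np.searchsorted(m, iv[1], side="right") - np.searchsorted(m, iv[0], side="left")
        )
    return pd.Series(counts, dtype=int)


def summarize_gene_counts(
    counts: pd.Series,
    genes: Sequence[GeneModel],
    genome: BinnedGenome,
    mark: str = "",
    condition: str = "",
    part: str = "body",
    log_base: float = 2.0,
    pseudocount: float = 1.0,
) -> SignalSummary:
    """Log-transform per-gene counts and average them per bin (by TSS bin).

    Bins containing no gene are excluded (NaN), mirroring the exclusion of
    gene-free windows from the epigenomic analysis.
    """
    logs = np.log(counts.astype(float) + pseudocount) / np.log(log_base)
    bins = gene_bins(genes, genome).reindex(logs.index)
    means = logs.groupby(bins).mean()
    bin_values = np.full(genome.n_bins, np.nan)
    bin_values[means.index.to_numpy(dtype=int)] = means.to_numpy()
    excluded = np.isnan(bin_values)
    return SignalSummary(
        mark=mark,
        condition=condition,
        part=part,
        bin_values=bin_values,
        excluded_bins=excluded,
        gene_values=logs,
        log_base=log_base,
        pseudocount=pseudocount,
    )


def aggregate_signal(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: BinnedGenome,
    part: str,
    mark: str = "",
    condition: str = "",
    flank: int = 5000,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
) -> SignalSummary:
    """Aggregate aligned-read intervals into a per-bin log-count summary."""
    chrom_lengths = dict(zip(genome.names, genome.lengths))
    counts = count_reads_in_parts(
        reads, genes, part, flank=flank, chrom_lengths=chrom_lengths
    )
    return summarize_gene_counts(
        counts, genes, genome, mark=mark, condition=condition, part=part,
        log_base=log_base, pseudocount=pseudocount,
    )


@dataclass
class EnrichmentResult:
    """Condition contrast of one mark/part over one interaction-type gene set."""

    mark: str
    part: str
    interaction_type: str
    statistic: float
    pvalue: float
    direction: int  # sign of (treated mean - control mean)
    n_genes: int
    test: str = "t"
    undefined: bool = False
    qvalue: float = field(default=np.nan)


def enrichment_test(
    summary_t1: SignalSummary,
    summary_t0: SignalSummary,
    gene_sets: Mapping[str, Iterable[str]],
    test: str = "t",
) -> list[EnrichmentResult]:
    """Treated-vs-control contrast of a mark over interaction-type gene sets.

    For each gene set the per-gene log counts of the two conditions are
    compared with a paired t-test (statistic sign positive iff the treated
    mean exceeds the control mean) or a two-sided Mann-Whitney U test.
    Sets with fewer than two genes present in both summaries are flagged
    undefined.
    """
    if test not in ("t", "mann-whitney"):
        raise ValueError(f"unknown test {test!r}")
    results = []
    for itype, names in gene_sets.items():
        names = pd.Index(sorted(set(names)))
        shared = names.intersection(summary_t1.gene_values.index).intersection(
            summary_t0.gene_values.index
        )
        x1 = summary_t1.gene_values.loc[shared].to_numpy(dtype=float)
        x0 = summary_t0.gene_values.loc[shared].to_numpy(dtype=float)
        base = dict(
            mark=summary_t1.mark,
            part=summary_t1.part,
            interaction_type=itype,
            n_genes=len(shared),
            test=test,
        )
        if len(shared) < 2:
            results.append(
                EnrichmentResult(
                    statistic=np.nan, pvalue=np.nan, direction=0,
                    undefined=True, **base,
                )
            )
            continue
        diff = x1 - x0
        direction = int(np.sign(diff.mean()))
        if test == "t":
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_rel(x1, x0)
        else:
            stat, p = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        results.append(
            EnrichmentResult(
                statistic=float(stat), pvalue=float(p), direction=direction, **base,
            )
        )
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results and attach Benjamini-Hochberg q-values."""
    df = pd.DataFrame(
        [
            {
                "mark": r.mark, "part": r.part, "type": r.interaction_type,
                "statistic": r.statistic, "pvalue": r.pvalue,
                "direction": r.direction, "n_genes": r.n_genes,
                "test": r.test, "undefined": r.undefined,
            }
            for r in results
        ]
    )
    df["qvalue"] = np.nan
    ok = df["pvalue"].notna()
    if ok.any():
        df.loc[ok, "qvalue"] = multipletests(df.loc[ok, "pvalue"], method="fdr_bh")[1]
    return df


def peaks_per_bin(peaks: pd.DataFrame, genome: BinnedGenome) -> np.ndarray:
    """Peak count per bin; a peak belongs to the bin containing its midpoint."""
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    if len(peaks) == 0:
        return counts
    cindex = genome.chrom_index
    off = np.asarray(genome.offsets)
    chrom = peaks["chrom"].astype(str)
    unknown = ~chrom.isin(cindex)
    if unknown.any():
        raise ValueError(f"unknown chromosome {chrom[unknown].iloc[0]!r} in peaks")
    mid = (peaks["start"].to_numpy(dtype=np.int64) + peaks["end"].to_numpy(dtype=np.int64)) // 2
    c = chrom.map(cindex).to_numpy()
    b = off[c] + np.clip(mid - 1, 0, None) // genome.window
    np.add.at(counts, b, 1)
    return counts


def rank_association(
    counts: np.ndarray, profile: FrequencyProfile
) -> tuple[float, float]:
    """Spearman correlation between per-bin peak counts and interaction frequency.

    Returns (rho, p); (nan, nan) when undefined (no peaks, or a constant
    input).
    """
    counts = np.asarray(counts, dtype=float)
    freq = profile.frequency
    if counts.sum() == 0 or np.ptp(counts) == 0 or np.ptp(freq) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(counts, freq)
    return float(rho), float(p)


@dataclass
class OverlapResult:
    """Break-point overlap with hot regions and its enrichment tail probability."""

    overlap: int
    n_breakpoints: int
    n_hot_bins: int
    n_bins: int
    pvalue: float
    log10_pvalue: float
    method: str = "binomial"


def binomial_tail_log10(k: int, n: int, p: float) -> float:
    """log10 of the upper binomial tail P(X >= k), by exact log-space summation."""
    if k <= 0:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(logsumexp(stats.binom.logpmf(ks, n, p)) / math.log(10))


def breakpoint_overlap(
    breakpoints: pd.DataFrame,
    hot_bins: Sequence[RegionCall] | Sequence[int],
    genome: BinnedGenome,
    method: str = "binomial",
) -> OverlapResult:
    """Count break-points inside hot regions and test enrichment.

    ``breakpoints`` has columns (chrom, pos), 1-based.  Under the uniform
    null a break-point lands in a hot bin with probability
    ``n_hot / n_bins``; the default test is the exact upper binomial tail
    computed in log space (a hypergeometric tail over bins is available with
    ``method="hypergeometric"``).
    """
    hot = {
        c.bin if isinstance(c, RegionCall) else int(c)
        for c in hot_bins
        if not isinstance(c, RegionCall) or c.call == "hot"
    }
    if not hot:
        raise ValueError("empty hot-region set: enrichment undefined")
    n = len(breakpoints)
    k = 0
    for _, row in breakpoints.iterrows():
        if genome.bin_index(str(row["chrom"]), int(row["pos"])) in hot:
            k += 1
    p0 = len(hot) / genome.n_bins
    if method == "binomial":
        log10p = binomial_tail_log10(k, n, p0)
    elif method == "hypergeometric":
        log10p = float(
            stats.hypergeom.logsf(k - 1, genome.n_bins, len(hot), n) / math.log(10)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapResult(
        overlap=k,
        n_breakpoints=n,
        n_hot_bins=len(hot),
        n_bins=genome.n_bins,
        pvalue=float(10.0**log10p),
        log10_pvalue=log10p,
        method=method,
    )


def expression_correlation(
    expr_t0: pd.Series, expr_t1: pd.Series, gene_set: Iterable[str] | None = None
) -> tuple[float, int]:
    """Pearson correlation of expression between conditions over shared genes.

    Returns (r, n); r is NaN when variance is zero.  Requires at least 3
    shared genes.
    """
    shared = expr_t0.index.intersection(expr_t1.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index(set(gene_set)))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = expr_t0.loc[shared].to_numpy(dtype=float)
    y = expr_t1.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), len(shared))
    r, _ = stats.pearsonr(x, y)
    return float(r), len(shared)


@dataclass
class ChiSquareResult:
    """2x2 DE-vs-region chi-square contrast."""

    statistic: float
    pvalue: float
    table: np.ndarray  # rows: in-region / outside; cols: DE / not DE
    warning: str | None = None


def de_enrichment_chisq(
    de_genes: Iterable[str],
    region_genes: Iterable[str],
    all_genes: Iterable[str],
    correction: bool = False,
) -> ChiSquareResult:
    """Chi-square test: are genes in a region class enriched for DE genes?

    Builds the 2x2 contingency (in-region vs not) x (DE vs not) over
    ``all_genes``; continuity correction off by default.  Expected cells
    below 1 produce a recorded warning, not an error.
    """
    universe = set(all_genes)
    de = set(de_genes) & universe
    region = set(region_genes)
    if not region <= universe:
        raise ValueError("region_genes must be a subset of all_genes")
    a = len(region & de)
    b = len(region - de)
    c = len(de - region)
    d = len(universe - region - de)
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChiSquareResult(
            statistic=0.0, pvalue=1.0, table=table,
            warning="degenerate margin; statistic undefined, reported as 0",
        )
    stat, p, _, exp = stats.chi2_contingency(table, correction=correction)
    warning = None
    if (exp < 1).any():
        warning = "expected cell count below 1; chi-square approximation unreliable"
    return ChiSquareResult(statistic=float(stat), pvalue=float(p), table=table, warning=warning)
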