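"""Readers and writers for the pipeline's text formats.

Conventions: every exported *interval* file uses BED conventions (0-based,
half-open); every human-readable *table* uses 1-based inclusive coordinates.
The conversion between the two lives here and only here.  Percentages are
printed with 4 decimals, relative ratios with 2.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinnedGenome, bin_genome
from .contacts import PAIR_COLUMNS
from .differential import DifferentialCall, calls_to_frame
from .frequency import FrequencyProfile, RegionCall
from .integration import GeneModel
from .zscores import ZScoreMatrix


class FormatError(ValueError):
    """A malformed input file; the message names file and line."""


# -- chrom.sizes -------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Two-column whitespace-delimited (name, length) text."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'name length', got {line!r}")
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{ln}: length {parts[1]!r} is not an integer"
                ) from None
            out.append((parts[0], length))
    if not out:
        raise FormatError(f"{path}: no chromosome records")
    return out


def write_chrom_sizes(records: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in records:
            fh.write(f"{name}\t{length}\n")


# -- read pairs (minimal BEDPE: chrom1 pos1 chrom2 pos2, 1-based) ------


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Minimal BEDPE-like pair TSV; optional header; gzip allowed."""
    opener = gzip.open if str(path).endswith(".gz") else open
    rows = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[:1] == ["chrom1"]:
                continue  # header
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{ln}: expected 4 tab-separated fields, got {len(parts)}"
                )
            try:
                rows.append((parts[0], int(parts[1]), parts[2], int(parts[3])))
            except ValueError:
                raise FormatError(
                    f"{path}:{ln}: non-integer position in {line!r}"
                ) from None
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs(pairs: pd.DataFrame, path: str | Path, header: bool = True) -> None:
    pairs.to_csv(path, sep="\t", index=False, header=header, columns=PAIR_COLUMNS)


# -- dense matrices ----------------------------------------------------


def write_matrix(
    matrix: np.ndarray, genome: BinnedGenome, path: str | Path, float_fmt: str = "%.17g"
) -> None:
    """Dense TSV with ``chrom:start-end`` bin labels on both axes."""
    labels = genome.bin_labels()
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=float_fmt, index_label="bin")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels disagree")
    return df.to_numpy(), list(df.index)


def save_zscores(z: ZScoreMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.z.tsv`` and ``<prefix>.mask.tsv`` (the observed mask
    disambiguates a genuine Z = 0 from the unobserved sentinel)."""
    prefix = str(prefix)
    write_matrix(z.z, z.genome, prefix + ".z.tsv")
    write_matrix(z.mask.astype(int), z.genome, prefix + ".mask.tsv", float_fmt="%d")


def load_zscores(
    prefix: str | Path, genome: BinnedGenome, condition: str = ""
) -> ZScoreMatrix:
    prefix = str(prefix)
    zmat, labels = read_matrix(prefix + ".z.tsv")
    mask, _ = read_matrix(prefix + ".mask.tsv")
    if labels != genome.bin_labels():
        raise FormatError(f"{prefix}.z.tsv: bin labels do not match the genome")
    return ZScoreMatrix(
        genome=genome, z=zmat, mask=mask.astype(bool), condition=condition
    )


def save_matrix_npz(
    path: str | Path, genome: BinnedGenome, **arrays: np.ndarray
) -> None:
    """Binary container (numpy .npz) for matrices; lossless and compact."""
    np.savez_compressed(
        path,
        names=np.array(genome.names),
        lengths=np.array(genome.lengths),
        window=np.array(genome.window),
        **arrays,
    )


def load_matrix_npz(path: str | Path) -> tuple[BinnedGenome, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as data:
        genome = bin_genome(
            list(zip(data["names"].tolist(), data["lengths"].tolist())),
            int(data["window"]),
        )
        arrays = {
            k: data[k] for k in data.files if k not in ("names", "lengths", "window")
        }
    return genome, arrays


# -- BED boundary conversions -----------------------------------------


def intervals_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive (chrom, start, end) -> BED 0-based half-open."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def bed_to_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """BED 0-based half-open -> 1-based inclusive."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ file -> 1-based inclusive intervals (extra columns preserved)."""
    rows = []
    extra = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 fields")
            try:
                rows.append([parts[0], int(parts[1]), int(parts[2]), *parts[3:]])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from None
            extra = max(extra, len(parts) - 3)
    cols = ["chrom", "start", "end"] + [f"col{i+4}" for i in range(extra)]
    df = pd.DataFrame([r + [None] * (len(cols) - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return bed_to_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    intervals_to_bed(df).to_csv(path, sep="\t", index=False, header=False)


# -- region calls ------------------------------------------------------


def region_calls_to_frame(calls: Sequence[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "call": [c.call for c in calls],
            "rank": [c.rank for c in calls],
            "frequency_pct": [round(c.frequency_pct, 4) for c in calls],
        }
    )


def write_region_calls(
    calls: Sequence[RegionCall], table_path: str | Path, bed_path: str | Path | None = None
) -> None:
    df = region_calls_to_frame(calls)
    df.to_csv(table_path, sep="\t", index=False, float_format="%.4f")
    if bed_path is not None:
        bed = df[["chrom", "start", "end"]].copy()
        bed["name"] = df["call"] + "." + df["rank"].astype(str)
        write_bed(bed, bed_path)


# -- differential calls ------------------------------------------------


def write_calls_bedpe(
    calls: Sequence[DifferentialCall], genome: BinnedGenome, path: str | Path
) -> None:
    """BEDPE export (both anchors 0-based half-open) of differential calls."""
    df = calls_to_frame(list(calls), genome)
    df["start1"] -= 1
    df["start2"] -= 1
    df["z_control"] = df["z_control"].round(6)
    df["z_treated"] = df["z_treated"].round(6)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.2f")


# -- genes / expression ------------------------------------------------

GENE_COLUMNS = ["chrom", "start", "end", "strand", "name"]


def read_genes(path: str | Path) -> list[GeneModel]:
    """Tabular gene models (chrom, start, end, strand, name), 1-based."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene columns {missing}")
    return [
        GeneModel(
            name=str(r["name"]), chrom=str(r["chrom"]), start=int(r["start"]),
            end=int(r["end"]), strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "name": [g.name for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x condition TSV, first column the gene name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression table has no condition columns")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# -- track counts (long format: mark, gene, upstream, body, downstream) -


def write_tracks(tracks: dict[str, pd.DataFrame], path: str | Path) -> None:
    long = pd.concat(
        [df.assign(mark=mark).reset_index() for mark, df in sorted(tracks.items())],
        ignore_index=True,
    )
    long[["mark", "gene", "upstream", "body", "downstream"]].to_csv(
        path, sep="\t", index=False
    )


def read_tracks(path: str | Path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    need = {"mark", "gene", "upstream", "body", "downstream"}
    if not need <= set(long.columns):
        raise FormatError(f"{path}: missing track columns {sorted(need - set(long.columns))}")
    return {
        str(mark): grp.set_index("gene")[["upstream", "body", "downstream"]]
        for mark, grp in long.groupby("mark")
    }


# -- frequency profile -------------------------------------------------


def write_frequency(profile: FrequencyProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_frequency(path: str | Path, genome: BinnedGenome, condition: str = "") -> FrequencyProfile:
    df = pd.read_csv(path, sep="\t")
    if len(df) != genome.n_bins:
        raise FormatError(f"{path}: {len(df)} rows but genome has {genome.n_bins} bins")
    counts = df["partners"].to_numpy(dtype=np.int64)
    return FrequencyProfile(
        genome=genome,
        counts=counts,
        frequency=counts / genome.n_bins,
        condition=condition,
    )
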