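"""Genomic coordinate system, binning, and plain-text readers/writers.

Coordinates are 0-based half-open (BED convention) everywhere, including on
output. Strand matters only for TSS placement; contacts and peaks are
strand-agnostic. A genome is tiled into fixed-size bins per chromosome, the
last bin of each chromosome may be short, and global bin ids are dense
``0..n_bins-1`` in chromosome order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "FeatureTrack",
    "GenomeBinning",
    "build_binning",
    "interval_to_bins",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a strand-aware TSS and a length for TPM normalization."""

    gene_id: str
    interval: GenomicInterval
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: length must be > 0")

    @property
    def tss(self) -> int:
        """TSS position: interval start on '+', last base (end-1) on '-'."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


class FeatureTrack:
    """Sorted list of (interval, value) pairs, e.g. peak calls with signal."""

    def __init__(self, features: Iterable[tuple[GenomicInterval, float]]):
        feats = list(features)
        for iv, v in feats:
            if not np.isfinite(v):
                raise ValueError(f"non-finite value {v} at {iv.chrom}:{iv.start}")
        feats.sort(key=lambda f: (f[0].chrom, f[0].start, f[0].end))
        self.features: list[tuple[GenomicInterval, float]] = feats

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.features]

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.features], dtype=float)


@dataclass
class GenomeBinning:
    """Fixed-width tiling of a genome with dense global bin ids.

    ``bin_table`` maps global bin id -> (chrom, start, end); bins tile each
    chromosome exactly, in order, with a possibly-short terminal bin.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    bin_size: int
    chrom_offsets: dict[str, int] = field(init=False)
    n_bins_per_chrom: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        offsets: dict[str, int] = {}
        nbins: dict[str, int] = {}
        off = 0
        for chrom in self.chrom_names:
            n = -(-self.chrom_lengths[chrom] // self.bin_size)  # ceil div
            offsets[chrom] = off
            nbins[chrom] = n
            off += n
        self.chrom_offsets = offsets
        self.n_bins_per_chrom = nbins
        self._n_bins = off

    @property
    def n_bins(self) -> int:
        return self._n_bins

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def bin_table(self) -> pd.DataFrame:
        """DataFrame indexed by global bin id with chrom/start/end columns."""
        rows = []
        for chrom in self.chrom_names:
            length = self.chrom_lengths[chrom]
            for i in range(self.n_bins_per_chrom[chrom]):
                start = i * self.bin_size
                rows.append((chrom, start, min(start + self.bin_size, length)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df.index.name = "bin_id"
        return df

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id containing position ``pos`` (0-based)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offsets[chrom] + pos // self.bin_size

    def bin_chrom(self, bin_id: int) -> str:
        for chrom in self.chrom_names:
            off = self.chrom_offsets[chrom]
            if off <= bin_id < off + self.n_bins_per_chrom[chrom]:
                return chrom
        raise IndexError(f"bin id {bin_id} out of range")

    def bin_interval(self, bin_id: int) -> GenomicInterval:
        chrom = self.bin_chrom(bin_id)
        local = bin_id - self.chrom_offsets[chrom]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.chrom_lengths[chrom])
        return GenomicInterval(chrom, start, end)

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin-id range [lo, hi) for one chromosome."""
        off = self.chrom_offsets[chrom]
        return off, off + self.n_bins_per_chrom[chrom]

    def chrom_of_bins(self) -> np.ndarray:
        """Integer chromosome index per global bin."""
        out = np.empty(self.n_bins, dtype=int)
        for ci, chrom in enumerate(self.chrom_names):
            lo, hi = self.chrom_bin_range(chrom)
            out[lo:hi] = ci
        return out

    def same_binning(self, other: "GenomeBinning") -> bool:
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )


def build_binning(chrom_sizes: Mapping[str, int], bin_size: int) -> GenomeBinning:
    """Tile a genome into ``bin_size``-bp bins with dense global ids."""
    if not chrom_sizes:
        raise ValueError("empty chromosome set")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
    return GenomeBinning(
        chrom_names=list(chrom_sizes),
        chrom_lengths=dict(chrom_sizes),
        bin_size=int(bin_size),
    )


def interval_to_bins(binning: GenomeBinning, iv: GenomicInterval) -> list[int]:
    """All global bin ids overlapping [iv.start, iv.end), ascending."""
    if iv.chrom not in binning.chrom_lengths:
        raise KeyError(f"unknown chromosome {iv.chrom!r}")
    off = binning.chrom_offsets[iv.chrom]
    n = binning.n_bins_per_chrom[iv.chrom]
    first = iv.start // binning.bin_size
    last = (iv.end - 1) // binning.bin_size  # end is exclusive
    last = min(last, n - 1)
    return [off + i for i in range(first, last + 1)]


# ---------------------------------------------------------------------------
# Plain-text IO: chrom.sizes, BED, bedGraph, gene table
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
    return sizes


def read_bed(path) -> FeatureTrack:
    """Read BED3/BED6 into a FeatureTrack (score column -> value, default 0).

    Records with start >= end are rejected with a warning; other malformed
    lines raise with their line number.
    """
    feats: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if start >= end:
                warnings.warn(
                    f"{path}: line {lineno}: start >= end, record skipped",
                    stacklevel=2,
                )
                continue
            value = float(parts[4]) if len(parts) >= 5 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) >= 6 else "."
            feats.append((GenomicInterval(chrom, start, end, strand), value))
    return FeatureTrack(feats)


def write_bed(track: FeatureTrack, path, names: Sequence[str] | None = None) -> None:
    """Write a FeatureTrack as BED6 (name column optional)."""
    with open(path, "w") as fh:
        for i, (iv, v) in enumerate(track):
            name = names[i] if names is not None else f"feature_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{v:g}\t{iv.strand}\n")


def write_bedgraph(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, v in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.17g}\n")


def read_bedgraph(path) -> FeatureTrack:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            feats.append(
                (GenomicInterval(parts[0], int(parts[1]), int(parts[2])), float(parts[3]))
            )
    return FeatureTrack(feats)


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "length"]


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read a TSV with header gene_id, chrom, start, end, strand, length."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                length=int(row.length),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path) -> None:
    rows = [
        (g.gene_id, g.interval.chrom, g.interval.start, g.interval.end,
         g.interval.strand, g.length)
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
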