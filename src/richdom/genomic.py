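"""Shared genomic data model and text-format I/O.

All coordinates are 0-based half-open (BED convention) internally; readers
for 1-based formats convert at the boundary.  Chromosome names are taken
verbatim — no "chr" normalization is attempted, and helpers that combine
two files raise when the naming styles disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SignalTrack",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "mean_signal",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_expression",
    "read_gmt",
    "check_chrom_compat",
]

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed record in a BED-family file; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_bp(other)
        if inter == 0:
            return 0.0
        union = len(self) + len(other) - inter
        return inter / union


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit offset and a score."""

    interval: GenomicInterval
    name: str = "."
    summit_offset: int | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when the caller reported none."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS and ordered disjoint exons."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end-1 on - strand."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class SignalTrack:
    """Fixed-bin per-chromosome signal (ChIP, input, or Hi-C eigenvector).

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``; values are float64.
    """

    def __init__(
        self,
        bin_size: int,
        values: Mapping[str, np.ndarray],
        units: str = "signal",
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.units = units
        self.values: dict[str, np.ndarray] = {
            chrom: np.asarray(v, dtype=float) for chrom, v in values.items()
        }

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def extent(self, chrom: str) -> int:
        """Covered extent of a chromosome in bp (number of bins x bin size)."""
        return len(self.values[chrom]) * self.bin_size

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.values

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            self.units,
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a transform flag.

    ``log_transformed`` records whether values are log2(x+1)-scaled;
    downstream tests assume that scale.
    """

    data: pd.DataFrame
    log_transformed: bool = True

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _split_line(line: str, lineno: int, min_cols: int, path: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise BedParseError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def _parse_coords(fields: list[str], lineno: int, path: str) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end:
        raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
    return fields[0], start, end


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; strand from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, lineno, 3, path)
            chrom, start, end = _parse_coords(fields, lineno, path)
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write sorted BED6 (name '.', score 0)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_narrowpeak(path: str) -> list[Peak]:
    """Read ENCODE narrowPeak (10 columns); summit -1 means absent."""
    out: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 10:
                raise BedParseError(
                    f"{path}:{lineno}: narrowPeak requires exactly 10 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end = _parse_coords(fields, lineno, path)
            strand = fields[5] if fields[5] in VALID_STRANDS else "."
            try:
                signal = float(fields[6])
                summit = int(fields[9])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad numeric field") from exc
            out.append(
                Peak(
                    GenomicInterval(chrom, start, end, strand),
                    name=fields[3],
                    summit_offset=None if summit == -1 else summit,
                    score=signal,
                )
            )
    return out


def write_narrowpeak(peaks: Iterable[Peak], path: str) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.score:g}\t-1\t-1\t{summit}\n"
            )


def read_bedgraph(path: str, bin_size: int = 50, units: str = "signal") -> SignalTrack:
    """Resample a bedGraph onto fixed bins by coverage-weighted mean.

    Uncovered parts of a bin contribute value 0, so a record covering half
    a bin at value 4 yields a bin value of 2.  Overlapping records with
    differing values are contradictory and raise; records may be unsorted.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, lineno, 4, path)
            chrom, start, end = _parse_coords(fields, lineno, path)
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric value") from exc
            records.setdefault(chrom, []).append((start, end, value))

    values: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        prev_end, prev = 0, None
        for rec in recs:
            if prev is not None and rec[0] < prev_end and not np.isclose(rec[2], prev[2]):
                raise ValueError(
                    f"{path}: overlapping contradictory records on {chrom}: "
                    f"[{prev[0]},{prev[1]})={prev[2]} vs [{rec[0]},{rec[1]})={rec[2]}"
                )
            prev_end = max(prev_end, rec[1])
            prev = rec
        extent = max(r[1] for r in recs)
        n_bins = -(-extent // bin_size)
        acc = np.zeros(n_bins)
        for start, end, value in recs:
            first, last = start // bin_size, (end - 1) // bin_size
            if first == last:
                acc[first] += value * (end - start)
                continue
            acc[first] += value * ((first + 1) * bin_size - start)
            acc[last] += value * (end - last * bin_size)
            if last - first > 1:
                acc[first + 1 : last] += value * bin_size
        values[chrom] = acc / bin_size
    return SignalTrack(bin_size, values, units=units)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write one record per bin (runs of equal value are not merged)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track.values[chrom]
            bs = track.bin_size
            for i, v in enumerate(vec):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:.6g}\n")


def mean_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Length-weighted per-bp mean of the track over an interval.

    Intervals extending past the covered extent are clipped with a warning;
    the mean is computed over the clipped part only.
    """
    if interval.chrom not in track.values:
        raise KeyError(
            f"chromosome {interval.chrom!r} absent from track "
            f"(track has {track.chroms})"
        )
    vec = track.values[interval.chrom]
    bs = track.bin_size
    extent = len(vec) * bs
    start, end = interval.start, min(interval.end, extent)
    if interval.end > extent:
        warnings.warn(
            f"interval {interval.chrom}:{interval.start}-{interval.end} extends "
            f"past covered extent {extent}; clipping",
            stacklevel=2,
        )
    if end <= start:
        return 0.0
    first, last = start // bs, (end - 1) // bs
    if first == last:
        return float(vec[first])
    total = vec[first] * ((first + 1) * bs - start)
    total += vec[last] * (end - last * bs)
    if last - first > 1:
        total += float(vec[first + 1 : last].sum()) * bs
    return float(total / (end - start))


def check_chrom_compat(a: Sequence[str], b: Sequence[str], what: str = "inputs") -> None:
    """Raise when two chromosome name sets use visibly different styles."""
    sa, sb = set(a), set(b)
    if sa & sb:
        return
    raise ValueError(
        f"chromosome naming mismatch between {what}: "
        f"{sorted(sa)[:3]} vs {sorted(sb)[:3]} share no names"
    )


def read_genes_tsv(path: str) -> list[GeneModel]:
    """Read the gene-table exchange format.

    Tab-separated columns: gene_id, chrom, start, end, strand,
    exon_starts (comma-joined), exon_ends (comma-joined).  Header lines
    starting with ``#`` or ``gene_id`` are skipped.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "gene_id")):
                continue
            fields = _split_line(line, lineno, 5, path)
            gid, chrom = fields[0], fields[1]
            start, end, strand = int(fields[2]), int(fields[3]), fields[4]
            exons: tuple[GenomicInterval, ...] = ()
            if len(fields) >= 7 and fields[5] and fields[6]:
                starts = [int(x) for x in fields[5].rstrip(",").split(",")]
                ends = [int(x) for x in fields[6].rstrip(",").split(",")]
                if len(starts) != len(ends):
                    raise BedParseError(f"{path}:{lineno}: exon start/end count mismatch")
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
                )
            genes.append(GeneModel(gid, GenomicInterval(chrom, start, end, strand), exons))
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path: str) -> None:
    rows = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\texon_starts\texon_ends\n")
        for g in rows:
            iv = g.interval
            es = ",".join(str(e.start) for e in g.exons)
            ee = ",".join(str(e.end) for e in g.exons)
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{es}\t{ee}\n")


def read_expression(path: str, log_transformed: bool = True) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene ids, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), log_transformed=log_transformed)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, then gene ids, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
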