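"""Core genomic data types, interval algebra and plain-text format I/O.

All coordinates are handled internally as 0-based half-open (BED convention).
GFF3, which is 1-based inclusive on disk, is converted at the read/write
boundary. Chromosome names are taken verbatim; no "chr" normalisation is
attempted, so the caller is responsible for consistent naming across inputs.

Strand is carried on intervals but ignored by the interval algebra; it only
matters for TSS computation and strand-aware profile orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MARKS = ("ATAC", "H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3")
"""Fixed assay order used by every bins x marks matrix in the package."""


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class GenomicValidationError(ValueError):
    """Semantically invalid genomic data (bad coordinates, bad values)."""


class InvalidParameterError(ValueError):
    """An operation was called with an out-of-range parameter."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise GenomicValidationError("chromosome name must be non-empty")
        if self.start < 0:
            raise GenomicValidationError(
                f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise GenomicValidationError(
                f"end ({self.end}) must exceed start ({self.start}) on {self.chrom}")
        if self.strand not in ("+", "-", "."):
            raise GenomicValidationError(f"bad strand {self.strand!r}")
        if self.score is not None and math.isnan(self.score):
            raise GenomicValidationError("NaN score not allowed")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff *a* and *b* share at least ``min_bp`` base pairs."""
    if min_bp < 1:
        raise InvalidParameterError(f"min_bp must be >= 1, got {min_bp}")
    return a.intersection_length(b) >= min_bp


def merge_intervals(intervals: Iterable[GenomicInterval], gap: int = 0
                    ) -> list[GenomicInterval]:
    """Union-merge intervals that overlap or lie within ``gap`` bp.

    With the default gap of 0, book-ended intervals (end == next start) are
    merged, matching the common behaviour of interval merge tools. Strand and
    score are dropped on merged output (the union of mixed-strand input has
    no meaningful strand).
    """
    if gap < 0:
        raise InvalidParameterError(f"gap must be >= 0, got {gap}")
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv in items:
        if iv.chrom == cur_chrom and iv.start <= cur_end + gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


@dataclass
class PeakSet:
    """Peak intervals for one assay in one sample, kept coordinate-sorted."""

    assay: str
    sample_id: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self):
        return len(self.intervals)


@dataclass
class SignalTrack:
    """Binned, non-negative signal (RPKM-like units) per chromosome."""

    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self):
        if self.bin_size <= 0:
            raise InvalidParameterError("bin_size must be positive")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise GenomicValidationError(
                    f"negative signal values on {chrom}")
            self.values[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size

    def total_bins(self) -> int:
        return sum(len(v) for v in self.values.values())

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in sorted(self.values)])


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two ordered, non-overlapping anchors on one chromosome."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval

    def __post_init__(self):
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise GenomicValidationError(
                "loop anchors must be on the same chromosome "
                f"({self.anchor_a.chrom} vs {self.anchor_b.chrom})")
        if self.anchor_a.start > self.anchor_b.start:
            raise GenomicValidationError("anchor_a must precede anchor_b")
        if self.anchor_a.intersection_length(self.anchor_b) > 0:
            raise GenomicValidationError("loop anchors must not overlap")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its genomic footprint, strand-aware TSS and exonic length."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    tss: int
    length: int

    def __post_init__(self):
        if not (self.interval.start <= self.tss < self.interval.end):
            raise GenomicValidationError(
                f"TSS {self.tss} outside gene body for {self.gene_id}")
        if self.length <= 0:
            raise GenomicValidationError(
                f"non-positive length for {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def gene_from_interval(gene_id: str, interval: GenomicInterval,
                       gene_name: str | None = None,
                       length: int | None = None) -> GeneAnnotation:
    """Build a GeneAnnotation, deriving the TSS from the strand."""
    tss = interval.start if interval.strand != "-" else interval.end - 1
    return GeneAnnotation(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        interval=interval,
        tss=tss,
        length=length if length is not None else interval.length,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_coords(path, lineno, chrom, start, end):
    if start < 0:
        raise ParseError(path, lineno, f"negative start coordinate {start}")
    if end <= start:
        raise ParseError(path, lineno, f"end {end} <= start {start}")
    if not chrom:
        raise ParseError(path, lineno, "empty chromosome name")


def _parse_interval_fields(path, lineno, fields):
    if len(fields) < 3:
        raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(path, lineno,
                         f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
    _check_coords(path, lineno, chrom, start, end)
    return chrom, start, end


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3/5/6-column BED file into sorted GenomicIntervals.

    Column 4 (name) is ignored, column 5 is the score, column 6 the strand.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = _parse_interval_fields(path, lineno, fields)
            score = None
            strand = "."
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {fields[4]!r}")
                if math.isnan(score):
                    raise ParseError(path, lineno, "NaN score")
            if len(fields) >= 6:
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ParseError(path, lineno, f"bad strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, strand, score))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(path, intervals: Sequence[GenomicInterval],
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED; emits 6 columns when a name list is given or
    any interval carries a score/strand, else plain BED3."""
    rich = names is not None or any(
        iv.score is not None or iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if rich:
                name = names[i] if names is not None else f"region_{i + 1}"
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path) -> list[Loop]:
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno,
                                 f"expected >=6 columns, got {len(fields)}")
            ca, cb = fields[0], fields[3]
            try:
                sa, ea, sb, eb = (int(fields[1]), int(fields[2]),
                                  int(fields[4]), int(fields[5]))
            except ValueError:
                raise ParseError(path, lineno, "non-integer anchor coordinates")
            _check_coords(path, lineno, ca, sa, ea)
            _check_coords(path, lineno, cb, sb, eb)
            try:
                loops.append(Loop(GenomicInterval(ca, sa, ea),
                                  GenomicInterval(cb, sb, eb)))
            except GenomicValidationError as exc:
                raise ParseError(path, lineno, str(exc))
    return loops


def write_bedpe(path, loops: Sequence[Loop]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path) -> list[GeneAnnotation]:
    """Read the gene subset of a GFF3 file (feature type ``gene``).

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    The exonic length for TPM is taken from an ``exonic_length`` attribute
    when present, else the gene span is used.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno,
                                 f"expected 9 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            chrom, strand = fields[0], fields[6]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if start1 < 1:
                raise ParseError(path, lineno,
                                 f"GFF3 start must be >= 1, got {start1}")
            if end1 < start1:
                raise ParseError(path, lineno, f"end {end1} < start {start1}")
            if strand not in ("+", "-", "."):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            attrs = _gff_attributes(fields[8])
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise ParseError(path, lineno, "gene record without ID attribute")
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            length = int(attrs.get("exonic_length", interval.length))
            genes.append(gene_from_interval(
                gene_id, interval, attrs.get("Name", gene_id), length))
    return sorted(genes, key=lambda g: (g.chrom, g.interval.start))


def write_gff3_genes(path, genes: Sequence[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = (f"ID={g.gene_id};Name={g.gene_name};"
                     f"exonic_length={g.length}")
            fh.write(f"{iv.chrom}\tovisepi\tgene\t{iv.start + 1}\t{iv.end}\t."
                     f"\t{iv.strand}\t.\t{attrs}\n")


def read_bedgraph(path, bin_size: int,
                  chrom_lengths: dict[str, int]) -> SignalTrack:
    """Read a bedGraph whose records are aligned to a fixed bin grid."""
    values = {c: np.zeros(-(-length // bin_size))
              for c, length in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno,
                                 f"expected 4 columns, got {len(fields)}")
            chrom, start, end = _parse_interval_fields(path, lineno, fields)
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, f"bad value {fields[3]!r}")
            if chrom not in values:
                raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
            if end > chrom_lengths[chrom]:
                raise ParseError(
                    path, lineno,
                    f"interval end {end} beyond {chrom} length {chrom_lengths[chrom]}")
            if start % bin_size:
                raise ParseError(path, lineno,
                                 f"record not aligned to {bin_size}-bp grid")
            values[chrom][start // bin_size: -(-end // bin_size)] = value
    return SignalTrack(bin_size=bin_size, values=values)


def write_bedgraph(path, track: SignalTrack) -> None:
    """Write a SignalTrack as bedGraph, run-length compressing equal bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * track.bin_size}\t{e * track.bin_size}"
                         f"\t{arr[s]:g}\n")


def read_tsv_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with a header row and row labels in column 0."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(path, df: pd.DataFrame, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
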