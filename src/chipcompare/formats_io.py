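"""Readers and writers for the external formats the pipeline touches.

All coordinates inside the package are 0-based half-open, matching BED and
bedGraph.  SAM input (1-based POS) is converted at this boundary and nowhere
else.  Peak tables published with 1-based inclusive coordinates are likewise
normalized on read.

Quality encoding is fixed to Phred+33 (Sanger) by default; a ``qual_offset``
argument is provided because files from older Illumina instruments vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chipcompare")

_VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A reference genome held in memory as uppercase ACGTN strings."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped single-end read.

    ``start`` is the 0-based leftmost aligned position regardless of strand;
    ``mean_quality`` is the mean Phred base quality of the read.
    """

    contig: str
    start: int
    length: int
    strand: str  # "+" or "-"
    mean_quality: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mean_quality < 0:
            raise ValueError("mean_quality must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """5' alignment position: start on +, end on - (duplicate key)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class BedInterval:
    """Generic half-open genomic interval (carrier for peaks, genes, sites)."""

    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    def sort_key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass
class BedGraphTrack:
    """Ordered runs of constant read depth, 0-based half-open.

    Runs within a contig must be sorted, non-overlapping, and adjacent runs
    must carry different values; zero-depth runs are never stored.
    """

    runs: list[tuple[str, int, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        prev: tuple[str, int, int, float] | None = None
        for run in self.runs:
            contig, start, end, value = run
            if start >= end:
                raise ValueError(f"empty run {run}")
            if value < 0:
                raise ValueError(f"negative depth in run {run}")
            if prev is not None and prev[0] == contig:
                if start < prev[2]:
                    raise ValueError(f"unsorted/overlapping runs {prev} and {run}")
                if start == prev[2] and value == prev[3]:
                    raise ValueError(f"adjacent runs {prev} and {run} not merged")
            prev = run

    def area(self) -> float:
        """Total depth x width; equals the summed fragment lengths."""
        return float(sum((end - start) * value for _, start, end, value in self.runs))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase is folded to uppercase and any character outside ACGTN is
    mapped to N.  Duplicate contig names and empty files are errors.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Alignments: SAM and BED6-with-quality
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    format: Literal["sam", "bed6q"] = "sam",
    qual_offset: int = 33,
) -> list[ReadAlignment]:
    """Read mapped single-end alignments from SAM or BED6q.

    SAM: 1-based POS becomes a 0-based start; unmapped and secondary records
    are skipped and their count logged; mean quality is computed from the
    QUAL string (Phred+33 unless ``qual_offset`` says otherwise).

    BED6q: BED6 where the score column holds the precomputed mean base
    quality (the simulator's native text format).
    """
    if format == "sam":
        return _read_sam(path, qual_offset)
    elif format == "bed6q":
        return _read_bed6q(path)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_sam(path: str | Path, qual_offset: int = 33) -> list[ReadAlignment]:
    # pysam decodes QUAL assuming Phred+33; shift if the file used another base
    shift = qual_offset - 33
    reads: list[ReadAlignment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            quals = rec.query_qualities
            if quals is None or len(quals) == 0:
                raise ValueError(
                    f"SAM record {rec.query_name!r} has no quality string"
                )
            reads.append(
                ReadAlignment(
                    contig=rec.reference_name,
                    start=rec.reference_start,  # pysam is already 0-based
                    length=rec.query_length,
                    strand="-" if rec.is_reverse else "+",
                    mean_quality=float(sum(quals)) / len(quals) - shift,
                )
            )
    if n_skipped:
        logger.info("read_alignments: skipped %d unmapped/secondary records", n_skipped)
    return reads


def _read_bed6q(path: str | Path) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                meanq, strand = float(fields[4]), fields[5]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            reads.append(
                ReadAlignment(
                    contig=contig,
                    start=start,
                    length=end - start,
                    strand=strand,
                    mean_quality=meanq,
                )
            )
    return reads


def write_alignments(
    reads: Sequence[ReadAlignment],
    path: str | Path,
    format: Literal["sam", "bed6q"] = "bed6q",
    genome_lengths: dict[str, int] | None = None,
) -> None:
    """Write alignments as BED6q (default) or minimal single-end SAM."""
    if format == "bed6q":
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\tread{i}\t"
                    f"{r.mean_quality:.10g}\t{r.strand}\n"
                )
        return
    if format != "sam":
        raise ValueError(f"unknown alignment format {format!r}")
    if genome_lengths is None:
        raise ValueError("writing SAM requires genome_lengths for the header")
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        tid = {name: i for i, name in enumerate(genome_lengths)}
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"read{i}"
            a.reference_id = tid[r.contig]
            a.reference_start = r.start
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.query_sequence = "N" * r.length
            q = max(0, min(93, round(r.mean_quality)))
            a.query_qualities = pysam.qualitystring_to_array(chr(q + 33) * r.length)
            sam.write(a)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: BedGraphTrack, path: str | Path) -> None:
    """Write a 4-column bedGraph; raises on unsorted/invalid tracks."""
    track.validate()
    with open(path, "w") as fh:
        for contig, start, end, value in track.runs:
            v = int(value) if float(value).is_integer() else value
            fh.write(f"{contig}\t{start}\t{end}\t{v}\n")


def read_bedgraph(path: str | Path) -> BedGraphTrack:
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            runs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    track = BedGraphTrack(runs)
    track.validate()
    return track


# ---------------------------------------------------------------------------
# BED intervals (peaks, genes, truth sites)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[BedInterval]:
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append(
                    BedInterval(
                        contig=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        name=f[3] if len(f) > 3 else ".",
                        score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                        strand=f[5] if len(f) > 5 else ".",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_peak_table(
    path: str | Path,
    dialect: Literal["bed", "supplementary_table"] = "bed",
    one_based_inclusive: bool | None = None,
) -> list[BedInterval]:
    """Read a peak set from BED or a published tab-separated peak table.

    The supplementary dialect permits a header row and defaults to 1-based
    inclusive coordinates (the common convention for such tables); set
    ``one_based_inclusive=False`` if the table is already BED-like.  All
    intervals are normalized to internal 0-based half-open coordinates.
    """
    if dialect == "bed":
        return read_bed(path)
    if dialect != "supplementary_table":
        raise ValueError(f"unknown peak-table dialect {dialect!r}")
    shift = 1 if (one_based_inclusive is None or one_based_inclusive) else 0
    peaks: list[BedInterval] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start_idx = 0
    if lines:
        first = lines[0].split("\t")
        try:
            int(first[1])
        except (ValueError, IndexError):
            start_idx = 1  # header row
    for lineno, line in enumerate(lines[start_idx:], start=start_idx + 1):
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns")
        start = int(f[1]) - shift
        end = int(f[2])  # 1-based inclusive end == 0-based exclusive end
        if start >= end:
            raise ValueError(
                f"{path}:{lineno}: start >= end after normalization ({start} >= {end})"
            )
        name = f[3] if len(f) > 3 else f"peak{lineno}"
        peaks.append(BedInterval(contig=f[0], start=start, end=end, name=name))
    return peaks


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def sort_intervals(intervals: Iterable[BedInterval]) -> list[BedInterval]:
    return sorted(intervals, key=BedInterval.sort_key)
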