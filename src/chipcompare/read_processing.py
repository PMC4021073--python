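"""Read-level pipeline: quality filter, duplicate removal, 3' extension,
coverage track.

The stages run in this order: reads with mean base quality below the
threshold are dropped first; PCR duplicates (reads sharing contig, 5'
alignment position and strand) are collapsed to one; each surviving read is
extended at its 3' end to the expected sonication fragment length; and the
extended fragments are piled up into a bedGraph coverage track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import BedGraphTrack, ReadAlignment

logger = logging.getLogger("chipcompare")


@dataclass
class ProcessingParams:
    """Parameters of the read-level pipeline.

    min_mean_quality: reads with mean Phred base quality strictly below this
        are removed (default 20).
    fragment_length: length in bases each read is extended to in its 3'
        direction (default 180, the expected sonication fragment size).
    """

    min_mean_quality: float = 20.0
    fragment_length: int = 180

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")


@dataclass(frozen=True)
class FragmentInterval:
    """A 3'-extended read, clipped to its contig; 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def filter_by_mean_quality(
    reads: Sequence[ReadAlignment], params: ProcessingParams
) -> tuple[list[ReadAlignment], int]:
    """Remove reads with mean base quality strictly below the threshold.

    The boundary is strict: a read at exactly the threshold is kept.
    Order is preserved.  Returns (kept_reads, n_removed).
    """
    kept = [r for r in reads if r.mean_quality >= params.min_mean_quality]
    n_removed = len(reads) - len(kept)
    if n_removed:
        logger.info(
            "quality filter: removed %d of %d reads (mean Q < %g)",
            n_removed, len(reads), params.min_mean_quality,
        )
    return kept, n_removed


def deduplicate(
    reads: Sequence[ReadAlignment],
) -> tuple[list[ReadAlignment], int]:
    """Collapse presumed PCR duplicates to a single read.

    Reads sharing (contig, 5' alignment position, strand) are duplicates;
    the 5' position is the start for + strand reads and the end for -
    strand reads, matching single-end duplicate-marking semantics.  The
    first read in (contig, start, strand) sort order is retained; output is
    sorted.  Returns (kept_reads, n_duplicates_removed).
    """
    ordered = sorted(reads, key=lambda r: (r.contig, r.start, r.strand))
    seen: set[tuple[str, int, str]] = set()
    kept: list[ReadAlignment] = []
    for r in ordered:
        key = (r.contig, r.five_prime, r.strand)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    n_removed = len(ordered) - len(kept)
    if n_removed:
        logger.info("deduplicate: removed %d of %d reads", n_removed, len(ordered))
    return kept, n_removed


def extend_reads(
    reads: Sequence[ReadAlignment],
    params: ProcessingParams,
    genome_lengths: dict[str, int],
) -> list[FragmentInterval]:
    """Extend each read at its 3' end to ``fragment_length`` bases.

    A + strand read [s, s+L) becomes [s, s+F); a - strand read becomes
    [s+L-F, s+L).  Fragments are clipped to [0, contig length).  Exactly one
    fragment is produced per read.
    """
    F = params.fragment_length
    fragments: list[FragmentInterval] = []
    for r in reads:
        clen = genome_lengths[r.contig]
        if r.strand == "+":
            start, end = r.start, r.start + F
        else:
            start, end = r.end - F, r.end
        start = max(0, start)
        end = min(clen, end)
        if start >= end:
            raise ValueError(
                f"fragment from read at {r.contig}:{r.start}({r.strand}) "
                f"falls entirely outside the contig"
            )
        fragments.append(FragmentInterval(r.contig, start, end, r.strand))
    return fragments


def coverage_track(
    fragments: Sequence[FragmentInterval],
    genome_lengths: dict[str, int],
) -> BedGraphTrack:
    """Pile fragments into a bedGraph track of per-base fragment depth.

    The value of each run is the number of fragments covering every base in
    it; zero-depth runs are omitted.  Total area (depth x width summed over
    runs) equals the summed fragment lengths exactly.
    """
    runs: list[tuple[str, int, int, float]] = []
    by_contig: dict[str, list[FragmentInterval]] = {}
    for f in fragments:
        by_contig.setdefault(f.contig, []).append(f)
    for contig in sorted(by_contig):
        frags = by_contig[contig]
        clen = genome_lengths[contig]
        delta = np.zeros(clen + 1, dtype=np.int64)
        for f in frags:
            delta[f.start] += 1
            delta[f.end] -= 1
        depth = np.cumsum(delta[:-1])
        # run-length encode the depth profile
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [clen]))
        for s, e in zip(starts, ends):
            v = depth[s]
            if v > 0:
                runs.append((contig, int(s), int(e), float(v)))
    track = BedGraphTrack(runs)
    track.validate()
    return track


def process_reads(
    reads: Sequence[ReadAlignment],
    params: ProcessingParams,
    genome_lengths: dict[str, int],
) -> tuple[list[FragmentInterval], BedGraphTrack, dict[str, int]]:
    """Run the full read-level pipeline; returns fragments, coverage and
    the per-stage retention counts."""
    kept, n_lowq = filter_by_mean_quality(reads, params)
    unique, n_dup = deduplicate(kept)
    fragments = extend_reads(unique, params, genome_lengths)
    track = coverage_track(fragments, genome_lengths)
    counts = {
        "reads_in": len(reads),
        "removed_low_quality": n_lowq,
        "duplicates_removed": n_dup,
        "fragments": len(fragments),
    }
    logger.info("read processing: %s", counts)
    return fragments, track, counts
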