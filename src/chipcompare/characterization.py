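"""Per-peak signal quantification and degenerate-motif frequency.

Signal is summarized as RPKM (fragments per kilobase of peak per million
library fragments), which is invariant under uniform duplication of the
whole library, plus sorted signal curves and quantile summaries.  Motif
frequency scans peaks for an IUPAC degenerate motif (default WGATAR, the
canonical GATA recognition element; reverse complement YTATCW) on both
strands; a peak contains the motif when at least one match lies entirely
inside the peak interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeSequence

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC degenerate motif; default WGATAR (W = A/T, R = A/G)."""

    iupac: str = "WGATAR"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("motif must be non-empty")
        for c in self.iupac:
            if c not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {c!r} in motif {self.iupac!r}")

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> str:
        return self.iupac.translate(_COMPLEMENT)[::-1]


class MotifMatcher:
    """Scanner for an IUPAC motif, optionally on both strands.

    Genome N bases match nothing: character classes are built from concrete
    A/C/G/T only, so even the motif code N does not match an N in the
    sequence.  Matches may overlap.
    """

    def __init__(self, spec: MotifSpec, both_strands: bool = True):
        self.spec = spec
        self.both_strands = both_strands
        fwd = "".join(f"[{IUPAC_CODES[c]}]" for c in spec.iupac)
        alternatives = [fwd]
        if both_strands:
            rev = "".join(f"[{IUPAC_CODES[c]}]" for c in spec.reverse_complement())
            if rev != fwd:
                alternatives.append(rev)
        # lookahead so overlapping occurrences are all reported
        self._regex = re.compile("(?=(?:" + "|".join(alternatives) + "))")

    def find(self, sequence: str) -> np.ndarray:
        """Start positions (sorted, unique) of matches on either strand."""
        seq = sequence.upper()
        return np.array(
            [m.start() for m in self._regex.finditer(seq)], dtype=np.int64
        )

    def search(self, sequence: str) -> bool:
        return self._regex.search(sequence.upper()) is not None


def compile_motif(spec: MotifSpec, both_strands: bool = True) -> MotifMatcher:
    """Compile an IUPAC motif into a scanner over forward sequence and, by
    default, its reverse complement."""
    return MotifMatcher(spec, both_strands=both_strands)


def peak_motif_fraction(
    peaks: Sequence,
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    both_strands: bool = True,
) -> tuple[int, float]:
    """Count peaks containing >= 1 motif match fully inside the interval.

    Returns (n_with_motif, fraction of peaks).  A peak extending beyond its
    contig is an error.
    """
    matcher = compile_motif(spec, both_strands=both_strands)
    n_with = 0
    for p in peaks:
        seq = genome.contigs.get(p.contig)
        if seq is None:
            raise ValueError(f"peak on unknown contig {p.contig!r}")
        if p.start < 0 or p.end > len(seq):
            raise ValueError(
                f"peak [{p.start}, {p.end}) exceeds contig {p.contig} "
                f"({len(seq)} bp)"
            )
        if matcher.search(seq[p.start:p.end]):
            n_with += 1
    fraction = n_with / len(peaks) if peaks else float("nan")
    return n_with, fraction


def stratified_motif_table(
    groups: Mapping[str, Sequence],
    genome: GenomeSequence,
    spec: MotifSpec = MotifSpec(),
    both_strands: bool = True,
) -> pd.DataFrame:
    """Motif frequency per peak group (whole sets, overlap classes, TSS
    bins, ...): columns group, n_peaks, n_with_motif, percent (1 decimal;
    NA for empty groups)."""
    rows = []
    for name, peaks in groups.items():
        if len(peaks) == 0:
            rows.append({"group": name, "n_peaks": 0,
                         "n_with_motif": 0, "percent": pd.NA})
            continue
        n_with, frac = peak_motif_fraction(peaks, genome, spec, both_strands)
        rows.append({
            "group": name, "n_peaks": len(peaks), "n_with_motif": n_with,
            "percent": round(100.0 * frac, 1),
        })
    return pd.DataFrame(rows, columns=["group", "n_peaks", "n_with_motif", "percent"])


@dataclass(frozen=True)
class PeakSignal:
    peak_name: str
    fragment_count: int
    rpkm: float


@dataclass(frozen=True)
class SignalSummary:
    mean: float
    median: float
    p5: float
    p25: float
    p75: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p5 <= self.p25 <= self.median <= self.p75 <= self.p95):
            raise ValueError("quantiles out of order")


def rpkm_scores(
    peaks: Sequence,
    fragments: Sequence,
    library_depth: int,
) -> list[PeakSignal]:
    """RPKM per peak: fragments with midpoint inside the peak, per kb of
    peak length, per million library fragments.

    ``library_depth`` is the total post-deduplication fragment count of the
    library the fragments came from.
    """
    if library_depth <= 0:
        raise ValueError("library_depth must be positive")
    mids: dict[str, np.ndarray] = {}
    by_contig: dict[str, list[int]] = {}
    for f in fragments:
        by_contig.setdefault(f.contig, []).append((f.start + f.end) // 2)
    for c, v in by_contig.items():
        mids[c] = np.sort(np.array(v, dtype=np.int64))
    out: list[PeakSignal] = []
    for i, p in enumerate(peaks):
        length = p.end - p.start
        if length <= 0:
            raise ValueError(f"zero-length peak at {p.contig}:{p.start}")
        m = mids.get(p.contig)
        count = 0
        if m is not None:
            count = int(
                np.searchsorted(m, p.end, side="left")
                - np.searchsorted(m, p.start, side="left")
            )
        rpkm = count / (length / 1000.0) / (library_depth / 1e6)
        name = getattr(p, "name", None) or f"peak{i}"
        out.append(PeakSignal(name, count, float(rpkm)))
    return out


def sorted_signal_curve(
    signals: Sequence[PeakSignal],
) -> tuple[np.ndarray, np.ndarray]:
    """Peaks sorted by increasing signal, scaled to percent of the maximum.

    Returns (rank fraction in [0, 1], percent of maximal RPKM); the curve is
    non-decreasing and ends at 100 whenever any signal is positive.
    """
    if not signals:
        raise ValueError("need at least one signal")
    values = np.sort(np.array([s.rpkm for s in signals], dtype=float))
    n = len(values)
    x = np.arange(n) / (n - 1) if n > 1 else np.zeros(1)
    top = values[-1]
    y = 100.0 * values / top if top > 0 else np.zeros(n)
    return x, y


def signal_summary(signals: Sequence[PeakSignal]) -> SignalSummary:
    """Mean, median and the 5/25/75/95 percentiles of RPKM, with
    percentiles by linear interpolation between order statistics."""
    if not signals:
        raise ValueError("need at least one signal")
    v = np.array([s.rpkm for s in signals], dtype=float)
    p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    return SignalSummary(
        mean=float(v.mean()), median=float(p50),
        p5=float(p5), p25=float(p25), p75=float(p75), p95=float(p95),
    )
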