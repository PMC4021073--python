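"""Two-sample overlap partitioning and TSS/gene annotation.

Overlap between two peak sets is defined as any shared base (>= 1 bp);
half-open intervals that merely abut do not overlap.  Two distance
conventions co-exist deliberately: signed midpoint-to-TSS distance (gene
strand oriented, negative = upstream) drives the distance histograms, while
gene-window membership uses the unsigned distance from the nearest peak
border to the TSS, inclusive at the window edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chipcompare")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    tss: int  # 0-based position of the transcription start site


@dataclass
class GeneModel:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")

    def by_contig(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.contig, []).append(g)
        return out


@dataclass
class OverlapPartition:
    """Partition of two peak sets by >= 1 bp overlap with the other set."""

    shared_a: list
    specific_a: list
    shared_b: list
    specific_b: list

    def sizes(self) -> dict[str, int]:
        return {
            "shared_a": len(self.shared_a),
            "specific_a": len(self.specific_a),
            "shared_b": len(self.shared_b),
            "specific_b": len(self.specific_b),
        }


@dataclass(frozen=True)
class TssAssignment:
    """Nearest-gene assignment for one peak.

    signed_distance is midpoint-to-TSS, oriented by gene strand (negative =
    peak upstream of the TSS); border_distance is the unsigned distance from
    the nearest covered peak base to the TSS (0 if the TSS lies inside the
    peak).
    """

    peak_name: str
    gene_id: str | None
    signed_distance: float | None
    border_distance: int | None


def _interval_arrays(peaks: Iterable) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per contig: (starts sorted ascending, prefix-max of ends in that order)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    out = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
        out[contig] = (starts, ends)
    return out


def _overlaps_any(
    peak, index: dict[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    if peak.contig not in index:
        return False
    starts, end_max = index[peak.contig]
    # candidates: intervals with start < peak.end; overlap iff max end > peak.start
    i = int(np.searchsorted(starts, peak.end, side="left"))
    return i > 0 and end_max[i - 1] > peak.start


def overlap_partition(set_a: Sequence, set_b: Sequence) -> OverlapPartition:
    """Split each peak set into peaks overlapping (>= 1 bp) the other set
    and peaks specific to their own set.

    Abutting half-open intervals ([0,10) and [10,20)) do not overlap.
    """
    index_a = _interval_arrays(set_a)
    index_b = _interval_arrays(set_b)
    shared_a = [p for p in set_a if _overlaps_any(p, index_b)]
    specific_a = [p for p in set_a if not _overlaps_any(p, index_b)]
    shared_b = [p for p in set_b if _overlaps_any(p, index_a)]
    specific_b = [p for p in set_b if not _overlaps_any(p, index_a)]
    return OverlapPartition(shared_a, specific_a, shared_b, specific_b)


def _peak_name(peak, i: int) -> str:
    name = getattr(peak, "name", None)
    return name if name not in (None, ".") else f"peak{i}"


def nearest_tss(peaks: Sequence, gene_model: GeneModel) -> list[TssAssignment]:
    """Assign each peak to its nearest gene by absolute midpoint-to-TSS
    distance; ties go to the lexicographically smaller gene id.

    Peaks on contigs without genes get an absent assignment (gene_id None)
    and their count is logged.
    """
    by_contig: dict[str, list[Gene]] = gene_model.by_contig()
    # sort genes by (tss, gene_id) so equal-TSS blocks are id-ordered
    sorted_genes: dict[str, tuple[np.ndarray, list[Gene]]] = {}
    for contig, genes in by_contig.items():
        genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        sorted_genes[contig] = (np.array([g.tss for g in genes], dtype=np.int64), genes)

    out: list[TssAssignment] = []
    n_absent = 0
    for i, p in enumerate(peaks):
        name = _peak_name(p, i)
        if p.contig not in sorted_genes:
            n_absent += 1
            out.append(TssAssignment(name, None, None, None))
            continue
        tss_arr, genes = sorted_genes[p.contig]
        mid = (p.start + p.end) / 2
        j = int(np.searchsorted(tss_arr, mid))
        # candidate distances from the flanking TSS values
        cand: list[float] = []
        if j > 0:
            cand.append(abs(mid - tss_arr[j - 1]))
        if j < len(tss_arr):
            cand.append(abs(mid - tss_arr[j]))
        dmin = min(cand)
        # all genes whose TSS sits at mid - dmin or mid + dmin are tied
        best: Gene | None = None
        for t in {mid - dmin, mid + dmin}:
            if t != int(t):
                continue
            lo = int(np.searchsorted(tss_arr, int(t), side="left"))
            if lo < len(tss_arr) and tss_arr[lo] == int(t):
                g = genes[lo]  # id-smallest gene in the equal-TSS block
                if best is None or g.gene_id < best.gene_id:
                    best = g
        assert best is not None
        signed = mid - best.tss if best.strand == "+" else best.tss - mid
        border = max(0, p.start - best.tss, best.tss - (p.end - 1))
        out.append(TssAssignment(name, best.gene_id, float(signed), int(border)))
    if n_absent:
        logger.info("nearest_tss: %d peaks on contigs without genes", n_absent)
    return out


def tss_distance_histogram(
    assignments: Sequence[TssAssignment],
    bin_edges: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of signed midpoint-to-TSS distances over half-open bins
    [lo, hi).

    Returns (counts, fractions over in-range assigned peaks, n_out_of_range).
    Unassigned peaks are excluded.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    dists = np.array(
        [a.signed_distance for a in assignments if a.signed_distance is not None]
    )
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    n_out = 0
    if dists.size:
        idx = np.searchsorted(edges, dists, side="right") - 1
        in_range = (idx >= 0) & (dists < edges[-1])
        n_out = int((~in_range).sum())
        np.add.at(counts, idx[in_range], 1)
    total = counts.sum()
    fractions = counts / total if total else np.zeros_like(counts, dtype=float)
    return counts, fractions, n_out


def genes_within_window(
    peaks: Sequence, gene_model: GeneModel, window: int
) -> tuple[set[str], int]:
    """Genes whose TSS lies within ``window`` bases (inclusive) of some
    peak border; a TSS inside a peak is at distance 0.

    Each gene is counted once regardless of how many peaks are nearby.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    index = _interval_arrays(peaks)
    hits: set[str] = set()
    for g in gene_model.genes:
        if g.contig not in index:
            continue
        starts, end_max = index[g.contig]
        # peak qualifies iff start <= tss + window and end - 1 >= tss - window
        i = int(np.searchsorted(starts, g.tss + window, side="right"))
        if i > 0 and end_max[i - 1] - 1 >= g.tss - window:
            hits.add(g.gene_id)
    return hits, len(hits)


def gene_window_table(
    peaks_a: Sequence,
    peaks_b: Sequence,
    gene_model: GeneModel,
    windows: Sequence[int] = (10_000, 50_000),
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Gene counts near peaks for two samples plus the common-gene count,
    one column per window (the layout of a genes-near-binding table)."""
    rows = {labels[0]: {}, labels[1]: {}, "Common": {}}
    for w in windows:
        genes_a, n_a = genes_within_window(peaks_a, gene_model, w)
        genes_b, n_b = genes_within_window(peaks_b, gene_model, w)
        col = f"within_{w // 1000}kb_of_TSS"
        rows[labels[0]][col] = n_a
        rows[labels[1]][col] = n_b
        rows["Common"][col] = len(genes_a & genes_b)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df
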