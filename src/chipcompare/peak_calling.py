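"""Input-normalized point-source peak caller.

A deliberately explicit, fully specified caller in the spirit of
factor-style callers: fragment midpoints are counted in sliding windows of
the expected binding footprint; candidate summits are local maxima accepted
greedily in decreasing height under a minimum summit-distance exclusion;
candidates must then clear fold-enrichment filters against both the
depth-normalized input and the local background, and a Poisson upper-tail
test whose rate is the most conservative of the normalized input, local and
global expectations.

Fragment membership in a window is by midpoint, not overlap, so no fragment
is counted by two adjacent candidates.  Ties among equal-height summits go
to the leftmost position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import maximum_filter1d

from .read_processing import FragmentInterval

logger = logging.getLogger("chipcompare")

PSEUDOCOUNT = 0.5


@dataclass
class PeakCallParams:
    """Caller thresholds.

    peak_size: width of the scanning window and of emitted peaks (default
        180 bases, the extended-fragment length).
    min_peak_distance: minimum distance between accepted summits.
    fold_over_input: minimum ratio of peak tag count to depth-normalized
        input count; set to 0 to disable the input test.
    fold_over_local: minimum ratio to the local background expectation,
        estimated from the mean ChIP fragment rate within +/- 10 peak sizes
        of the summit (peak region included).
    pvalue_threshold: Poisson upper-tail threshold.
    tags_per_position_cap: cap on fragment midpoints counted per base
        position, applied to ChIP and input alike; 0 means uncapped.
    min_input_window: the input expectation for a peak window is estimated
        from at least this many bases centered on the summit and scaled to
        the peak width; a raw count from the narrow peak window alone would
        make the input fold test a coin flip whenever the ChIP library is
        much deeper than the input.  Set to 0 to count input in the peak
        window only.
    """

    peak_size: int = 180
    min_peak_distance: int = 180
    fold_over_input: float = 4.0
    fold_over_local: float = 4.0
    pvalue_threshold: float = 1e-4
    tags_per_position_cap: int = 0
    local_background_windows: int = 10
    min_input_window: int = 2000

    def __post_init__(self) -> None:
        if self.peak_size <= 0 or self.min_peak_distance <= 0:
            raise ValueError("peak_size and min_peak_distance must be positive")
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError("pvalue_threshold must be in (0, 1)")
        if self.fold_over_input < 0 or self.fold_over_local < 0:
            raise ValueError("fold thresholds must be >= 0")


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    tag_count: int
    input_count_normalized: float
    fold_input: float
    pvalue: float
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak interval")
        if self.tag_count < 1:
            raise ValueError("peaks require at least one tag")

    def score(self) -> int:
        """BED score: round(-10 log10 p), clipped to [0, 1000]."""
        if self.pvalue <= 0:
            return 1000
        return int(min(1000, round(-10.0 * np.log10(self.pvalue))))


@dataclass
class PeakSet:
    label: str
    peaks: list[Peak]
    library_depth: int  # total post-dedup fragments, for RPKM

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.contig, p.start))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), via the survival function.

    Computed as sf(k - 1) so k = 0 returns exactly 1.0.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(stats.poisson.sf(k - 1, lam))


def _midpoints_by_contig(
    fragments: Sequence[FragmentInterval],
) -> dict[str, np.ndarray]:
    mids: dict[str, list[int]] = {}
    for f in fragments:
        mids.setdefault(f.contig, []).append(f.midpoint)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids.items()}


def _prefix_counts(mids: np.ndarray, clen: int, cap: int) -> np.ndarray:
    """C[i] = number of (possibly capped) midpoints < i; length clen + 1."""
    counts = np.bincount(mids, minlength=clen)
    if cap > 0:
        counts = np.minimum(counts, cap)
    return np.concatenate(([0], np.cumsum(counts)))


def call_peaks(
    chip_fragments: Sequence[FragmentInterval],
    input_fragments: Sequence[FragmentInterval],
    params: PeakCallParams,
    genome_lengths: dict[str, int],
    label: str = "sample",
) -> PeakSet:
    """Call point-source peaks from ChIP fragments against an input library.

    Steps: (1) fragment-midpoint counts in sliding windows of ``peak_size``
    (stride 1); (2) candidate summits accepted greedily in decreasing window
    count with a ``min_peak_distance`` exclusion zone (leftmost wins ties);
    (3) peak interval [summit - peak_size/2, summit + peak_size/2); the tag
    count is the window count at the summit; input counts are scaled by the
    ChIP/input depth ratio with pseudocount 0.5; (4) candidates are retained
    when both fold filters pass and the Poisson upper tail at
    lambda = max(normalized input, local expectation, global expectation)
    is at or below the threshold.
    """
    if not chip_fragments:
        raise ValueError("ChIP fragment set is empty")
    if not input_fragments and params.fold_over_input > 0:
        raise ValueError(
            "input library is empty; set fold_over_input=0 to disable the "
            "input enrichment test"
        )

    ps = params.peak_size
    hs = ps // 2
    cap = params.tags_per_position_cap
    chip_mids = _midpoints_by_contig(chip_fragments)
    input_mids = _midpoints_by_contig(input_fragments)
    chip_depth = len(chip_fragments)
    input_depth = len(input_fragments)
    depth_ratio = chip_depth / input_depth if input_depth else 0.0
    genome_size = sum(genome_lengths.values())
    global_exp = chip_depth / genome_size * ps

    # smallest tag count that could ever clear the filters: the Poisson
    # rate is at least global_exp and the fold denominators at least the
    # pseudocount, so lower windows need not enter the greedy selection
    # (any candidate they could exclude is lower still and fails too)
    min_tag = 1
    while (
        poisson_upper_tail(min_tag, global_exp) > params.pvalue_threshold
        and min_tag < 10_000_000
    ):
        min_tag += 1
    if params.fold_over_input > 0:
        min_tag = max(min_tag, int(np.ceil(params.fold_over_input * PSEUDOCOUNT)))
    if params.fold_over_local > 0:
        min_tag = max(min_tag, int(np.ceil(params.fold_over_local * PSEUDOCOUNT)))

    peaks: list[Peak] = []
    for contig, mids in sorted(chip_mids.items()):
        clen = genome_lengths[contig]
        C = _prefix_counts(mids, clen, cap)
        pos = np.arange(clen)
        w = C[np.minimum(pos + (ps - hs), clen)] - C[np.maximum(pos - hs, 0)]

        Cin = None
        if contig in input_mids:
            Cin = _prefix_counts(input_mids[contig], clen, cap)

        # candidate summits are local maxima of the window profile at the
        # min_peak_distance scale (a shoulder position next to a stronger
        # summit is not a candidate), then greedily accepted in decreasing
        # window count, leftmost on ties
        local_max = w == maximum_filter1d(
            w, size=2 * params.min_peak_distance - 1, mode="nearest"
        )
        candidates = np.flatnonzero(local_max & (w >= min_tag))
        order = candidates[np.lexsort((candidates, -w[candidates]))]
        blocked = np.zeros(clen, dtype=bool)
        for summit in order:
            if blocked[summit]:
                continue
            s = int(summit)
            blocked[max(0, s - params.min_peak_distance + 1):
                    s + params.min_peak_distance] = True
            start, end = max(0, s - hs), min(clen, s + (ps - hs))
            tag_count = int(w[s])

            # depth-normalized input expectation for the peak interval,
            # estimated over >= min_input_window bases around the summit
            input_norm = 0.0
            if Cin is not None:
                ihalf = max(ps, params.min_input_window) // 2
                in_lo = max(0, s - ihalf)
                in_hi = min(clen, s + ihalf)
                raw_input = float(Cin[in_hi] - Cin[in_lo])
                input_norm = (
                    raw_input * (end - start) / (in_hi - in_lo) * depth_ratio
                )
            fold_input = tag_count / max(input_norm, PSEUDOCOUNT)

            # local background: mean ChIP midpoint rate within +/- K window
            # widths scaled to the peak width; the peak region itself is
            # included, which suppresses satellite summits on the shoulders
            # of strong peaks
            K = params.local_background_windows
            loc_lo = max(0, s - K * ps)
            loc_hi = min(clen, s + K * ps)
            local_total = float(C[loc_hi] - C[loc_lo])
            local_width = loc_hi - loc_lo
            local_exp = local_total * ps / local_width if local_width > 0 else 0.0
            fold_local = tag_count / max(local_exp, PSEUDOCOUNT)

            lam = max(input_norm, local_exp, global_exp)
            pvalue = poisson_upper_tail(tag_count, lam)

            if (
                (params.fold_over_input <= 0 or fold_input >= params.fold_over_input)
                and (params.fold_over_local <= 0
                     or fold_local >= params.fold_over_local)
                and pvalue <= params.pvalue_threshold
            ):
                peaks.append(
                    Peak(
                        contig=contig, start=start, end=end, summit=s,
                        tag_count=tag_count,
                        input_count_normalized=input_norm,
                        fold_input=fold_input, pvalue=pvalue,
                    )
                )

    peaks.sort(key=lambda p: (p.contig, p.start))
    peaks = [
        Peak(
            contig=p.contig, start=p.start, end=p.end, summit=p.summit,
            tag_count=p.tag_count,
            input_count_normalized=p.input_count_normalized,
            fold_input=p.fold_input, pvalue=p.pvalue,
            name=f"{label}_peak{i + 1}",
        )
        for i, p in enumerate(peaks)
    ]
    logger.info("call_peaks[%s]: %d peaks from %d ChIP fragments",
                label, len(peaks), chip_depth)
    return PeakSet(label=label, peaks=peaks, library_depth=chip_depth)
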