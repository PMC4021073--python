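"""End-to-end orchestration: simulate -> process -> call peaks -> compare
-> characterize -> report.

Every stage writes its artifacts under the output directory and contributes
counts to a machine-readable run report (JSON + text).  The whole run is
deterministic given the simulation seed.  When peak sets are supplied
externally the simulation/processing/calling stages are skipped and only
comparison and characterization run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import annotation, peak_calling
from .annotation import GeneModel, gene_window_table, nearest_tss, overlap_partition
from .characterization import (
    MotifSpec, peak_motif_fraction, rpkm_scores, signal_summary,
    sorted_signal_curve, stratified_motif_table,
)
from .formats_io import (
    BedInterval, read_bed, read_fasta, read_peak_table, write_alignments,
    write_bed, write_bedgraph, write_fasta,
)
from .peak_calling import PeakCallParams, PeakSet
from .read_processing import ProcessingParams, process_reads
from .synthetic import SimulationConfig, simulate_experiment

logger = logging.getLogger("chipcompare")

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run; every default equals the
    corresponding stated analysis parameter (quality 20, fragment length
    180, read length 36, sonication 200-400, WGATAR, 10/50 kb windows,
    >= 1 bp overlap)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    peaks: PeakCallParams = field(default_factory=PeakCallParams)
    motif: str = "WGATAR"
    both_strands: bool = True
    gene_windows: tuple[int, ...] = (10_000, 50_000)
    tss_bin_edges: tuple[int, ...] = tuple(range(-10_000, 10_001, 1_000))
    # external inputs; when peak paths are set, simulate/process/call are skipped
    peaks_a_path: str | None = None
    peaks_b_path: str | None = None
    peak_dialect: str = "bed"
    genome_path: str | None = None
    genes_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "processing" in kwargs:
            kwargs["processing"] = ProcessingParams(**kwargs["processing"])
        if "peaks" in kwargs:
            kwargs["peaks"] = PeakCallParams(**kwargs["peaks"])
        for key in ("gene_windows", "tss_bin_edges"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def genes_to_bed(genes: GeneModel) -> list[BedInterval]:
    return [
        BedInterval(g.contig, g.tss, g.tss + 1, name=g.gene_id, strand=g.strand)
        for g in genes.genes
    ]


def bed_to_genes(intervals: Sequence[BedInterval]) -> GeneModel:
    genes = []
    for iv in intervals:
        tss = iv.start if iv.strand != "-" else iv.end - 1
        genes.append(annotation.Gene(iv.name, iv.contig, iv.strand, tss))
    return GeneModel(genes)


def peaks_to_bed(peakset: PeakSet) -> list[BedInterval]:
    return [
        BedInterval(p.contig, p.start, p.end, name=p.name, score=p.score())
        for p in peakset
    ]


def evaluate_against_truth(
    peakset: PeakSet,
    manifest,
    cell_line: str,
    tolerance: int = 180,
) -> dict[str, float]:
    """Recall/precision of called peaks against the planted sites active in
    the cell line; a site is recovered (and a peak true) when a peak summit
    lies within ``tolerance`` bases of the site position."""
    sites = manifest.sites_for(cell_line)
    site_pos: dict[str, np.ndarray] = {}
    for s in sites:
        site_pos.setdefault(s.contig, []).append(s.position)
    site_pos = {c: np.sort(np.array(v)) for c, v in site_pos.items()}
    summit_pos: dict[str, np.ndarray] = {}
    for p in peakset:
        summit_pos.setdefault(p.contig, []).append(p.summit)
    summit_pos = {c: np.sort(np.array(v)) for c, v in summit_pos.items()}

    def near(pos: int, arr: np.ndarray | None) -> bool:
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        best = min(
            [abs(pos - arr[j]) for j in (i - 1, i) if 0 <= j < arr.size]
        )
        return best <= tolerance

    n_recovered = sum(near(s.position, summit_pos.get(s.contig)) for s in sites)
    n_true = sum(near(p.summit, site_pos.get(p.contig)) for p in peakset)
    return {
        "n_sites": len(sites),
        "n_peaks": len(peakset),
        "recall": n_recovered / len(sites) if sites else float("nan"),
        "precision": n_true / len(peakset) if len(peakset) else float("nan"),
    }


def _tss_groups(peaks, assignments) -> dict[str, list]:
    """Fig-7E-style peak groups by absolute midpoint distance to the
    nearest TSS: within 1 kb, within 10 kb, not TSS-associated (> 10 kb)."""
    groups = {"TSS_in_1kb": [], "TSS_in_10kb": [], "no_TSS": []}
    for p, a in zip(peaks, assignments):
        d = abs(a.signed_distance) if a.signed_distance is not None else None
        if d is None or d > 10_000:
            groups["no_TSS"].append(p)
        elif d <= 1_000:
            groups["TSS_in_1kb"].append(p)
        else:
            groups["TSS_in_10kb"].append(p)
    return groups


def validate_report(report: dict) -> None:
    """Internal-consistency checks before the report is written."""
    part = report.get("partition", {})
    for line in ("A", "B"):
        key = line.lower()
        total = report["peaks"].get(f"n_peaks_{line}")
        if total is not None and part:
            if part[f"shared_{key}"] + part[f"specific_{key}"] != total:
                raise AssertionError(
                    f"partition sizes for {line} do not sum to the peak total"
                )
    for row in report.get("motif_table", []):
        if row["n_with_motif"] > row["n_peaks"]:
            raise AssertionError("motif count exceeds peak count")


def render_tables(report: dict, outdir: str | Path) -> None:
    """Write the comparison tables as TSV: gene counts per window (with the
    common-gene row), the overlap partition, and the motif-frequency table."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "gene_counts" in report:
        pd.DataFrame(report["gene_counts"]).to_csv(
            outdir / "gene_counts.tsv", sep="\t"
        )
    if "partition" in report:
        pd.Series(report["partition"]).rename("n_peaks").to_csv(
            outdir / "overlap_partition.tsv", sep="\t"
        )
    if "motif_table" in report:
        pd.DataFrame(report["motif_table"]).to_csv(
            outdir / "motif_frequency.tsv", sep="\t", index=False
        )
    if "signal_summaries" in report:
        pd.DataFrame(report["signal_summaries"]).T.to_csv(
            outdir / "signal_summary.tsv", sep="\t"
        )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the pipeline and return the run report (also written to
    ``outdir/report.json`` and ``report.txt``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": config.simulation.seed}
    spec = MotifSpec(config.motif)

    external = config.peaks_a_path is not None and config.peaks_b_path is not None
    fragments = {}
    peaksets: dict[str, PeakSet] = {}

    if external:
        genome = read_fasta(config.genome_path) if config.genome_path else None
        genes = (
            bed_to_genes(read_bed(config.genes_path)) if config.genes_path else None
        )
        peaks_a = read_peak_table(config.peaks_a_path, dialect=config.peak_dialect)
        peaks_b = read_peak_table(config.peaks_b_path, dialect=config.peak_dialect)
        report["peaks"] = {"n_peaks_A": len(peaks_a), "n_peaks_B": len(peaks_b)}
        manifest = None
    else:
        experiment = simulate_experiment(config.simulation)
        genome, manifest, genes = (
            experiment.genome, experiment.manifest, experiment.genes,
        )
        lengths = genome.lengths
        write_fasta(genome, outdir / "genome.fa")
        write_bed(genes_to_bed(genes), outdir / "genes.bed")
        write_bed(manifest.to_bed(), outdir / "truth_sites.bed")
        manifest.to_json(outdir / "truth.json")

        report["processing"] = {}
        for (line, kind), reads in experiment.libraries.items():
            write_alignments(reads, outdir / f"reads_{line}_{kind}.bed6q")
            frags, track, counts = process_reads(reads, config.processing, lengths)
            fragments[(line, kind)] = frags
            report["processing"][f"{line}_{kind}"] = counts
            if kind == "chip":
                write_bedgraph(track, outdir / f"coverage_{line}_chip.bedgraph")

        report["peaks"] = {}
        for line in ("A", "B"):
            ps = peak_calling.call_peaks(
                fragments[(line, "chip")], fragments[(line, "input")],
                config.peaks, lengths, label=line,
            )
            peaksets[line] = ps
            write_bed(peaks_to_bed(ps), outdir / f"peaks_{line}.bed")
            report["peaks"][f"n_peaks_{line}"] = len(ps)
            report["peaks"][f"library_depth_{line}"] = ps.library_depth
        report["truth_evaluation"] = {
            line: evaluate_against_truth(
                peaksets[line], manifest, line,
                tolerance=config.peaks.min_peak_distance,
            )
            for line in ("A", "B")
        }
        peaks_a = list(peaksets["A"])
        peaks_b = list(peaksets["B"])

    # ---- compare: overlap partition, TSS annotation, gene windows ----
    part = overlap_partition(peaks_a, peaks_b)
    report["partition"] = part.sizes()
    assignments = {}
    if genes is not None:
        table = gene_window_table(
            peaks_a, peaks_b, genes, windows=config.gene_windows, labels=("A", "B")
        )
        report["gene_counts"] = json.loads(table.to_json())
        edges = list(config.tss_bin_edges)
        report["tss_histograms"] = {}
        for line, peaks in (("A", peaks_a), ("B", peaks_b)):
            assignments[line] = nearest_tss(peaks, genes)
            counts, fracs, n_out = annotation.tss_distance_histogram(
                assignments[line], edges
            )
            report["tss_histograms"][line] = {
                "edges": edges,
                "counts": counts.tolist(),
                "fractions": fracs.tolist(),
                "out_of_range": n_out,
            }

    # ---- characterize: motif frequency and signal ----
    if genome is not None:
        groups = {
            "A_all": peaks_a,
            "A_overlapping_B": part.shared_a,
            "A_specific": part.specific_a,
            "B_all": peaks_b,
            "B_overlapping_A": part.shared_b,
            "B_specific": part.specific_b,
        }
        motif_df = stratified_motif_table(
            groups, genome, spec, both_strands=config.both_strands
        )
        report["motif_table"] = motif_df.to_dict(orient="records")

    if not external:
        report["signal_summaries"] = {}
        report["signal_curves"] = {}
        for line in ("A", "B"):
            ps = peaksets[line]
            signals = rpkm_scores(
                list(ps), fragments[(line, "chip")], ps.library_depth
            )
            with open(outdir / f"signal_{line}.tsv", "w") as fh:
                fh.write("peak\tfragment_count\trpkm\n")
                for s in signals:
                    fh.write(f"{s.peak_name}\t{s.fragment_count}\t{s.rpkm:.6g}\n")
            if signals:
                x, y = sorted_signal_curve(signals)
                report["signal_curves"][line] = {
                    "rank_fraction": np.round(x, 6).tolist(),
                    "percent_of_max": np.round(y, 4).tolist(),
                }
                summ = signal_summary(signals)
                report["signal_summaries"][line] = dataclasses.asdict(summ)
                if genes is not None and line in assignments:
                    sig_by_name = {s.peak_name: s for s in signals}
                    for gname, gpeaks in _tss_groups(
                        list(ps), assignments[line]
                    ).items():
                        group_sigs = [sig_by_name[p.name] for p in gpeaks]
                        if group_sigs:
                            report["signal_summaries"][f"{line}_{gname}"] = (
                                dataclasses.asdict(signal_summary(group_sigs))
                            )

    validate_report(report)
    render_tables(report, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    _write_text_report(report, outdir / "report.txt")
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [f"chipcompare run (seed {report.get('seed')})", ""]
    for line, counts in report.get("processing", {}).items():
        lines.append(f"library {line}: {counts}")
    for k, v in report.get("peaks", {}).items():
        lines.append(f"{k}: {v}")
    if "truth_evaluation" in report:
        for line, ev in report["truth_evaluation"].items():
            lines.append(
                f"line {line}: recall {ev['recall']:.3f} "
                f"precision {ev['precision']:.3f} ({ev['n_peaks']} peaks, "
                f"{ev['n_sites']} sites)"
            )
    if "partition" in report:
        lines.append(f"overlap partition: {report['partition']}")
    for row in report.get("motif_table", []):
        lines.append(
            f"motif {row['group']}: {row['n_with_motif']}/{row['n_peaks']} "
            f"({row['percent']}%)"
        )
    for grp, s in report.get("signal_summaries", {}).items():
        lines.append(
            f"signal {grp}: mean {s['mean']:.2f} median {s['median']:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")
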