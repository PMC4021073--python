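"""Synthetic ChIP-seq experiment generator with full ground truth.

Emulates, at desk scale, a two-cell-line transcription-factor ChIP-seq
study: a small multi-chromosome genome; point-source binding sites that are
shared between the two lines or specific to one; a controllable probability
that a site carries a concrete WGATAR instance; occupancy-scaled ChIP
fragment sampling at sonication sizes 200-400 bp over a uniform background;
matched input (unchipped) libraries; 36-base single-end reads with mean
base qualities (a configurable fraction failing the mean<20 filter) and
verbatim PCR duplicates.

Everything is reproducible from the config seed; independent RNG streams
are spawned per stage and per library so regenerating one library never
perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .annotation import Gene, GeneModel
from .formats_io import BedInterval, GenomeSequence, ReadAlignment

Membership = Literal["shared", "A_only", "B_only"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults define the standard desk-scale benchmark: a 2 x 2.5 Mb genome
    with 300 shared, 150 A-specific and 450 B-specific sites (line B is the
    more promiscuously bound of the two), motif-planting probability 0.72,
    mean occupancy 40
    ChIP fragments per site, background 5 fragments/kb, 10% duplicates and
    5% low-quality reads.
    """

    n_contigs: int = 2
    contig_length: int = 2_500_000
    gc_fraction: float = 0.5
    n_shared_sites: int = 300
    n_specific_sites_a: int = 150
    n_specific_sites_b: int = 450
    p_motif_plant: float = 0.72
    occupancy_mean: float = 40.0
    occupancy_rel_spread: float = 0.4  # per-site occupancy ~ U(1-s, 1+s) * mean
    occupancy_scale_b: float = 4.0  # line-B per-site occupancy multiplier
    fragment_length_range: tuple[int, int] = (200, 400)
    read_length: int = 36
    background_rate: float = 5.0  # fragments per kb, ChIP and input alike
    duplicate_rate: float = 0.1
    lowq_rate: float = 0.05
    n_genes: int = 300
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.p_motif_plant, self.duplicate_rate, self.lowq_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")
        lo, hi = self.fragment_length_range
        if not (self.read_length < lo <= hi < self.contig_length):
            raise ValueError(
                "fragment_length_range must lie within (read_length, contig_length)"
            )
        for n in (
            self.n_contigs, self.n_shared_sites, self.n_specific_sites_a,
            self.n_specific_sites_b, self.n_genes,
        ):
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.occupancy_mean < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.occupancy_rel_spread < 1.0:
            raise ValueError("occupancy_rel_spread must be in [0, 1)")

    @property
    def max_fragment_length(self) -> int:
        return self.fragment_length_range[1]

    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]


@dataclass(frozen=True)
class Site:
    contig: str
    position: int
    membership: Membership
    motif_planted: bool
    occupancy: float  # expected ChIP fragments in line A; line B scales this

    def active_in(self, cell_line: str) -> bool:
        return self.membership == "shared" or self.membership == f"{cell_line}_only"


@dataclass
class TruthManifest:
    """Ground truth of the planted experiment, for parameter-recovery tests."""

    sites: list[Site]

    def sites_for(self, cell_line: str) -> list[Site]:
        return [s for s in self.sites if s.active_in(cell_line)]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"sites": [asdict(s) for s in self.sites]}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(sites=[Site(**s) for s in data["sites"]])

    def to_bed(self) -> list[BedInterval]:
        return [
            BedInterval(
                s.contig, s.position, s.position + 1,
                name=f"{s.membership}{'_motif' if s.motif_planted else ''}_{i}",
                score=s.occupancy,
            )
            for i, s in enumerate(self.sites)
        ]


# RNG stream labels: one spawned child per (stage) and per (library)
_STREAMS = {"genome": 0, "sites": 1, "genes": 2}
_LIB_STREAMS = {("A", "chip"): 10, ("A", "input"): 11,
                ("B", "chip"): 12, ("B", "input"): 13}


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. nucleotide genome at the configured GC fraction."""
    rng = _rng(config, _STREAMS["genome"])
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for name in config.contig_names():
        draws = rng.choice(_BASES, size=config.contig_length, p=p)
        contigs[name] = draws.tobytes().decode("ascii")
    return GenomeSequence(contigs)


_W = "AT"  # IUPAC W
_R = "AG"  # IUPAC R


def plant_sites(
    genome: GenomeSequence, config: SimulationConfig
) -> tuple[GenomeSequence, TruthManifest]:
    """Place binding sites and write concrete WGATAR instances.

    Sites keep a margin of at least the maximum fragment length from the
    contig ends and a minimum spacing of twice the maximum fragment length,
    so neighbouring sites never merge into one fragment pileup.  A site with
    the motif-planted flag gets a 6-mer centred at its position with W and R
    resolved uniformly at random; unplanted sites leave the sequence alone.
    """
    rng = _rng(config, _STREAMS["sites"])
    n_total = (
        config.n_shared_sites + config.n_specific_sites_a + config.n_specific_sites_b
    )
    names = config.contig_names()
    margin = config.max_fragment_length
    spacing = 2 * config.max_fragment_length

    # allocate site counts to contigs proportionally
    lengths = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    alloc = np.floor(n_total * lengths / lengths.sum()).astype(int)
    for i in range(n_total - alloc.sum()):
        alloc[i % len(alloc)] += 1

    positions: list[tuple[str, int]] = []
    for name, k in zip(names, alloc):
        L = len(genome.contigs[name])
        usable = L - 2 * margin - (k - 1) * spacing if k else 0
        if k and usable <= 0:
            raise ValueError(
                f"contig {name} ({L} bp) too small for {k} sites at spacing {spacing}"
            )
        if k == 0:
            continue
        offsets = np.sort(rng.integers(0, usable, size=k))
        pos = margin + offsets + spacing * np.arange(k)
        positions.extend((name, int(x)) for x in pos)

    memberships = (
        ["shared"] * config.n_shared_sites
        + ["A_only"] * config.n_specific_sites_a
        + ["B_only"] * config.n_specific_sites_b
    )
    memberships = [memberships[i] for i in rng.permutation(n_total)]
    planted = rng.random(n_total) < config.p_motif_plant
    s = config.occupancy_rel_spread
    occupancy = config.occupancy_mean * rng.uniform(1 - s, 1 + s, size=n_total)

    mutable = {name: bytearray(seq, "ascii") for name, seq in genome.contigs.items()}
    sites: list[Site] = []
    for i, (contig, pos) in enumerate(positions):
        if planted[i]:
            word = _W[rng.integers(2)] + "GATA" + _R[rng.integers(2)]
            mutable[contig][pos - 3: pos + 3] = word.encode("ascii")
        sites.append(
            Site(contig, pos, memberships[i], bool(planted[i]), float(occupancy[i]))
        )
    planted_genome = GenomeSequence(
        {name: bytes(buf).decode("ascii") for name, buf in mutable.items()}
    )
    return planted_genome, TruthManifest(sites)


def generate_genes(genome: GenomeSequence, config: SimulationConfig) -> GeneModel:
    """Uniformly placed single-TSS gene model over the synthetic genome."""
    rng = _rng(config, _STREAMS["genes"])
    names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    for i in range(config.n_genes - alloc.sum()):
        alloc[i % len(alloc)] += 1
    genes: list[Gene] = []
    gid = 0
    for name, k in zip(names, alloc):
        tss = np.sort(rng.integers(0, len(genome.contigs[name]), size=k))
        strands = rng.integers(0, 2, size=k)
        for t, s in zip(tss, strands):
            genes.append(Gene(f"gene{gid:05d}", name, "+-"[s], int(t)))
            gid += 1
    return GeneModel(genes)


def simulate_library(
    genome: GenomeSequence,
    manifest: TruthManifest,
    cell_line: Literal["A", "B"],
    kind: Literal["chip", "input"],
    config: SimulationConfig,
) -> list[ReadAlignment]:
    """Simulate one sequencing library as single-end reads.

    ChIP libraries draw, per site active in the cell line, Poisson(occupancy)
    fragments whose midpoints are jittered uniformly within +/- half the
    fragment length around the site and whose lengths are uniform in the
    sonication range; line B's occupancies are scaled by
    ``occupancy_scale_b``.  Background fragments arrive uniformly at
    ``background_rate`` per kb in ChIP and input alike; input has no
    site-driven fragments.  Each fragment yields one read from a uniformly
    chosen end (the 5' end of the + or - strand).  Mean base qualities are
    uniform in [25, 40] for passing reads and [2, 19.5] for the ``lowq_rate``
    fraction, so the quality-filter boundary is unambiguous.  Duplicates are
    verbatim re-emissions of existing reads (same position, strand and
    quality) appended at ``duplicate_rate``.
    """
    if (cell_line, kind) not in _LIB_STREAMS:
        raise ValueError(f"unknown library {(cell_line, kind)!r}")
    rng = _rng(config, _LIB_STREAMS[(cell_line, kind)])
    lo, hi = config.fragment_length_range
    scale = config.occupancy_scale_b if cell_line == "B" else 1.0

    frag_contig: list[str] = []
    starts_all: list[np.ndarray] = []
    lens_all: list[np.ndarray] = []

    if kind == "chip":
        for site in manifest.sites_for(cell_line):
            n = rng.poisson(site.occupancy * scale)
            if n == 0:
                continue
            lens = rng.integers(lo, hi + 1, size=n)
            jitter = rng.integers(-(lens // 2), lens // 2 + 1)
            mids = site.position + jitter
            starts = mids - lens // 2
            clen = len(genome.contigs[site.contig])
            starts = np.clip(starts, 0, None)
            lens = np.minimum(lens, clen - starts)
            frag_contig.extend([site.contig] * n)
            starts_all.append(starts)
            lens_all.append(lens)

    for name, seq in genome.contigs.items():
        clen = len(seq)
        n_bg = rng.poisson(config.background_rate * clen / 1000.0)
        if n_bg == 0:
            continue
        lens = rng.integers(lo, hi + 1, size=n_bg)
        starts = rng.integers(0, clen - lens + 1)
        frag_contig.extend([name] * n_bg)
        starts_all.append(starts)
        lens_all.append(lens)

    if not frag_contig:
        return []
    starts = np.concatenate(starts_all)
    lens = np.concatenate(lens_all)
    n = len(starts)

    plus = rng.integers(0, 2, size=n).astype(bool)
    read_starts = np.where(plus, starts, starts + lens - config.read_length)
    read_starts = np.clip(read_starts, 0, None)

    lowq = rng.random(n) < config.lowq_rate
    quals = np.where(
        lowq, rng.uniform(2.0, 19.5, size=n), rng.uniform(25.0, 40.0, size=n)
    )

    reads = [
        ReadAlignment(
            contig=frag_contig[i],
            start=int(read_starts[i]),
            length=config.read_length,
            strand="+" if plus[i] else "-",
            mean_quality=float(quals[i]),
        )
        for i in range(n)
    ]

    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.integers(0, n, size=n_dup)
        reads.extend(reads[i] for i in dup_idx)
    return reads


@dataclass
class SyntheticExperiment:
    """Everything the desk-scale benchmark produces, with ground truth."""

    config: SimulationConfig
    genome: GenomeSequence
    manifest: TruthManifest
    genes: GeneModel
    libraries: dict[tuple[str, str], list[ReadAlignment]] = field(default_factory=dict)


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Generate genome, sites, genes and all four libraries (A/B x chip/input)."""
    genome = generate_genome(config)
    genome, manifest = plant_sites(genome, config)
    genes = generate_genes(genome, config)
    libraries = {
        (line, kind): simulate_library(genome, manifest, line, kind, config)
        for line in ("A", "B")
        for kind in ("chip", "input")
    }
    return SyntheticExperiment(config, genome, manifest, genes, libraries)
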