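"""Shared fixtures: tiny configurations for fast unit tests and one
session-scoped run of the full default benchmark reused by the pipeline
and acceptance tests."""

from __future__ import annotations

import dataclasses

import pytest

import chipcompare as cc


@pytest.fixture(scope="session")
def tiny_config() -> cc.SimulationConfig:
    """A miniature experiment (1 x 150 kb, 50 sites) for fast end-to-end
    exercises."""
    return cc.SimulationConfig(
        n_contigs=1,
        contig_length=150_000,
        n_shared_sites=20,
        n_specific_sites_a=10,
        n_specific_sites_b=20,
        n_genes=30,
        seed=7,
    )


@dataclasses.dataclass
class BenchmarkRun:
    config: cc.SimulationConfig
    experiment: object
    fragments: dict
    peaksets: dict
    partition: cc.OverlapPartition


@pytest.fixture(scope="session")
def default_run() -> BenchmarkRun:
    """The standard desk-scale benchmark (2 x 2.5 Mb, 900 sites, seed 1):
    simulate, process all four libraries, call peaks in both lines and
    partition them.  Computed once per session."""
    config = cc.SimulationConfig()
    experiment = cc.simulate_experiment(config)
    lengths = experiment.genome.lengths
    params = cc.ProcessingParams()
    fragments = {
        key: cc.process_reads(reads, params, lengths)[0]
        for key, reads in experiment.libraries.items()
    }
    peaksets = {
        line: cc.call_peaks(
            fragments[(line, "chip")],
            fragments[(line, "input")],
            cc.PeakCallParams(),
            lengths,
            label=line,
        )
        for line in ("A", "B")
    }
    partition = cc.overlap_partition(list(peaksets["A"]), list(peaksets["B"]))
    return BenchmarkRun(config, experiment, fragments, peaksets, partition)
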