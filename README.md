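# chipcompare

Comparative analysis of transcription-factor ChIP-seq experiments in two
samples (e.g. two cell lines), built as a tested, reusable pipeline:

* **read processing** — mean-base-quality filtering (Phred < 20 removed),
  single-end PCR-duplicate removal keyed on (contig, 5′ position, strand),
  3′ extension of every read to the expected sonication fragment size
  (180 bp), and bedGraph coverage tracks;
* **peak calling** — an explicit, input-normalized point-source caller:
  fragment-midpoint counts in sliding 180 bp windows, greedy local-maximum
  summit selection, fold-enrichment filters against the depth-normalized
  input and the local background, and a Poisson upper-tail test at
  λ = max(normalized input, local expectation, global expectation);
* **comparison** — two-sample overlap partitioning (≥ 1 bp shared base,
  half-open semantics), nearest-TSS assignment with signed
  midpoint-to-TSS distances, TSS-distance histograms, and gene counts
  within ±10/±50 kb of a peak border (inclusive);
* **characterization** — per-peak RPKM (fragments per kb of peak per
  million library fragments), sorted signal curves, quantile summaries,
  and the frequency of an IUPAC degenerate motif (default **WGATAR**, the
  canonical GATA recognition element; reverse complement YTATCW) scanned on
  both strands, stratified by peak class;
* **a synthetic-data generator** — a small multi-chromosome genome with
  planted point-source binding sites (shared between the two simulated
  lines or line-specific), a controllable probability that a site carries a
  concrete WGATAR instance, occupancy-scaled ChIP fragment sampling at
  sonication sizes 200–400 bp, matched input libraries, 36-base single-end
  reads with qualities, and PCR duplicates — with a full truth manifest, so
  every stage is verifiable without any download.

Intended users: people building or validating regulatory-genomics analysis
code who need a fully specified, oracle-testable version of the standard
"filter → dedup → extend → call → compare → characterize" ChIP-seq recipe,
at desk scale.

## Worked example

Run the standard synthetic benchmark (two simulated cell lines over a
2 × 2.5 Mb genome; 300 shared + 150 A-specific + 450 B-specific sites,
mean occupancy 40 fragments/site, background 5 fragments/kb, 10%
duplicates, 5% low-quality reads, seed 1):

```bash
chipcompare run --out-dir runs/demo          # or: python -m chipcompare run ...
cat runs/demo/report.txt
```

which prints (abridged):

```
library A_chip: {'reads_in': 47655, 'removed_low_quality': 2537, 'duplicates_removed': 4690, 'fragments': 40428}
n_peaks_A: 444
n_peaks_B: 739
line A: recall 0.982 precision 1.000 (444 peaks, 450 sites)
line B: recall 0.985 precision 1.000 (739 peaks, 750 sites)
overlap partition: {'shared_a': 293, 'specific_a': 151, 'shared_b': 292, 'specific_b': 447}
motif A_all: 342/444 (77.0%)
motif B_all: 592/739 (80.1%)
signal A: mean 3477.55 median 3435.46
signal B: mean 3776.56 median 3773.79
```

Reading these numbers: the caller recovers 98% of planted sites with no
false calls; the overlap partition recovers the planted 300/150/450
shared/specific structure; ~77–80% of peaks contain a WGATAR instance —
the 72% planting probability plus chance hits in 180 bp of background
sequence; and line B, simulated with higher per-site occupancy, keeps
higher depth-normalized RPKM summaries. Per-stage artifacts (FASTA, BED,
bedGraph, TSV tables, JSON report) are written under `runs/demo/`.

The stages are also available individually (`chipcompare simulate`,
`process`, `callpeaks`, `compare`, `characterize`) and as plain library
functions (`chipcompare.call_peaks`, `overlap_partition`, `nearest_tss`,
`peak_motif_fraction`, `rpkm_scores`, ...). Externally called peak sets
(BED or published supplementary-style tables with 1-based inclusive
coordinates) can be fed straight into the comparison and motif stages.

## Layout

```
src/chipcompare/
  formats_io.py        FASTA / SAM / BED6q / bedGraph / peak-table IO
  synthetic.py         genome + site + library simulator with truth manifest
  read_processing.py   quality filter, dedup, 3' extension, coverage
  peak_calling.py      input-normalized point-source peak caller
  annotation.py        overlap partition, nearest TSS, gene windows
  characterization.py  motif frequency, RPKM, curves, summaries
  pipeline.py          orchestration, run report, table rendering
  cli.py               click command-line interface
docs/methods.md        model, parameters, numerical choices, limitations
```
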