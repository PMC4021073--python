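# Methods

## The analysis model

The pipeline treats a transcription-factor ChIP-seq experiment as a set of
mapped single-end reads whose local density, relative to a matched input
(unchipped) library, identifies point-source binding events. All genomic
coordinates inside the package are 0-based half-open; SAM input (1-based)
and 1-based-inclusive peak tables are converted once, at the IO boundary.

### Read processing

Stages run in a fixed order: quality filter → duplicate removal → 3′
extension → coverage.

* **Quality filter.** A read is removed iff its mean Phred base quality is
  strictly below `min_mean_quality` (default 20); a read at exactly the
  threshold is kept. Quality strings are decoded as Phred+33 by default,
  with a `qual_offset` escape hatch for older Illumina encodings.
* **Duplicate removal.** Reads sharing (contig, 5′ alignment position,
  strand) — the start for + strand reads, the end for − strand reads — are
  presumed PCR duplicates and collapsed to one, emulating single-end
  MarkDuplicates semantics. The first read in (contig, start, strand) sort
  order is retained; qualities are not compared, because only positions
  survive into later stages. Note this also removes *genuine* distinct
  fragments that happen to share a 5′ position, which matters at very
  dense sites (see Limitations).
* **Extension.** Each read is projected to `fragment_length` bases
  (default 180, the expected average genomic fragment size) in its 3′
  direction and clipped to the contig. Exactly one fragment per read.
* **Coverage.** Per-base fragment depth, run-length encoded with
  zero-depth runs omitted (bedGraph). The conservation law
  Σ depth×width = Σ fragment lengths holds exactly and is tested.

### Peak calling

The caller is a deliberately explicit stand-in for factor-style callers,
specified so that every decision is testable:

1. ChIP fragment midpoints are counted in sliding windows of `peak_size`
   (default 180 bp) at stride 1. Membership is by midpoint, not overlap,
   so adjacent candidates never double-count a fragment. An optional
   per-position midpoint cap (`tags_per_position_cap`, default 0 =
   uncapped) applies to ChIP and input alike.
2. Candidate summits are strict local maxima of the window profile at the
   `min_peak_distance` scale: a position qualifies only if no higher
   window lies within ±(`min_peak_distance` − 1). Candidates are accepted
   greedily in decreasing window count with a `min_peak_distance`
   exclusion zone; among equal heights the leftmost wins. The local-maximum
   requirement is essential: without it, the shoulders of strong pileups
   (extended-fragment midpoints spread over several hundred bases when
   sonication fragments are longer than the extension length) yield
   satellite peaks ~one peak-width away from real summits.
3. The peak interval is [summit − `peak_size`/2, summit + `peak_size`/2);
   its tag count is the window count at the summit. The input expectation
   for the peak window is estimated from at least `min_input_window`
   (default 2000) bases centered on the summit, scaled to the peak width
   and to the ChIP/input depth ratio. Estimating input from the narrow
   peak window alone would make the input test a coin flip whenever the
   ChIP library is much deeper than the input (a raw input count of 3
   where 0.9 is expected, scaled by a depth ratio of 3+, fails a 4-fold
   test even at strongly bound sites).
4. A candidate is retained when tag/max(input, 0.5) ≥ `fold_over_input`
   (default 4), tag/max(local, 0.5) ≥ `fold_over_local` (default 4), and
   the Poisson upper tail P(X ≥ tag) at
   λ = max(input, local, global expectation) is ≤ `pvalue_threshold`
   (default 1e-4). The local expectation is the mean ChIP midpoint rate
   within ±10 peak sizes of the summit, *including* the peak region; this
   conservative choice lets a borderline background spike raise its own λ
   and suppresses residual shoulder candidates. The tail is computed with
   the Poisson survival function, never 1 − CDF.

Specificity at these defaults: on a site-free 5 Mb background at
5 fragments/kb, a 7-tag window at λ ≈ 0.9 sits exactly at the p = 1e-4
boundary and the genome offers ~1.4 × 10⁴ candidate regions, so up to ~1
false call per 2.5 Mb contig can survive; at p ≤ 1e-6 the expected
genome-wide false count is ~0.03. There is no FDR correction by design
(out of scope); users wanting genome-scale specificity should tighten
`pvalue_threshold` accordingly.

### Comparison and annotation

* **Overlap partition.** A peak is *shared* iff it overlaps a peak of the
  other sample by ≥ 1 bp (half-open semantics: abutting intervals do not
  overlap). Each set partitions exactly into shared + specific; both
  per-set shared counts are reported, since they need not be equal.
* **Nearest TSS.** Each peak is assigned to the gene minimizing the
  absolute midpoint-to-TSS distance, ties broken by lexicographically
  smaller gene id. The signed distance is oriented by gene strand
  (negative = peak upstream of the TSS). Histograms use half-open bins,
  default 1 kb steps within ±10 kb (configurable); out-of-range mass is
  reported separately.
* **Gene windows.** Deliberately a *different* distance: a gene counts as
  associated at window k iff some peak's border-to-TSS distance — the gap
  between the TSS and the nearest covered peak base, 0 if the TSS lies
  inside the peak — is ≤ k (inclusive). Genes are counted once regardless
  of peak multiplicity, and the common-gene count across samples is the
  set intersection. Both conventions coexist because published analyses of
  this kind use midpoint distances for histograms but border distances for
  gene tables.

### Characterization

* **Motif frequency.** The IUPAC motif (default WGATAR) is compiled to a
  regex over concrete A/C/G/T character classes; genome N matches nothing,
  not even the motif code N. Both strands are scanned by default (the
  motif is non-palindromic and the factor binds double-stranded DNA); a
  single-strand mode exists for sensitivity analysis. A peak "contains"
  the motif iff at least one match lies entirely inside the peak interval.
* **RPKM.** fragment_count / (peak length in kb) / (library depth in
  millions), with fragment membership by midpoint and depth = post-dedup
  fragment count. Invariant under uniform duplication of the library.
* **Curves and summaries.** Sorted signal curves report percent of the
  per-sample maximum against rank fraction; summaries report mean, median
  and the 5/25/75/95 percentiles using linear interpolation between order
  statistics (numpy's default), stated here because plotting packages
  differ.

## The synthetic experiment

The generator emulates the study design the pipeline targets: two cell
lines sharing part of their binding repertoire, sequenced as 36-base
single-end reads from 200–400 bp sonication fragments, with matched input
libraries.

Defaults (the standard benchmark): 2 contigs × 2.5 Mb of i.i.d. sequence
at GC 0.5; 300 shared + 150 A-specific + 450 B-specific sites placed with
≥ 400 bp margin from contig ends and ≥ 800 bp spacing; motif-planting
probability 0.72 (a concrete WGATAR instance, W/R uniform, written at the
site center); per-site occupancy = 40 × Uniform(0.6, 1.4) expected ChIP
fragments; background 5 fragments/kb in ChIP and input alike; duplicate
rate 0.1 (verbatim re-emissions, so duplicates share position, strand and
quality); low-quality rate 0.05 with mean qualities drawn from [2, 19.5]
vs [25, 40] for passing reads, keeping the filter boundary unambiguous;
300 uniformly placed single-TSS genes; seed 1.

Choices worth explaining:

* **Fragment midpoint jitter** is uniform within ± half the fragment
  length (no binding-profile shape is assumed). Each fragment yields one
  read from a uniformly chosen end. After 3′ extension to 180 bp, the
  midpoints of *extended* fragments are bimodal at ±(L/2 − 90) around the
  site — up to ±110 for 400 bp fragments — which is why summit-accuracy
  tolerances are stated as (max fragment − extension)/2 plus sampling
  noise, and why the local-maximum candidate rule in the caller matters.
* **Line-B occupancy scale = 4.** The per-site occupancy multiplier for
  line B is a free parameter. Because library depth is the sum of
  occupancies, per-million normalization cancels most of the scale
  (mean-RPKM ratio B/A = s·(450·occ + bg)/(750·s·occ + bg), further eroded
  by duplicate-collision losses at B's dense sites); s = 4 yields a
  depth-normalized RPKM excess of ~7–12% in mean and median across seeds —
  a strong per-site effect whose visible normalized excess is modest.
* **RNG streams.** Independent generators are spawned per stage and per
  (cell line, library kind) from the config seed, so regenerating one
  library never perturbs another and identical configs are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: base-level sequencing errors, mappability and
repeat structure, chromatin-accessibility-biased backgrounds, fragment-size
selection skew, diploid genotypes, and binding-profile shape beyond
uniform jitter. Parameter-recovery results (recall ≈ 0.98,
precision ≈ 1.0) characterize the pipeline's correctness on its own model,
not expected performance on real libraries.

## Degenerate inputs and tie-breaks

Empty peak groups render as NA percentages; empty assignment lists give
all-zero histograms; a constant signal vector gives a flat curve at 100%;
single-signal curves put x = 0. Equal-height summits resolve leftmost;
equal-distance TSS ties resolve to the smaller gene id; duplicate-read
retention follows sort order. An empty input library is an error unless
the input fold test is explicitly disabled.

## Problem sizes

The standard benchmark (5 Mb, ~260k reads across four libraries) runs in a
few seconds; the test suite, including brute-force oracle comparisons on
hundreds of randomized instances and a full benchmark run, completes in
well under a minute. These sizes were chosen so that exhaustive oracles
(all-pairs interval checks, per-position motif enumeration, term-by-term
Poisson sums) remain exact and fast.

## Known limitations

* The caller is not a bit-exact reimplementation of any published tool;
  externally called peak sets can be imported instead.
* Deduplication at very dense sites removes genuine fragments sharing a 5′
  position, biasing strong-site tag counts downward (~10% at occupancy
  ≈ 160 fragments/site in the benchmark's line B).
* No FDR control; the per-candidate Poisson threshold is genome-size
  agnostic.
* The two shared-peak counts of the overlap partition can differ when
  peaks merge across samples; both are reported and consumers should not
  assume equality.
* Reproducing the published comparison tables this pipeline reimplements
  requires the study's released supplementary peak files and an hg19
  reference, which must be supplied externally (`data/supplementary/`);
  the loaders and computations are in place.
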