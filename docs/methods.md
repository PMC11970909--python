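# Methods

## Coordinates and interval arithmetic

All genomic spans are BED-convention 0-based half-open intervals;
chromosome names compare by exact string match (no `chr` aliasing). The
overlap of `[a1,a2)` and `[b1,b2)` on the same chromosome is
`max(0, min(a2,b2) − max(a1,b1))`. Set-vs-set queries use per-chromosome
interval trees; fragment-vs-window counting uses a sorted-array counting
identity — for windows at least `m` bp wide,
`count = #{fragments with start ≤ win_end − m} − #{fragments with end < win_start + m}`
over fragments of length ≥ `m` — which scales to the multi-million-fragment
libraries the simulator emits. Both paths are checked against all-pairs
brute-force oracles in the test suite.

## Promoters, RPKM and chromatin states

The TSS is strand-aware (`tx_start` on `+`, `tx_end` on `−`); the promoter
is TSS ± 2 kb (configurable halfwidth), clipped at chromosome edges with
the clipped length used in the RPKM denominator. A fragment counts toward a
window on ≥ 1 bp overlap (configurable), and may count toward several
windows. RPKM = `count / ((L/10³)·(N/10⁶))` with `N` the library's total
mapped fragments — the conventional definition; in-window totals would
break cross-sample comparability, so they are not used.

State clustering runs Lloyd's k-means (k = 4 by default) on
log2(RPKM+1)-transformed H3K4me3/H3K27me3 columns. The transform
stabilizes the variance of high-signal promoters; signals are deliberately
*not* z-scored, so the two marks keep their natural scales (both choices
are exposed). Restart `i` of `n_init = 10` is seeded `seed + i` and the
lowest within-cluster sum of squares wins, making the fit deterministic
given `(seed, n_init)` and the best-of-restarts contract directly testable.
Clusters are re-indexed by descending H3K4me3 centroid; with k = 4 the two
highest-K4 clusters become `K4_high_A`/`K4_high_B`, the higher-K27
remainder `K27_high`, the last `both_low`. Centroid ties break by cluster
index. Genes with zero signal in both marks are retained — they are what
populates the both-low state. Expression summaries per state exclude genes
without an expression value; nothing is imputed.

## Domain breadth and the differential call

A gene's H3K4me3 domain is built by merging peaks genome-wide (gaps ≤
`merge_gap`, default 0, i.e. touching peaks join) and taking the total span
of merged blocks overlapping the promoter window. The width thresholds are
applied literally: broad strictly above 5 kb, narrow strictly below 1 kb,
medium closed on both ends (so 1 000 and 5 000 are medium). BD calling
flags exactly `ceil(fraction·N)` domains (default fraction 0.05) with ties
at the cutoff broken by (width desc, chrom, start). The >5 kb class and the
top-5 % BD flag are kept as separate fields and never conflated.

Differential signal quantifies both genotypes over the same WT-derived
domain coordinates, so the comparison is symmetric on fixed spans. The
reduced call is `log2((RPKM_KO+ε)/(RPKM_WT+ε)) ≤ −log2(1.5)` with
pseudocount ε = 0.1; both threshold and ε are parameters and are echoed in
output headers. The BD-reduced gene set is the intersection of the BD flag
and the reduced call.

## Binding sets, Venn counts and fractions

Transcription-factor binding uses gene-or-promoter overlap ("covered by a
binding site"); H3K4me3 promoter enrichment uses promoter-only overlap and
defaults to ≥ 1 peak (an RPKM-quantile alternative exists). A peak may be
assigned to several genes — gene-set membership, not 1:1 nearest-TSS
assignment, is what the overlap analyses consume. Venn regions are exact
set algebra over an explicit universe (membership outside the universe is
an error). Conditional fractions force the numerator conjunction on top of
the denominator, so numerator ⊆ denominator holds by construction; report
strings round percentages half-up while tables keep full precision.

## Methylation summaries

Per-CpG levels are always recomputed from counts (the percentage column of
coverage files is checked and logged, never trusted). Zero-coverage rows
drop with a logged count. Classes are non-exclusive — a promoter CpG inside
a CGI counts in both — except genebody/intergenic, which are complementary
by construction, giving the conservation identity: the coverage-weighted
combination of their means equals the coverage-weighted global mean. The
default estimator is the unweighted mean of per-CpG levels; the pooled
Σmeth/Σtotal estimator and a minimum-coverage filter (default 1; 5 is a
reasonable choice for real libraries) are available. Because the gene model
carries no CDS records, UTR intervals (like CGIs and repeats) are direct
inputs to the element map rather than derived.

## TCR clonotypes

"Top expression" is read as the top-1 chain per locus: the highest-UMI TRA
plus the highest-UMI TRB define one clonotype key per cell (ties break on
the lexicographically smaller CDR3). Cells missing one locus keep an `NA`
placeholder so single-chain clones can still expand; cells missing both are
dropped. Expansion (≥ 2 cells) is assessed over the whole dataset, so a
clonotype seen once in each of two clusters is expanded. The sharing matrix
defaults to the overlap coefficient with Jaccard behind a flag; empty
clonotype sets yield 0 with a logged warning.

## The synthetic-data generator

The generator emulates the statistical structure of the study conditions,
not read-level sequence:

- **Annotation.** Slot-based placement: each chromosome is divided into
  equal slots, one gene per slot with a 12 kb clear margin on each side, so
  genes, promoter windows and domains of neighbours can never collide.
  Gene length is uniform on 6–12 kb with a fixed internal layout
  (UTR5/exon/intron/UTR3 segments at set offsets from the TSS) so that
  element-level methylation means are identifiable. Packing infeasibility
  raises rather than silently overlapping.
- **States and signal.** State counts follow the configured proportions by
  exact largest-remainder apportionment (shuffled over genes), so design
  cardinalities are feasible deterministically. Promoter-window fragment
  counts are Poisson with per-state rates (defaults 800/300/4/4 for H3K4me3
  and 10/10/400/4 for H3K27me3); K4-high genes additionally carry flank
  fragments at 100 per kb across the domain outside the window. The rates
  separate the states by far more than 5 within-cluster SDs in transformed
  space, and put the null distribution of the differential log2 fold-change
  ≥ 6 SDs from the reduced-call threshold — a design calculation, made
  before measurement, that is what lets the planted overlap design be
  recovered exactly.
- **Widths and the overlap design.** Domain widths are class-conditional
  uniforms (narrow 0.2–1 kb, medium 1–5 kb, broad 5–12 kb, proportions
  0.25/0.60/0.15). When a three-way design is configured, the designed
  BD-reduced genes draw widths 14–20 kb — above every other gene — so they
  always clear the top-5 % cut; FOXP3/CXXC1 peaks are placed at the
  promoters of the designed membership sets. The full-scale design uses
  7 500 genes with K4-high proportions 0.42/0.40 (6 150 domains, 308 BDs)
  and plants 294 CXXC1∩BD-reduced genes, 283 of them FOXP3-bound. The KO
  library thins the affected genes' rates by the configured reduction
  (default 60 %); without a design, the affected set is a 20 % sample of
  the called BDs.
- **Methylome.** Each CpG is generated from one class (Beta-Binomial,
  depth 30, dispersion 0.05); CGIs and repeats sit in inter-gene gaps,
  promoter CpGs upstream of the TSS, so promoter/CGI/repeat means are pure
  while genebody and intergenic are known mixtures. The generator records
  the expected estimator mean per class (the mean of planted Beta means
  over CpGs inside the class intervals), which is what recovery tests
  compare against.
- **Repertoire.** Per cluster, `round(expansion_fraction·n)` cells belong
  to expanded clones with shifted-geometric sizes (≥ 2, p = 0.5); the rest
  are singletons with globally unique keys. New expanded clones reuse a
  clonotype from an earlier cluster with probability `sharing_rate`.
  A fraction of cells carries a decoy low-UMI TRA chain to exercise the
  top-expression rule without changing the truth.

Every generator is a pure function of the config (which carries the seed);
the demo pipeline run twice writes byte-identical files.

### What the generator does not model

Mappability/GC bias, peak-caller artefacts, fragment-length distributions,
doublets and V(D)J assembly errors, CpG density variation, biological
replicate variance, and any correlation between binding and methylation.
Passing tests therefore demonstrate the correctness and operating
characteristics of the *analysis* under the planted model, not performance
on real libraries, where class separations are weaker and the stated
sensitivities will not transfer as-is.

## Problem sizes and numerical choices

Default problem sizes (demo: 2 000 genes, ~1.7 M fragments; full-scale
overlap design: 7 500 genes, ~8 M fragments; methylome: 5 000–10 000 CpGs;
repertoire: 2 000 cells) were chosen so the whole pipeline runs in well
under a minute per stage on one CPU while keeping Monte-Carlo error far
inside the tolerances asserted in tests. Degenerate inputs raise early and
explicitly: fewer distinct points than k, empty domain cohorts, empty Venn
denominators, genes on unknown chromosomes, infeasible gene packing,
malformed BED/coverage records (with line numbers). Ties are always broken
deterministically (documented per operation), and every stochastic step is
driven by a `numpy` `Generator` seeded from the config.

## Known limitations

- The genomic-distribution classifier fixes any-overlap membership with
  promoter > exon > intron > intergenic precedence; tools differ here, so
  proportions on real data may shift relative to other annotators.
- The domain width is the *span* of promoter-overlapping merged blocks;
  measuring on raw peak calls, or capping the domain to a fixed window
  around the TSS, would shift class boundaries for fragmented peak sets.
- The co-occupancy universe (all annotated genes vs expressed genes) is an
  explicit input; fractions depend on it.
- Whether TCR expansion should be counted within a sample or across pooled
  genotypes is a study-design choice; cluster labels are carried so either
  grouping can be selected upstream.
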