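# Methods

This note documents the analysis definitions, the synthetic-data model,
the numerical choices, and the limitations of the `genebody` package. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and gene anatomy

All coordinates are 0-based, half-open (BED convention), internally and in
files. A transcript is a span plus ordered disjoint exon blocks; gene loci
are the connected components of the transcript span-overlap graph
(overlap on the intron-inclusive span, ≥1 shared bp, transitive closure).
Merging is strand-aware by default — overlapping antisense transcripts
remain separate genes, which is the biologically conservative reading —
with a `strand_aware=False` switch to reproduce strand-blind merging.
Locus ids are assigned in coordinate order, so they are deterministic
functions of the input annotation.

Derived anatomy per locus, with defaults:

| quantity | definition | default |
|---|---|---|
| TSS / TTS | single 0-based positions at the span ends, strand-aware | — |
| gene body | span trimmed by `body_trim` at both ends | 1 kb trims |
| TSS flank | oriented window around the TSS | −3 kb .. +5 kb |
| TTS flank | oriented window around the TTS | −5 kb .. +3 kb |
| introns | span minus exon union | — |

Loci no longer than `2·body_trim` (2 kb) have an empty body and are
excluded from gene-body statistics. Flank windows are clipped at
chromosome ends rather than dropping the gene; windows that contain no
covered CpG propagate as missing, never as zero. Flanks are *not* clipped
against neighbouring genes; with dense annotations a flank can therefore
overlap the next locus.

On a real genome-wide annotation this merge rule collapses transcript
catalogues to roughly two-thirds as many loci, but the exact count depends
on the frozen annotation release; no such count is asserted or tested
here.

## Methylation aggregation

A region's methylation is the **unweighted mean percent methylation of
all covered cytosines** whose position falls in the region; read coverage
is never used as a weight (an optional minimum-coverage filter, default
off, can drop shallow sites at load time). Strand-resolved cytosine
records are treated independently; CpG dyads are not collapsed. Query
regions are unioned before aggregation so no site is counted twice, which
makes the pooling identity exact: the combined mean of disjoint region
sets equals the site-count-weighted mean of the parts.

Metagene profiles lay fixed-size windows (default 100 bp) at
transcription-oriented offsets around the TSS and TTS. Per expression bin
and window the reported value is the **gene-weighted** mean (mean of
per-gene window means, missing windows dropped), not the site-weighted
mean — this matches averaging "percent methylation levels" across genes
and prevents CpG-dense genes from dominating a window. The per-bin body
value is a single untrimmed-mean over the whole body; a per-gene
length-scaled body profile is possible future work, not implemented.

Genic vs intergenic methylation is a per-CpG comparison: a site is genic
when it falls in any locus span (either strand); means are reported with
the standard error sd/√n over sites.

## Promoter activity, densities, intron partition

- CAGE cluster activity = tag count / cluster bp.
- A cluster is attached to the locus whose span contains its **midpoint**
  (floor of (start+end)/2); boundary-straddling clusters are not split. A
  strict-containment rule is available (`rule='contained'`). Within its
  locus a cluster is *canonical* when its midpoint lies within 500 bp of
  the TSS, *intronic* when the midpoint falls in an intron, else exonic.
- Assay density (Pol2, DNase) over a region set = number of tags whose
  **start position** falls in the set / total bp of the set. Counting tag
  starts gives single assignment (no double counting across adjacent
  regions), conservation and exact linearity in tag multiplicity.
- Intronic initiation level of a locus = summed tag counts of its
  intronic clusters / total intron bp. The whole-locus denominator is one
  switch away (`denominator='locus'`); the intron-bp default was chosen
  for comparability with the intron partition.
- The intron partition intersects intron space with the union of cluster
  footprints; bp conservation |initiation| + |silent| = |introns| is
  exact. Methylation of the two classes reuses the regional-methylation
  definition on each class's interval list. Intronic-promoter methylation
  uses the cluster span only, with no added flank.

## Binned regressions

Genes are sorted ascending on the ranking variable with a stable
tie-break on the gene id and split into k contiguous equal-count bins
(sizes differ by ≤1, remainder to the lowest bins; bin 1 = lowest). The
assignment is invariant to input order. Figures use k = 100 (quintiles,
k = 5, for the metagene profile). Pearson's r is computed on the ≤k
(mean_x, mean_y) bin points, missing bins skipped, with a guard requiring
≥3 usable bins; the two-sided p-value comes from the t transform with n−2
degrees of freedom. The gene-level (unbinned) correlation is also
reported for transparency, since binned and raw correlations answer
slightly different questions. No multiple-testing correction is applied;
the pipeline reports a handful of planned correlations, not a screen.

Two analysis-level conventions worth calling out:

- **Promoter-methylation trend vs expression** is computed on a 2-kb
  window centred on the TSS. The full −3 kb..+5 kb display flank reaches
  4 kb into the gene body, whose non-monotone expression relationship
  would mix into the promoter signal; the 2-kb promoter window isolates
  the monotone component. The metagene profile still shows the full
  flanks.
- **Cluster activity is binned on log2(activity)**. Activities span
  decades; rank-based bins are unchanged by the monotone transform, only
  the bin mean_x values (and hence the reported correlation's x scale)
  are affected.
- **Peak bin** of the 100-bin body-methylation curve is the argmax of an
  11-bin centred moving average (NaN-aware, shrinking at the edges). The
  bell is analytically flat near its optimum, so the raw argmax would be
  a high-variance estimate; light smoothing makes the peak location
  stable without shifting a symmetric maximum.
- In the binned Figure-3 analysis clusters are keyed by host-gene
  expression, oriented TSS offset, width and tag count rather than by
  genomic position, so tie-breaking is independent of coordinate
  orientation; mirroring the genome (see below) then leaves the result
  bit-for-bit unchanged.

The low/high expression comparison splits genes at the median by rank
(split quantile configurable); each group reports mean ± SE of body
methylation and intronic initiation. A constant expression vector is
rejected as a degenerate split.

## The synthetic-data generator

The generator emulates the statistical structure of the real tracks — it
is the quantitative instantiation of the accessibility–interference
model, not a simulation of any sequencing protocol.

Body methylation follows `M(E) = M_max·s_open(E)·s_int(E)` with Hill
terms `s_open = E^h/(E^h+K_open^h)` and `s_int = K_int^h/(K_int^h+E^h)`.
For equal Hill coefficients the peak sits at `E* = √(K_open·K_int)`
(unequal coefficients fall back to a numeric grid search). Defaults:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | study size for all end-to-end checks |
| `expression_meanlog`, `expression_sdlog` | 3.0, 0.45 (natural log) | log-normal expression; the spread keeps a density that is linear in E close enough to linear in log2 E for a strongly positive binned correlation, while spanning ~e^±1.3 around the median |
| `K_open`, `K_int`, `h_open`, `h_int` | 5, 80, 2, 2 | E* = 20 = median expression, so the bell peaks mid-distribution; h=2 keeps the peak identifiable within a few bins |
| `M_max` | 95% | peak body methylation ≈ 84%, realistic for methylated gene bodies |
| `tss_meth_max`, `tss_meth_K`, `tss_meth_decay` | 80, 20, 1.5 | promoter methylation falls logistically with log E through ~40% at the median |
| `intergenic_meth` | 10% | low baseline, well below the genic mean |
| `noise_sd` | 5 percent points | per-CpG Gaussian noise, clamped to [0, 100] |
| `cpg_spacing` | 100 bp | mean covered-CpG spacing (exponential gaps) |
| `cage_rate`, `cage_expr_K` | 3, 20 | intronic cluster count ~ Poisson(rate·E/(E+K)): initiation intensity rises, saturating, with expression |
| `meth_activity_decay` | 0.05 per percent point | cluster tag intensity ∝ exp(−λ·local m): local methylation suppresses initiation |
| `pol2_rate` | 2×10⁻⁴ tags/bp per expression unit | Pol2 count ~ Poisson(length·c·E), linear in E |
| `dhss_rate`, `K_dhss` | 0.02, 30 | DNase count with saturating link E/(E+K) |

Genes (log-normal lengths, mean 8 kb, ≥3 kb) are placed with ≥3 kb
intergenic gaps; a fifth of multi-exon genes get a second transcript
spanning all but the first exon, so merging is exercised and the merged
locus provably equals the placed gene. Methylation zones: gene spans get
the body model, an oriented promoter zone (−3 kb..+1 kb around the TSS)
overrides it with the monotone promoter model, everything else is
baseline. Intronic CAGE clusters are placed only in introns inside the
trimmed body, wholly contained with ≥1 bp margin; a canonical TSS cluster
(width 100 bp, oriented downstream from the TSS so it lies strictly
inside the span) is always emitted with activity proportional to E.

All randomness flows through a single numpy Generator keyed by the seed;
every output file carries the seed and a config hash in its header, and a
fixed seed reproduces every file byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no DNA sequence, CpG islands, or RRBS fragment
bias; no coverage-dependent measurement error; no gene-length or GC
dependence of methylation; no correlated neighbouring genes; expression
noise only through the downstream Poisson sampling, not array noise; and
one dataset, not multiple cell lines. Recovery of the planted model
demonstrates that the pipeline measures what it claims to measure, not
that the accessibility–interference model is true of any genome.

## Symmetry and determinism guarantees

Mirroring every coordinate through its chromosome (x → L−x) and swapping
strands preserves transcription orientation, so every summary statistic
is invariant and the oriented metagene profile is unchanged (the genomic
windows themselves are reversed). The test suite asserts this end to end;
it is the package's strongest internal consistency check. Width-1
methylation records make the start-position membership test an exact
mirror involution.

Pipeline runs are deterministic given inputs and parameters: tables and
the summary JSON are byte-identical across reruns, and the manifest hash
is content-addressed (parameters + input bytes, not paths).

## Problem sizes

The default end-to-end checks simulate 2,000 genes on four chromosomes
(~30 Mb, ~300k CpGs, ~700k tags), which the full pipeline processes in a
few seconds; oracle comparisons run on hundreds of small random genomes
where brute-force per-bp scans are feasible. These sizes give the binned
statistics ~20 genes per bin, enough for the sign and peak-location
checks to hold with wide margins across seeds.

## Known limitations

- BED12 only for transcripts; no GTF/GFF ingestion.
- No isoform-aware analysis; the locus is the unit throughout.
- Bin-level Pearson on 100 bins is a description of a curve, not an
  inferential model; no smoothing/loess alternative is provided.
- The intronic CAGE denominator ambiguity (intron bp vs whole-locus bp)
  is exposed as a switch rather than resolved.
- Single-dataset runs; cross-cell-line comparison is out of scope (run
  the pipeline per dataset instead).
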