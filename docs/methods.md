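# Methods

## Problem and model

`chipcross` reproduces, as a reusable pipeline, a differential histone-mark
analysis: two ChIP-seq peak sets (a treatment such as a deacetylase
overexpression, and a control) are compared to find where an active mark such
as H3K9ac was *gained* or *lost*, those per-gene region calls are intersected
with fold-change differential expression, and the resulting gene sets are
tested for term over-representation.

The inference chain is deliberately simple and set-theoretic:

1. **Peak partition.** A peak is *common* iff it overlaps (≥ 1 bp) at least
   one peak of the other condition, else *condition-specific*. Accounting is
   per peak and per condition — no merging — so the two per-condition counts
   can both exceed the size of a merged universe. Condition-specific peaks
   are the only evidence unit used downstream.
2. **Region calls.** For each gene we define a *TSS region* (the ±2 kb
   promoter window around the transcription start site) and a *gene body*
   (the gene span minus the first 2 kb downstream of the TSS, so the two
   regions are disjoint by construction). A treatment-specific peak
   overlapping a region by ≥ 1 bp makes that (gene, region) *gained*; a
   control-specific peak makes it *lost*. A gene may legitimately carry
   several calls (both regions, or both directions when opposing evidence
   exists); nothing is collapsed. No quantitative signal threshold is used —
   peak presence is the criterion, which is the only criterion a Venn-style
   intersection supports.
3. **Differential expression.** A gene is *up* when
   mean_treatment / mean_control ≥ 1.25 and *down* when the ratio ≤ 1/1.25,
   boundaries inclusive. No FDR filter by default (an optional q-value
   column and cutoff are supported). With a zero control mean and zero
   pseudocount, a positive treatment mean calls the gene up; a gene with
   both means zero is dropped.
4. **Integration.** *Peak-associated genes* are genes whose edge-to-edge gap
   to any condition-specific peak (both conditions pooled) is ≤ 20 kb,
   boundary inclusive; overlap counts as gap 0. The *common* set is
   peak-associated ∩ (up ∪ down); the *both-down* set is common genes with a
   lost call in either region that are down-regulated; the *quadrants* split
   the common set by (region × direction × sign).
5. **Enrichment.** One-sided hypergeometric upper tail
   P[X ≥ k] for X ~ Hypergeom(N, K, n), computed exactly with big-integer
   binomial sums (no normal approximation, so deep tails keep full double
   precision), Benjamini–Hochberg adjusted; terms with q < 0.05 are
   significant. The background defaults to all annotated genes.

ChIP-qPCR support implements percent input = 100 × 2^(CT_input − CT_IP),
with an optional `input_dilution_log2` correction (0 by default — useful
when only a diluted input fraction was amplified), and fold enrichment as
division by a control condition's percent input.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `promoter_up` / `promoter_down` | 2000 / 2000 | bp | TSS window for region calls, annotation and promoter profiles |
| `tss_exclusion` | 2000 | bp | removed from the gene 5' end to form the gene body (0 restores the full span) |
| `downstream_window` | 3000 | bp | Downstream feature class past the TES |
| `max_distance` | 20000 | bp | peak–gene association gap |
| `fold_threshold` | 1.25 | ratio | DEG boundary, inclusive |
| `alpha` | 0.05 | — | FDR significance cutoff |
| `bin_size` | 50 | bp | coverage bin; a standard metagene resolution |
| `flank` | 3000 | bp | half-width of TSS/TES profile windows |
| `use_summit` | true | — | feature assignment tests the narrowPeak summit base when recorded, else the whole interval |

Coordinates are 0-based half-open internally (BED convention); GTF/GFF3
1-based closed coordinates are converted at the boundary. Feature precedence
for peak annotation is Promoter > Exon > Intron > Downstream >
DistalIntergenic; UTR classes are not modelled because gene-level annotation
lacks them, and a gene without exon records counts as a single exon.
Nearest-gene distance is |summit-or-midpoint − TSS| (signed, negative
upstream in transcript orientation), whereas the 20 kb association uses
edge-to-edge gaps — the two notions serve different questions and are kept
distinct. Nearest-gene ties break to the lexicographically smaller gene id.

## Synthetic experiment and its truth table

The generator emits a complete miniature experiment — GTF annotation,
two narrowPeak sets, a bedGraph per condition, an expression table, a GMT
term map and a JSON truth table — with all randomness drawn from one seeded
generator and all coordinates integral, so output files are byte-identical
across runs and platforms.

Default design (the reference verification scenario): 50 genes of 8–15 kb on
2 chromosomes of 2.5 Mb, ≥ 60 kb intergenic gaps, 5 lost-at-TSS / 3
gained-at-TSS / 4 lost-in-body genes, 10 down and 6 up DEGs fully
overlapping the signal changes, 30 shared background peaks per condition,
planted folds 2.0 / 0.5, zero expression noise. Geometry guarantees:
specific peaks sit inside their gene's target region and extend at most
200 bp beyond the gene span, so with ≥ 60 kb gaps no specific peak comes
within 20 kb of any other gene; background peaks are placed 24 kb into
intergenic gaps with deliberately jittered interval bounds in the two
conditions, so their mutual overlap (hence "common" status) is by
construction. Unplanted expression ratios are drawn log-uniformly inside
[1/1.1, 1.1], a margin that cannot cross the 1.25 threshold at zero noise;
optional lognormal noise multiplies each condition mean.

`overlap_with_changes` is implemented direction-matched: the requested
fraction of *down* DEGs is drawn from lost-signal genes and of *up* DEGs
from gained-signal genes, capped by how many such genes exist, with the
remainder assigned to unchanged genes. (A literal "every DEG carries a
region change" is infeasible whenever planted DEGs outnumber planted
changed genes, as in the default design: 16 DEGs vs 12 changed genes.)
At full overlap this makes the expected quadrant contents exactly the
planted category memberships, which is what the closure tests assert.

The term map contains one term covering exactly the planted lost-and-down
genes plus five random 8-gene decoy terms, so the planted term must rank
first under the exact test.

Perturbations (`drop_peak`, `shift_peak`, `flip_expression`) apply one
controlled mutation, rewrite the files and update the truth table;
`shift_peak` moves a peak upstream of its gene by 30 kb by default, which
with the default ≥ 60 kb gaps strands it > 20 kb from every gene.

What the generator does **not** emulate: read-level noise and peak-shape
variation, replicate structure, library-size normalisation between the two
coverage tracks, overlapping genes and isoforms, and realistic
expression-count distributions. Passing the closure tests therefore shows
the *inference chain* is correct given peaks, coverage and expression
tables; it says nothing about upstream peak calling or quantification on
real libraries.

## Numerical and design choices

- **Interval engines.** Partition and association queries use sorted starts
  with prefix maxima of ends (O((n+m) log m)); tests compare against
  quadratic all-pairs oracles on randomized instances, and overlap
  semantics are validated exhaustively on a small coordinate axis.
- **Exact tail.** `hypergeom_upper_tail` sums exact integer binomials and
  divides once via `fractions.Fraction`, giving correctly rounded doubles
  even for tails near 1e-300; `scipy.stats.hypergeom.sf` serves as an
  independent cross-check in the tests. BH adjustment delegates to
  `statsmodels.stats.multitest.multipletests`.
- **Profiles.** bedGraph records are length-weighted into fixed bins
  (conserving value × length); profile bins are window means re-sampled
  from the track bins; rows are reversed for minus-strand genes so every
  row reads 5'→3'; windows past a chromosome edge average in zeros and the
  gene is flagged. Gene-body–rescaled metagenes are not implemented — the
  TSS- and TES-anchored matrices cover the same question without
  introducing an interpolation scheme.
- **Degenerate inputs** are errors, not silent defaults: empty intervals,
  inverted bedGraph records, overlapping bedGraph records (ambiguous
  signal), summits outside their peak, duplicate gene ids, queries not
  contained in the enrichment background.
- **Problem sizes.** The default verification scenario (50 genes, ~70 peaks,
  5 Mb of 50 bp bins) runs the full pipeline in about a second; oracle
  equivalence tests use up to 200 peaks per set and 100 random instances,
  sizes at which the quadratic oracle is still exact and fast.

## Known limitations

- Expression input is a per-gene mean table; no count modelling, dispersion
  estimation or significance testing of expression (a q-value column, if
  supplied, can be used as a filter).
- Coverage tracks are compared as given; no between-library normalisation.
- One TSS per gene; alternative promoters and isoforms are out of scope.
- Enrichment is database-free: the user supplies the term map, and no
  gene-length bias correction is applied.
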