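# Methods

This document is the package's own scientific account of what each stage
computes and why, independent of any external write-up.

## 1. Synthetic test bed

The study design is a wild-versus-cultivated genome comparison in which the
"sample" genome carries structural variants relative to a reference. Because
real data at that scale are not desk-reproducible, all results here are
demonstrated on a simulated frame with known truth.

- **Reference**: i.i.d. bases at a configurable GC content (default 0.436),
  with optional assembly gaps written as `N` runs (`gap_spec`). Default one
  2 Mb chromosome.
- **Variants**: deletions, inversions, (inverted) translocations, insertions
  of novel sequence and inverted duplications are planned non-overlapping
  with margins, then implanted in a single right-to-left sweep so that all
  coordinates stay in reference space. The implantation returns both the
  sample genome and a truth table, plus coordinate maps in both directions.
  Requests outside the detectable size range of the library raise rather
  than silently degrade the truth set.
- **Reads**: paired-end, fragment length ~ Normal(μ = 500, σ = 30),
  read length 90, default 30× coverage. Fragments are placed on the sample
  genome and mapped back to reference coordinates; reads that cross a
  junction, fall in novel (inserted) sequence or touch a gap are dropped, as
  a real aligner would fail or soft-clip them. Divergent "paralog-like"
  regions can be simulated by elevating the per-base mismatch rate locally;
  mismatch counts are carried as SAM `NM` tags.
- **Annotations**: non-overlapping genes (a configurable fraction flagged as
  transposable-element related, a sub-fraction retrotransposon) and QTL
  intervals drawn from a fixed vocabulary of 15 rice domestication traits in
  six categories.
- **Transcripts**: one transcript per gene copied from the reference (so it
  maps back in the screen), a configurable number of organellar-derived
  transcripts copied from synthetic mitochondrial/chloroplast cDNA sets, and
  implanted *novel* transcripts that exist nowhere in the subject sets — the
  truth for the lost-transcript screen. A fragmentation rate truncates a
  subset, as assemblies do.

All randomness derives from a single seed through named substreams
(`np.random.default_rng([seed, stream_id])`), so changing e.g. the
annotation count cannot perturb the read stream.

## 2. Read-pair classification

A pair is summarised by chromosome, leftmost positions, strands and the
*outer distance* (rightmost end − leftmost start + 1), which for a
concordant forward-reverse pair equals the sequenced fragment length.

μ and σ are estimated from the data by a trimmed mean and trimmed standard
deviation (default 5 % per tail), the SD rescaled by the normal consistency
factor `sqrt(1 − 2·z·φ(z)/(1 − 2t))` so that the estimate is unbiased for
the underlying Normal despite trimming. Without the correction σ is
underestimated by ~8 % at t = 0.05, which widens the anomalous set with
thousands of false positives at genome scale.

Classification is by precedence:
`INTERCHROMOSOMAL > WRONG_ORIENTATION > WRONG_ORDER > INSERT_TOO_LARGE >
INSERT_TOO_SMALL`; a pair is NORMAL iff it matches none, with the
insert-size window μ ± kσ (k = 3) inclusive.

## 3. SV detection (linked windows)

Anomalous pairs are binned into sliding windows of size μ + 2σ with a half-
window step; the two reads of a pair link a window pair, and window pairs
sharing adjacent bins are merged (union–find). A link becomes a call when it
has ≥ 3 supporting pairs and a ≥ 80 % signature majority:

| signature (order/orientation/insert) | call |
|---|---|
| FR, insert too large | DELETION |
| FR, insert too small | INSERTION |
| FF or RR, same chromosome | INVERSION (INVERTED_DUPLICATION when the local depth ratio ≥ 1.6; INVERTED_FRAGMENT_INVERSION / FRAGMENT_INSERTION for reciprocal-pair geometries) |
| interchromosomal, opposite strands | TRANSLOCATION |
| interchromosomal, same strands | INVERTED_TRANSLOCATION |
| no majority | UNDEFINED |

Sizes: deletion size = median outer distance − μ; insertion size =
μ − median outer distance, structurally capped at μ − 2·read_length
(= 320 bp here) because a larger insertion cannot be bridged by both reads
of a pair — the practical ceiling quoted for this library design (~300 bp)
is a detectability statement, not a threshold in the code.

Breakpoints: the inner interval spanned by the supporting pairs (max left
read end + 1, min right read start − 1). When contradictory pairs make the
interval empty the call falls back to the window bounds and is flagged.
Per-side junction *hints* for the ratio filter are estimated per strand
(0.9-quantile of forward read ends + 1; 0.1-quantile of reverse read starts
− 1) and averaged when a side carries both strands — necessary because the
two junction clusters of an inversion merge into one link.

## 4. Filter chain

Five filters in canonical order, then deduplication; each call records the
first stage it fails.

1. **ratiofilter** — at each breakpoint, anomalous / (anomalous +
   concordant) spanning pairs must reach 0.5. DELETION and INSERTION calls
   must pass at *both* breakpoints; all other types pass with one supported
   junction, because for composite events (e.g. the inner edge of an
   inverted duplication) the second estimated side has no reference
   junction. Interchromosomal pairs contribute 1 bp-padded per-read
   intervals as anomalous evidence at both loci.
2. **gapfilter** — calls overlapping an assembly gap are removed.
3. **SNVfilter** — mean mismatch density in 100 bp bins around the
   breakpoints must stay ≤ 0.02; removes paralog-misalignment artifacts.
4. **coveragefilter** (deletions only) — at most 20 % of the deleted
   interval may be read-covered.
5. **depthfilter** (deletions only) — mean depth over the interval must be
   ≤ 1/3 of the genome mean.

**Dedup**: among DELETION survivors, identical intervals keep the
best-supported call (ties by id); an interval strictly containing another is
removed, keeping the inner call.

Satellite clusters — small UNDEFINED/INSERTION-signature clusters adjacent
to true junctions — legitimately pass the ratio filter because genuinely
anomalous pairs dominate there; they are duplicate evidence of real events,
not noise, and are reported as such.

## 5. Annotation of deletions

Intersection is 1-based inclusive; a single shared base is a hit
(a feature *touching* at distance 1 is not). Summaries:

- genes per deletion, % of deletions hitting ≥ 1 gene, % of those hitting
  exactly one;
- TE and retrotransposon composition of the deleted gene set against the
  genome-wide gene universe;
- QTL hits deduplicated by coordinate + trait (or coordinate only);
- a per-trait table (QTL count, genes in QTL-bearing deletions, distinct
  regions), sorted by QTL count, with an optional mode that assigns each
  gene to a single trait.

## 6. Transcript presence/absence screen

Hierarchical: transcripts (minimum 200 bp) are searched against the
reference transcriptome; the unmapped remainder against the mitochondrial
cDNA, chloroplast cDNA and nuclear genome together; survivors are LOST, and
lost genes are the distinct gene ids among them (gene ids parsed from
assembler-style `_t<k>`/`_i<k>` isoform suffixes).

Homology is decided by an internal seed-and-extend search, not an external
aligner: exact 16-mer seeds (2-bit-packed, numpy), grouped by
(subject, diagonal), the best groups extended gaplessly with +1/−2 scoring
and an x-drop of 20. A hit requires identity ≥ 0.90 over the aligned span
and ≥ 0.50 query coverage, on either strand; ties break deterministically
(score desc, subject id asc, forward strand first). The acceptance suite
checks the hit/no-hit decision against a quadratic local-alignment oracle.
The thresholds are defaults chosen to be stringent enough that random
sequences never map; they are fully configurable.

Statistics: N50 is the largest length L such that transcripts ≥ L hold at
least half the assembled bases; mean length rounds half-up; N50 ≥ mean is
*not* an invariant (false in general).

## 7. Reporting conventions

Every percentage is a `FractionStatement` printed as `X.XX % (a/b)` with
exact-rational round-half-up to two decimals (`Decimal`, no binary-float
artifacts). The SV type table adds a combined translocation +
inverted-translocation row. Deletion calls are matched to truth at ≥ 0.5
reciprocal overlap for recall/precision.

## 8. Limitations

- The simulator drops junction-crossing reads instead of modelling split or
  soft-clipped alignments, so breakpoint precision here (± a few bp after
  quantile estimation) is optimistic relative to real aligners.
- Organellar cDNA sets are synthetic stand-ins; the screen validates the
  routing logic, not organellar biology.
- Translocation origins leave deletion-signature calls that are removed by
  the coverage/depth filters rather than being re-labelled; on a
  single-chromosome bed translocations surface as long-range
  inversion-signature calls.
- Insertions are detectable only below μ − 2·read_length; larger novel
  sequence is invisible to this read-pair design.
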