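# Methods

This note documents the models and procedures implemented in `acds`, the
parameters that matter, what the synthetic benchmark does and does not
show, and the design choices made where the underlying biology or the
historical protocol leaves the design open.

## The structural model

An Ac/Ds-family element is modeled as a sequence bounded by the 11-bp
terminal inverted repeats (TIRs) — 5' `[C/T]AGGGATGAAA`, 3'
`TTTCATCCCT[A/G]` — and flanked by an 8-bp target-site duplication (TSD),
a direct repeat of host sequence created by insertion. The TSD is not part
of the element; element coordinates are TIR-inclusive and TSD-exclusive.
All internal coordinates are 0-based half-open; GFF3 output converts to
1-based inclusive.

Because the two TIRs are mutual reverse complements, a perfect element
reads identically on both strands at its termini: element orientation is
not observable from the scan alone. The scanner therefore emits every
motif window under both interpretations (5' end of a plus-strand element
and 3' end of a minus-strand element), and the classifier later fixes the
orientation by whichever strand of the element aligns better against the
full reference Ac. The degenerate motif positions (first base of the 5'
TIR, last base of the 3' TIR) never count as mismatches, and windows
overlapping `N` are discarded because motif identity is undefined there.

## Discovery scan

`scan_motif` computes, for every window on both strands, the Hamming
distance to the (degenerate) TIR motif, vectorized over the genome.
`pair_candidates` pairs 5' with 3' hits of the same element strand within
a length window (defaults 50 bp – 30 kb; the upper bound exceeds the
largest retrotransposon-bloated elements on record, ~24 kb) and requires
TSD evidence: the 8-mers immediately outside the element within the TSD
mismatch budget. TIR and TSD budgets are independent parameters, each
defaulting to 2 mismatches.

Competing pairings are resolved innermost-first (shortest span), then by
total mismatch score, then leftmost, with each 11-bp genome window
supporting at most one emitted call. Innermost-first makes elements nested
inside larger elements detectable; the one-call-per-window rule
deduplicates the strand-symmetric reading of the same element. These
tie-break rules are this package's own (the historical search did not
state its resolution rule) and are chosen to make output deterministic.

**Mismatch budgets and false discovery.** A 2-mismatch TIR scan admits a
motif match roughly every 4.5 kb of random sequence per orientation, and a
2-mismatch TSD check passes for ~0.4% of random flank pairs; together they
produce on the order of 8 chance calls per Mb of random DNA. On real
genomes those candidate calls were historically curated by homology; on
the synthetic benchmark (below) the matched configuration for
mismatch-free implants is the exact scan (`tir_mm=0, tsd_mm=0`), which
this package uses for its recall/precision benchmark. Mismatch tolerance
is exercised separately: the scanner is verified against a brute-force
Hamming oracle at budgets 0/1/2, and the degradation suite checks that
eroded TIRs (3 mismatches) and destroyed TSDs drop out of the default
2-mismatch scan.

**TSD-less rescue.** `rescue_no_tsd` re-runs pairing without the TSD
requirement and reports calls that do not overlap the primary catalog,
annotated with the flank identity out of 8 — the signature of an old
insertion whose TSD has mutated away. Without a TSD constraint, a
mismatch-tolerant scan pairs essentially at random, so the rescue scan
requires perfect TIRs by default (`rescue_tir_mm=0`, configurable); the
few genuine TSD-less elements reported in the field have well-conserved
ends, consistent with this choice.

## Classification

Local alignments use Smith–Waterman scoring (+1 match, −1 mismatch, −2
gap open, −1 gap extend) via Biopython's `PairwiseAligner`; an independent
quadratic dynamic-programming implementation serves as the test oracle.
A `HomologyProfile` records:

* `term5_len`/`term3_len` — ungapped terminal identity runs against the
  reference ends (10-bp windows at ≥80% identity; first failing window
  stops the extension);
* `str5_cov`/`str3_cov`/`exon23_cov`/`full_cov` — the identity-weighted
  fraction of each reference segment (200-bp subterminal regions,
  transposase exon 2–3, whole element) recovered by the maximal local
  alignment of the element against it;
* `exon23_block` — the longest gap-free aligned block on the exon
  segment;
* `best_identity` — identities per alignment column of the full-reference
  alignment.

The decision cascade is first-match-wins:

1. **Ac-like**: `full_cov ≥ 0.9` and `best_identity ≥ 0.9`;
2. **Ds2**: both STR coverages ≥ 0.5;
3. **Ds-l3**: `exon23_cov ≥ 0.1` with an aligned block ≥ 200 bp;
4. **Ds1**: length < 500 bp and either a supplied Ds1 family consensus
   matches (identity ≥ 0.7 over ≥ 100 alignment columns) or, when no
   consensus is supplied (logged warning) or it fails, terminal homology
   ≤ 40 bp at both ends;
5. **Ds-l4**: terminal homology ≤ 40 bp at both ends;
6. otherwise unclassified.

The numeric thresholds are this package's quantification of qualitative
class descriptions ("~200 bp of the subterminal region", "about 30 bp at
either end", "small indels"); they separate the five synthetic archetypes
with wide margins and are all configurable.

The AAACGG transposase-binding hexamer is counted in the 200-bp
subterminal windows, each read inward on the element's own strand (the 3'
window on the reverse complement); elements shorter than 400 bp use their
two halves (the protocol is silent there). Three or more copies are the
classical mobility requirement; the per-end counts are recorded
separately and the mobility flag is raised on the pooled count, since the
published criterion ("within their subterminal regions") does not specify
an end.

Census tables are pandas crosstabs with margins; the chi-square
goodness-of-fit against chromosome length uses expected counts
proportional to length (`df = #chromosomes − 1`, unplaced scaffolds
excluded). Percentages round half-up to whole percents, matching printed
tables. Annotation comparison calls an element `full` at ≥90% reciprocal
overlap with a prior feature, `partial` for any lesser overlap, `new`
otherwise.

## Annotation

**Flank copy number.** Repetitiveness of an insertion site is measured as
the median genome-wide occurrence count of the canonical 20-mers in the
two 200-bp flanks (element-overlapping k-mers excluded; flanks over 10%
`N` skipped). This is a self-contained, library-free stand-in for a
repeat-masking protocol; the threshold (default 2.0) and k are
configurable. The median is taken over the pooled k-mers of both flanks,
so a site is "repetitive" when flanking sequence as a whole is multi-copy.

**Insertion context** has precedence genic > repetitive > intergenic. An
element is genic when a gene model (GFF3, strand ignored) lies in or
within 200 bp. Database-level evidence for target-site genes (ESTs,
mRNAs) is out of scope; user-supplied gene models are the interface.

**Internal cargo.** The element interior (between the TIRs) is aligned
against an optional repeat library (record kind tagged `name#ltr_retro` /
`name#dna_transposon`) and an optional donor exon database; matches need
identity ≥ 0.8 over ≥ 100 bp. Two exon matches of one donor separated by
an interior segment with `GT..AG` termini merge into one gene fragment
with `intron_ok=True`. Nested TIR elements come from a recursive scan of
the interior. Overlaps resolve best-score-first, then longest; residual
interior runs (≥10 bp) are reported as intergenic filler. Features never
extend into the TIRs.

**Compound elements.** Serial insertion at one target site leaves internal
copies of the element's own 8-bp TSD word between trapped blocks.
`decompose_compound` splits the element at every internal exact copy of
its TSD word: the first segment is the core element; the last is labelled
a truncated duplicate when it ends in a 3' TIR and locally aligns to the
core (identity ≥ 0.8 over ≥ 50 bp); everything between is cargo. Segments
always tile the element exactly. The synthetic compound builder uses the
same grammar, which reproduces the published 7,344-bp four-segment
architecture (987 / 663 / 4887 / 807).

**Excision products.** The predicted empty site is `flank + one TSD copy +
flank` (default flank 500 bp, total 1,008 bp). A single intact TSD copy is
a convention — the PCR assay this emulates does not resolve footprint
sequence — and elements without TSD evidence get their flanks joined
directly with a warning.

**Junction reads.** A transposon-display read is host flank followed by an
element 5' terminus. The TIR is located in the read (all candidate
offsets are tried, best motif match and longest host first, so chance
near-motif words in the flank cannot shadow the true junction), the host
portion is mapped by seed-and-verify in both orientations (identity ≥ 0.9
over ≥ 30 bp), and the junction is `shared` when a cataloged element
terminus lies within 8 bp (the TSD ambiguity) of the mapped point,
`polymorphic` when the host maps with no adjacent element, `unmapped`
otherwise.

## Filler clustering

Ds-l4 interiors carry variable filler DNA that falls into families.
Distances are alignment-free — 1 minus the cosine similarity of 8-mer
count vectors — rather than MSA-based: an alignment of hundreds of
kilobase-scale sequences would dominate runtime without adding anything
testable. Cosine distance is not a metric; violations of the triangle
inequality are possible and are logged, not treated as errors.

Neighbor joining is the standard Q-criterion agglomeration with
deterministic tie-breaking (lexicographically smallest cluster-label
pair; the Q matrix is evaluated on its upper triangle only because the
two symmetric entries can differ in the last floating-point bit) and
negative branch lengths clamped to zero. On additive matrices the
reconstructed path-length matrix equals the input to ~1e-15. Clusters cut
the longest internal edges, skipping cuts that would strand a leafless
internal component; the cluster count is a user parameter (the published
three-cluster structure was a visual judgment; elements above a length
cutoff, default 5 kb, can be excluded as in that analysis).

## The synthetic benchmark

`make_ac_reference` builds a 4,565-bp reference bounded by the printed
TIRs with four AAACGG copies per subterminal region and a designated
exon-2/3 segment. Element builders emit class-faithful architectures with
lengths drawn from truncated normals around the published class
means/modes: Ds1 ~400 bp (shared family filler, 2% divergence, <500 bp),
Ds2 ~1.4 kb (both 200-bp STRs + unrelated filler), Ds-l3 ~4 kb (an
exon-2/3 fragment plus hexamer-bearing subterminal blocks), Ds-l4 ~1 kb
(30-bp Ac termini, filler from one of three families, hexamers near both
ends), Ac-like (the reference with a few ≤8-bp indels). Backgrounds are
i.i.d. bases at GC 0.47 with gene models and repeat families copied at 2%
divergence — enough realism to exercise the repetitive/unique distinction
without modeling a real chromosome. Implantation duplicates the 8-bp
target word (the duplication is created, never assumed), and everything
flows from one `numpy` generator per seed.

Synthetic backgrounds and fillers are scrubbed of chance exact TIR words
so that truth sets stay exact; real genomes have no such guarantee, which
is precisely why the mismatch-tolerant scan needs downstream curation.
Passing the benchmark therefore demonstrates correctness of the machinery
(coordinates, TSD semantics, classification logic), not the false
discovery rate to expect on a real genome.

Problem sizes used by the test suite and acceptance script: a 2-Mb
genome with 60 clean implants for end-to-end recovery; 500-kb and smaller
genomes for degradation, context, and CLI checks; 50 × 5-kb sequences for
the scanner oracle; 20 random 8-leaf trees for NJ exactness; 20 replicate
genome pairs (8 shared + 8 private implants, 12 reads each) for the
junction-sharing simulation, whose pooled sharing fraction is checked
against 0.5 within three binomial standard deviations.

## Known limitations

* The false-positive behavior of the 2-mismatch scan on real repetitive
  genomes is not modeled; downstream homology curation remains necessary.
* Ds1 vs Ds-l4 separation without a family consensus falls back to a
  length rule (<500 bp) and short terminal homology; intermediate-length
  decayed elements can land in `unclassified`.
* Compound decomposition requires internal TSD copies to have survived
  exactly; older compounds with mutated internal TSDs resolve as a single
  core.
* The k-mer repetitiveness measure saturates for very high copy numbers
  and is blind to repeats diverged beyond the k-mer identity horizon.
* Junction matching assumes reads without sequencing error (seed-and-
  verify with exact 20-mer seeds); the generator does not simulate errors.
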