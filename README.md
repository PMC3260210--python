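# acds — Ac/Ds transposon family discovery and annotation

`acds` is a toolkit for finding and characterizing the *Ac/Ds* transposon
family (hAT superfamily) in genome sequence. *Ac* (*Activator*) is the
4.6-kb autonomous maize transposon; *Ds* (*Dissociation*) elements are its
nonautonomous relatives, mobilized in trans by the Ac transposase. All
family members share two structural signatures:

* an 11-bp **terminal inverted repeat** (TIR) at each end — 5'
  `[C/T]AGGGATGAAA` and 3' `TTTCATCCCT[A/G]`, mutual reverse complements —
  and
* an 8-bp **target-site duplication** (TSD), a direct repeat of host
  sequence created on insertion.

The toolkit is aimed at genome annotators and transposon biologists who
want a reproducible, scriptable version of the classical motif-anchored
search: scan a FASTA genome for TIR pairs flanked by a TSD (each with a
configurable mismatch budget, up to 2 bp), then classify every call by
homology to a reference Ac element into the five structural classes —
**Ac-like** (near-complete Ac), **Ds2** (both ~200-bp subterminal regions +
filler), **Ds-l3** (transposase exon 2–3 fragments, decaying Ac), **Ds1**
(<500 bp, family filler), and **Ds-l4** (~1 kb, only ~30 bp of Ac at each
end). Downstream operations annotate insertion context (genic / repetitive
/ intergenic), internal cargo (LTR retrotransposons, nested elements,
captured gene fragments with GT..AG intron checks), compound-element
structure, predicted excision ("empty site") products, transposon-display
junction reads, and neighbor-joining clusters of variable filler DNA.

A fully seeded synthetic-genome generator (`acds.synthetic`) builds
class-faithful elements, implants them with true TSD semantics, and returns
exact ground truth, so the entire pipeline is testable without downloading
any genome.

## Worked example

Simulate a 500-kb genome with 19 implanted elements and run the full
pipeline (scan → classify → annotate → census):

```bash
cat > sim.yaml <<EOF
simulate:
  length: 500000
  gene_count: 5
  repeat_families: 1
  n_elements: 20
scan:
  tir_mm: 0
  tsd_mm: 0
EOF
acds simulate --config sim.yaml --seed 42 -o study
acds pipeline study/genome.fasta --ac-ref study/ac.fasta \
    --ac-segments study/ac.yaml --genes study/genes.gff3 \
    --ds1-consensus study/ds1_consensus.fasta --config sim.yaml -o out
```

This prints the census table:

```
class       Ds1  Ds2  Ds-l3  Ds-l4  Ac-like  Total
chromosome
chr1          7    2      2      7        1     19
Total         7    2      2      7        1     19
```

Every implanted element was recovered with exact boundaries and assigned
its true class (compare `out/classified.tsv` against `study/truth.tsv`).
The first catalog rows look like:

```
seq_id  start   end     strand  length  label
chr1    15523   19227   +       3704    Ds-l3
chr1    38080   38464   +       384     Ds1
```

`start`/`end` are 0-based half-open genome coordinates (GFF3 output is
1-based inclusive); `length` excludes the TSD. The ~3.7-kb Ds-l3 carries a
transposase exon-2/3 fragment; the 384-bp Ds1 matches the shared Ds1 family
filler.

The published B73 maize census ships with the package for the reporting
operations and worked examples:

```python
>>> from acds.datasets import load_b73_census, catalog_from_counts
>>> from acds.classify import summarize_counts
>>> summarize_counts(catalog_from_counts(load_b73_census())).loc["Total"]
class
Ds1        331
Ds2         39
Ds-l3       44
Ds-l4      486
Ac-like      3
Total      903
```

903 TIR/TSD-bounded elements, more than half of them Ds-l4 — the class
with the least Ac homology, invisible to homology-first annotation.

## Library layout

| module | contents |
|---|---|
| `acds.core` | sequence/interval model, FASTA/GFF3/BED/TSV I/O, the `AcReference` |
| `acds.tir_scan` | motif scanning, TIR pairing, TSD validation, TSD-less rescue |
| `acds.classify` | local alignment, homology profiles, class cascade, census tables, chi-square |
| `acds.annotate` | flank copy number, insertion context, internal cargo, compound decomposition, empty sites, junction matching |
| `acds.cluster` | k-mer distances, neighbor joining, cluster cutting |
| `acds.synthetic` | seeded genomes, element builders, implantation, junction reads |
| `acds.datasets` | bundled B73 census tables |
| `acds.cli` | `acds scan / classify / annotate / cluster / junctions / simulate / report / pipeline` |

See `docs/methods.md` for the model, parameter defaults, and the design
decisions behind them.
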