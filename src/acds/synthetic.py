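"""Seeded synthetic genomes carrying implanted Ac/Ds-family elements.

Every other module of the toolkit is testable without downloads because this
module generates, from a single integer seed, a complete study bundle:

* a reference autonomous Ac element (4,565 bp, printed TIRs, >= 3 AAACGG
  hexamers per subterminal region, an annotated exon-2/3 segment);
* class-faithful element sequences: Ds1 (~400 bp, shared family filler),
  Ds2 (both 200-bp subterminal regions + variable filler, ~1.4 kb mean),
  Ds-l3 (~4 kb with an exon-2/3 fragment), Ds-l4 (~1 kb, ~30-bp Ac termini,
  family filler), Ac-like (the reference with small indels), and compound
  elements that trap cargo blocks between their termini;
* background genomes (i.i.d. bases at configurable GC, default 0.47) with
  gene models and divergent repeat families, into which elements are
  implanted with true 8-bp target-site duplication semantics (the
  duplication is created by the insertion, never assumed);
* transposon-display junction reads (host flank + element 5' terminus).

A :class:`TruthRecord` per implant carries post-insertion coordinates, class,
TSD word, context, and cargo, so recall/precision and classification
accuracy can be scored exactly.  All randomness flows through one
:class:`numpy.random.Generator`; identical seeds give identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AcReference, Genome, GenomeSequence, HEXAMER, Interval, TIR_LEN, TSD_LEN,
    reverse_complement, write_fasta, write_gff3_genes,
)
from .tir_scan import ScanParams, scan_motif

log = logging.getLogger("acds")

TIR5 = "TAGGGATGAAA"
TIR3 = reverse_complement(TIR5)          # TTTCATCCCTA
AC_LENGTH = 4565
STR_LEN = 200
EXON23 = (988, 3100)

CLASS_LABELS = ("Ds1", "Ds2", "Ds-l3", "Ds-l4", "Ac-like")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.47) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _scrub_motifs(seq: str, rng: np.random.Generator,
                  protect: Sequence[tuple[int, int]] = ()) -> str:
    """Mutate away accidental exact TIR motif occurrences.

    Keeps synthetic backgrounds and fillers free of spurious element
    termini so that truth sets stay exact.  Regions listed in ``protect``
    (half-open) are left untouched.
    """
    out = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(out)
        for motif in (TIR5, "C" + TIR5[1:], TIR3, TIR3[:-1] + "G"):
            k = text.find(motif)
            while k != -1:
                if not any(lo <= k and k + len(motif) <= hi for lo, hi in protect):
                    mid = k + len(motif) // 2
                    alternatives = [b for b in "ACGT" if b != out[mid]]
                    out[mid] = alternatives[int(rng.integers(len(alternatives)))]
                    changed = True
                    break
                k = text.find(motif, k + 1)
            if changed:
                break
    return "".join(out)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitution-only divergence at the given per-base rate."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _with_hexamers(seq: str, rng: np.random.Generator, n: int,
                   lo: int, hi: int, reverse: bool = False) -> str:
    """Overwrite ``n`` spaced hexamer copies into seq[lo:hi]."""
    word = reverse_complement(HEXAMER) if reverse else HEXAMER
    out = list(seq)
    span = hi - lo - len(word)
    offsets = sorted(rng.choice(span // 12, size=n, replace=False)) if span >= 12 * n else range(n)
    for i, off in enumerate(offsets):
        p = lo + int(off) * 12
        out[p:p + len(word)] = word
    return "".join(out)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> int:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))


# ---------------------------------------------------------------------------
# Reference Ac
# ---------------------------------------------------------------------------

def make_ac_reference(seed: int, outdir: str | Path | None = None) -> AcReference:
    """Generate a deterministic synthetic reference Ac element.

    4,565 bp, bounded by the canonical TIRs, with four AAACGG hexamers in
    each 200-bp subterminal region and an annotated exon-2/3 segment.
    Optionally writes ``ac.fasta`` + ``ac.yaml`` to ``outdir``.
    """
    rng = np.random.default_rng(seed)
    body = random_dna(rng, AC_LENGTH)
    body = TIR5 + body[TIR_LEN:-TIR_LEN] + TIR3
    body = _with_hexamers(body, rng, 4, TIR_LEN + 5, STR_LEN)
    body = _with_hexamers(body, rng, 4, AC_LENGTH - STR_LEN,
                          AC_LENGTH - TIR_LEN - 5, reverse=True)
    body = _scrub_motifs(body, rng, protect=[(0, TIR_LEN),
                                             (AC_LENGTH - TIR_LEN, AC_LENGTH)])
    ref = AcReference(
        residues=body,
        tir5=Interval("Ac", 0, TIR_LEN),
        tir3=Interval("Ac", AC_LENGTH - TIR_LEN, AC_LENGTH),
        str5=Interval("Ac", 0, STR_LEN),
        str3=Interval("Ac", AC_LENGTH - STR_LEN, AC_LENGTH),
        exon23=Interval("Ac", *EXON23),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref.write(outdir / "ac.fasta", outdir / "ac.yaml")
    return ref


# ---------------------------------------------------------------------------
# Element builders
# ---------------------------------------------------------------------------

@dataclass
class FamilyPool:
    """Per-run shared sequence families (Ds1 filler, Ds-l4 filler clusters,
    repeat families) so that family structure is reproducible."""

    ds1_filler: str
    dsl4_families: list[str]
    retro_family: str
    dna_tn_family: str

    @classmethod
    def from_rng(cls, rng: np.random.Generator) -> "FamilyPool":
        def clean(n: int) -> str:
            return _scrub_motifs(random_dna(rng, n), rng)

        dsl4 = [clean(1600) for _ in range(3)]
        return cls(
            ds1_filler=clean(380),
            dsl4_families=dsl4,
            retro_family=clean(3000),
            dna_tn_family=clean(1500),
        )


def build_element(label: str, ac_ref: AcReference | None,
                  rng: np.random.Generator,
                  pool: FamilyPool | None = None,
                  divergence: float = 0.02) -> str:
    """Emit one element sequence matching its class architecture."""
    pool = pool or FamilyPool.from_rng(rng)
    ref = ac_ref.residues if ac_ref is not None else None
    if ref is None and label != "Ds1":
        raise ValueError("a reference Ac is required for classes other than Ds1")

    if label == "Ac-like":
        out = list(ref)
        # a few small interior indels, as in near-complete decayed copies
        for _ in range(3):
            p = int(rng.integers(300, AC_LENGTH - 300))
            k = int(rng.integers(1, 9))
            if rng.random() < 0.5:
                del out[p:p + k]
            else:
                out[p:p] = list(random_dna(rng, k))
        seq = "".join(out)
        return _scrub_motifs(seq, rng, protect=[(0, TIR_LEN),
                                                (len(seq) - TIR_LEN, len(seq))])

    if label == "Ds1":
        total = _truncated_normal(rng, 400, 30, 320, 480)
        filler = _mutate(pool.ds1_filler, rng, divergence)[:total - 2 * TIR_LEN]
        seq = TIR5 + filler + TIR3
    elif label == "Ds2":
        total = _truncated_normal(rng, 1400, 200, 1050, 2000)
        filler = random_dna(rng, total - 2 * STR_LEN)
        seq = ref[:STR_LEN] + filler + ref[-STR_LEN:]
    elif label == "Ds-l3":
        total = _truncated_normal(rng, 4000, 400, 3200, 4800)
        exon_lo, exon_hi = ac_ref.exon23.start, ac_ref.exon23.end
        frag_len = min(int(rng.integers(1200, 2000)), exon_hi - exon_lo)
        off = int(rng.integers(0, exon_hi - exon_lo - frag_len + 1))
        fragment = _mutate(ref[exon_lo + off:exon_lo + off + frag_len], rng,
                           divergence)
        sub5 = _with_hexamers(random_dna(rng, 180), rng, 3, 5, 175)
        sub3 = _with_hexamers(random_dna(rng, 180), rng, 3, 5, 175,
                              reverse=True)
        pad = max(0, total - 2 * TIR_LEN - len(sub5) - len(sub3) - len(fragment))
        seq = (TIR5 + sub5 + fragment + random_dna(rng, pad) + sub3 + TIR3)
    elif label == "Ds-l4":
        total = _truncated_normal(rng, 1000, 150, 700, 1600)
        family = pool.dsl4_families[int(rng.integers(len(pool.dsl4_families)))]
        term = 30
        filler = _mutate(family, rng, divergence)[:total - 2 * term]
        # class architecture: subterminal AAACGG copies at both ends
        filler = _with_hexamers(filler, rng, 2, 10, 150)
        filler = _with_hexamers(filler, rng, 2, len(filler) - 150,
                                len(filler) - 10, reverse=True)
        seq = ref[:term] + filler + ref[-term:]
    else:
        raise ValueError(f"unknown element class {label!r}")
    return _scrub_motifs(seq, rng, protect=[(0, TIR_LEN),
                                            (len(seq) - TIR_LEN, len(seq))])


def embed_cargo(element_seq: str, kind: str, rng: np.random.Generator,
                pool: FamilyPool,
                donor_id: str = "donor1") -> tuple[str, dict, dict[str, str]]:
    """Insert one cargo block into an element's interior.

    ``kind`` is one of ``ltr_retro`` (a fragment of the pool's LTR
    retrotransposon family), ``gene_fragment`` (two synthetic exons separated
    by a GT..AG intron; the exon sequences are returned as a donor database),
    or ``nested_element`` (a Ds1 element inserted with full 8-bp TSD
    duplication).  Returns ``(new_sequence, cargo_record, donor_db)``.
    """
    lo, hi = TIR_LEN + 60, len(element_seq) - TIR_LEN - 60
    if hi <= lo:
        raise ValueError("element too short to carry cargo")
    at = int(rng.integers(lo, hi))
    donor_db: dict[str, str] = {}

    if kind == "ltr_retro":
        frag_len = int(rng.integers(300, 600))
        off = int(rng.integers(0, len(pool.retro_family) - frag_len))
        block = pool.retro_family[off:off + frag_len]
        new_seq = element_seq[:at] + block + element_seq[at:]
    elif kind == "gene_fragment":
        exon1 = _scrub_motifs(random_dna(rng, 180), rng)
        exon2 = _scrub_motifs(random_dna(rng, 160), rng)
        intron = "GT" + _scrub_motifs(random_dna(rng, 110), rng) + "AG"
        donor_db = {f"{donor_id}.exon1": exon1, f"{donor_id}.exon2": exon2}
        block = exon1 + intron + exon2
        new_seq = element_seq[:at] + block + element_seq[at:]
    elif kind == "nested_element":
        inner = build_element("Ds1", None, rng, pool)
        word = element_seq[at:at + TSD_LEN]
        block = inner
        new_seq = (element_seq[:at + TSD_LEN] + inner
                   + element_seq[at:])
        at += TSD_LEN
    else:
        raise ValueError(f"unknown cargo kind {kind!r}")
    record = {"kind": kind, "start": at, "end": at + len(block),
              "donor": donor_id if kind == "gene_fragment" else None}
    return new_seq, record, donor_db


def build_compound_element(ac_ref: AcReference, rng: np.random.Generator,
                           pool: FamilyPool | None = None,
                           segment_lengths: Sequence[int] = (987, 663, 4887, 807),
                           ) -> tuple[str, str, list[int]]:
    """Build a compound element: core + cargo blocks + truncated duplicate.

    Serial insertion at one target site leaves an internal copy of the 8-bp
    target word at the start of every trapped block; the final block is a
    truncated copy of the core ending in the element's 3' TIR.  Returns
    ``(sequence, tsd_word, boundaries)`` where boundaries are the segment
    start offsets including 0 and the total length.
    """
    pool = pool or FamilyPool.from_rng(rng)
    core_len, *cargo_lens, dup_len = segment_lengths
    ref = ac_ref.residues
    term = 30

    while True:
        filler = _scrub_motifs(random_dna(rng, core_len - 2 * term), rng)
        core = ref[:term] + filler + ref[-term:]
        tsd = random_dna(rng, TSD_LEN)
        blocks = [core]
        sources = [pool.retro_family, None]   # retro fragment, then anonymous cargo
        for idx, length in enumerate(cargo_lens):
            body_len = length - TSD_LEN
            src = sources[idx % len(sources)]
            if src is not None and len(src) >= body_len:
                off = int(rng.integers(0, len(src) - body_len + 1))
                body = _mutate(src[off:off + body_len], rng, 0.02)
            else:
                body = random_dna(rng, body_len)
            blocks.append(tsd + _scrub_motifs(body, rng))
        dup_body = core[-(dup_len - TSD_LEN):]
        blocks.append(tsd + dup_body)
        seq = "".join(blocks)
        if seq.count(tsd) == len(cargo_lens) + 1:
            bounds = [0]
            for b in blocks:
                bounds.append(bounds[-1] + len(b))
            return seq, tsd, bounds


# ---------------------------------------------------------------------------
# Genome implantation
# ---------------------------------------------------------------------------

@dataclass
class ImplantSpec:
    """How many elements of one class to implant, and in what state."""

    label: str
    count: int
    tir_mm: int = 0                 # mismatches injected into each TIR
    tsd_destroy_p: float = 0.0      # probability of randomizing the right TSD copy
    context: str = "unique"         # unique | genic | repeat_array
    cargo: str | None = None        # ltr_retro | gene_fragment | nested_element


@dataclass
class BackgroundSpec:
    length: int = 2_000_000
    gc: float = 0.47
    gene_count: int = 20
    gene_length: int = 3000
    repeat_families: int = 2
    repeat_copies: int = 15
    seq_id: str = "chr1"


@dataclass
class TruthRecord:
    """Ground truth for one implant (post-insertion coordinates)."""

    element_id: str
    label: str
    seq_id: str
    start: int
    end: int
    strand: str
    tsd: str
    tsd_destroyed: bool
    tir_mm: int
    context: str
    shared: bool = True
    cargo: list = field(default_factory=list)

    @property
    def interval(self) -> Interval:
        return Interval(self.seq_id, self.start, self.end, self.strand)


@dataclass
class SimBundle:
    """One synthetic study: genome, annotations, libraries, and truth."""

    genome: Genome
    genes: list[Interval]
    repeats: dict[str, str]
    truth: list[TruthRecord]
    ac_ref: AcReference
    ds1_consensus: str
    pool: FamilyPool
    gene_db: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gff3_genes(self.genes, outdir / "genes.gff3")
        write_fasta(self.repeats, outdir / "repeats.fasta")
        self.ac_ref.write(outdir / "ac.fasta", outdir / "ac.yaml")
        write_fasta({"Ds1_consensus": self.ds1_consensus},
                    outdir / "ds1_consensus.fasta")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("element_id\tlabel\tseq_id\tstart\tend\tstrand\ttsd\t"
                     "tsd_destroyed\ttir_mm\tcontext\tshared\n")
            for t in self.truth:
                fh.write(f"{t.element_id}\t{t.label}\t{t.seq_id}\t{t.start}\t"
                         f"{t.end}\t{t.strand}\t{t.tsd}\t{t.tsd_destroyed}\t"
                         f"{t.tir_mm}\t{t.context}\t{t.shared}\n")


def _inject_tir_mismatches(seq: str, rng: np.random.Generator, n: int) -> str:
    """Mutate ``n`` positions in each TIR (avoiding the degenerate ones)."""
    if n <= 0:
        return seq
    out = list(seq)
    for lo in (0, len(seq) - TIR_LEN):
        # positions 1..10 of the 5' TIR / 0..9 of the 3' TIR are specific
        positions = range(lo + 1, lo + TIR_LEN) if lo == 0 else \
            range(lo, lo + TIR_LEN - 1)
        for p in rng.choice(list(positions), size=n, replace=False):
            alternatives = [b for b in "ACGT" if b != out[p]]
            out[p] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _default_specs(total: int = 60) -> list[ImplantSpec]:
    """The standard benchmark mix: all five classes, clean TIR/TSD."""
    weights = {"Ds1": 22, "Ds-l4": 22, "Ds2": 6, "Ds-l3": 6, "Ac-like": 4}
    scale = total / sum(weights.values())
    specs = [ImplantSpec(label, max(1, round(n * scale)))
             for label, n in weights.items()]
    return specs


def implant_genome(specs: Sequence[ImplantSpec] | None = None,
                   background: BackgroundSpec | None = None,
                   seed: int = 0,
                   ac_ref: AcReference | None = None) -> SimBundle:
    """Generate a background genome and implant elements with TSD semantics.

    Each insertion at target position ``p`` duplicates the 8-bp word at
    ``[p, p+8)``: the element lands between the two copies, so exactly one
    extra copy of the target word is created.  Genes and repeat arrays are
    placed first; implant positions honor their requested context and keep
    >= 2 kb spacing.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    background = background or BackgroundSpec()
    specs = list(specs) if specs is not None else _default_specs()
    ac_ref = ac_ref or make_ac_reference(int(rng.integers(2 ** 31)))
    pool = FamilyPool.from_rng(rng)

    host = random_dna(rng, background.length, background.gc)

    # repeat arrays: copy-paste a family with 2% divergence
    repeats: dict[str, str] = {}
    repeat_arrays: list[tuple[int, int]] = []
    margin = 5000
    for fam_idx in range(background.repeat_families):
        fam = (pool.retro_family if fam_idx % 2 == 0 else pool.dna_tn_family)
        name = (f"retro{fam_idx}#ltr_retro" if fam_idx % 2 == 0
                else f"dnatn{fam_idx}#dna_transposon")
        repeats[name] = fam
        placed_copies = 0
        while placed_copies < background.repeat_copies:
            p = int(rng.integers(margin, background.length - margin - len(fam)))
            if any(lo - 500 < p + len(fam) and p < hi + 500
                   for lo, hi in repeat_arrays):
                continue
            host = host[:p] + _mutate(fam, rng, 0.02) + host[p + len(fam):]
            repeat_arrays.append((p, p + len(fam)))
            placed_copies += 1

    # gene models on the background, clear of the repeat arrays
    genes_pre: list[tuple[int, int]] = []
    while len(genes_pre) < background.gene_count:
        p = int(rng.integers(margin,
                             background.length - margin - background.gene_length))
        span = (p, p + background.gene_length)
        if any(lo - 500 < span[1] and span[0] < hi + 500
               for lo, hi in repeat_arrays + genes_pre):
            continue
        genes_pre.append(span)

    host = _scrub_motifs(host, rng)

    # choose implant positions honoring context, spaced >= 2 kb
    taken: list[int] = []

    def pick_position(context: str) -> int:
        for _ in range(10000):
            if context == "genic":
                if not genes_pre:
                    raise ValueError("genic context requested but no genes")
                g = genes_pre[int(rng.integers(len(genes_pre)))]
                p = int(rng.integers(g[0] + 50, g[1] - 50))
            elif context == "repeat_array":
                if not repeat_arrays:
                    raise ValueError("repeat context requested but no repeat "
                                     "families declared")
                a = repeat_arrays[int(rng.integers(len(repeat_arrays)))]
                p = int(rng.integers(a[0] + 100, a[1] - 100))
            else:
                p = int(rng.integers(margin, background.length - margin))
                if (any(lo - 300 <= p <= hi + 300 for lo, hi in repeat_arrays)
                        or any(lo - 300 <= p <= hi + 300 for lo, hi in genes_pre)):
                    continue
            if all(abs(p - q) >= 2000 for q in taken):
                taken.append(p)
                return p
        raise RuntimeError("could not place implant; background too crowded")

    @dataclass
    class _Pending:
        position: int
        seq: str
        record: TruthRecord

    pending: list[_Pending] = []
    gene_db: dict[str, str] = {}
    counter = 0
    for spec in specs:
        for _ in range(spec.count):
            counter += 1
            seq = build_element(spec.label, ac_ref, rng, pool)
            cargo_records = []
            if spec.cargo:
                seq, cargo_rec, db = embed_cargo(
                    seq, spec.cargo, rng, pool, donor_id=f"donor{counter}")
                cargo_records.append(cargo_rec)
                gene_db.update(db)
            seq = _inject_tir_mismatches(seq, rng, spec.tir_mm)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = seq if strand == "+" else reverse_complement(seq)
            p = pick_position(spec.context)
            rec = TruthRecord(
                element_id=f"{spec.label}-{counter}", label=spec.label,
                seq_id=background.seq_id, start=-1, end=-1, strand=strand,
                tsd="", tsd_destroyed=rng.random() < spec.tsd_destroy_p,
                tir_mm=spec.tir_mm, context=spec.context,
                cargo=cargo_records)
            pending.append(_Pending(p, inserted, rec))

    # insert right-to-left so earlier positions stay valid; shift the
    # coordinates of records already placed to the right
    pending.sort(key=lambda x: -x.position)
    placed: list[TruthRecord] = []
    gene_iv = [list(g) for g in genes_pre]
    for item in pending:
        p = item.position
        word = host[p:p + TSD_LEN]
        elem = item.seq
        host = host[:p + TSD_LEN] + elem + host[p:]
        if item.record.tsd_destroyed:
            # randomize the right copy until it is far from the left one
            right_at = p + TSD_LEN + len(elem)
            while True:
                new_word = random_dna(rng, TSD_LEN)
                if sum(a != b for a, b in zip(new_word, word)) >= 4:
                    break
            host = host[:right_at] + new_word + host[right_at + TSD_LEN:]
        shift = TSD_LEN + len(elem)
        for rec in placed:
            if rec.start >= p:
                rec.start += shift
                rec.end += shift
        for g in gene_iv:
            if g[0] >= p:
                g[0] += shift
                g[1] += shift
            elif g[0] < p < g[1]:
                g[1] += shift
        for idx, (lo, hi) in enumerate(repeat_arrays):
            if lo >= p:
                repeat_arrays[idx] = (lo + shift, hi + shift)
            elif lo < p < hi:
                repeat_arrays[idx] = (lo, hi + shift)
        item.record.start = p + TSD_LEN
        item.record.end = p + TSD_LEN + len(elem)
        item.record.tsd = word
        placed.append(item.record)

    placed.sort(key=lambda r: r.start)
    genome: Genome = {background.seq_id:
                      GenomeSequence(background.seq_id, host)}
    genes = [Interval(background.seq_id, lo, hi) for lo, hi in gene_iv]
    return SimBundle(genome=genome, genes=genes, repeats=repeats,
                     truth=placed, ac_ref=ac_ref,
                     ds1_consensus=pool.ds1_filler, pool=pool,
                     gene_db=gene_db)


def make_genome_pair(seed: int, n_shared: int = 10, n_private: int = 10,
                     background: BackgroundSpec | None = None,
                     label: str = "Ds-l4") -> tuple[SimBundle, SimBundle]:
    """Two genomes over one shared background with partially shared implants.

    Genome A and genome B both carry the ``n_shared`` shared implants at the
    same background positions; each additionally carries ``n_private``
    implants of its own.  Truth records carry a ``shared`` flag, emulating
    two inbred lines whose transposon complements only partially overlap.
    """
    rng = np.random.default_rng(seed)
    background = background or BackgroundSpec(length=400_000, gene_count=0,
                                              repeat_families=0)
    ac_ref = make_ac_reference(int(rng.integers(2 ** 31)))
    pool = FamilyPool.from_rng(rng)
    host = _scrub_motifs(random_dna(rng, background.length, background.gc), rng)

    margin = 5000
    positions: list[int] = []
    while len(positions) < n_shared + 2 * n_private:
        p = int(rng.integers(margin, background.length - margin))
        if all(abs(p - q) >= 3000 for q in positions):
            positions.append(p)
    shared_pos = positions[:n_shared]
    a_pos = positions[n_shared:n_shared + n_private]
    b_pos = positions[n_shared + n_private:]

    def build_set(pos_list: list[int], shared_flags: list[bool],
                  ids: list[str]) -> list[tuple[int, str, TruthRecord]]:
        out = []
        for p, fl, eid in zip(pos_list, shared_flags, ids):
            seq = build_element(label, ac_ref, rng, pool)
            rec = TruthRecord(element_id=eid, label=label,
                              seq_id=background.seq_id, start=-1, end=-1,
                              strand="+", tsd="", tsd_destroyed=False,
                              tir_mm=0, context="unique", shared=fl)
            out.append((p, seq, rec))
        return out

    shared_items = build_set(shared_pos, [True] * n_shared,
                             [f"shared-{i}" for i in range(n_shared)])

    def assemble(items: list[tuple[int, str, TruthRecord]]) -> SimBundle:
        text = host
        placed: list[TruthRecord] = []
        for p, seq, rec in sorted(items, key=lambda x: -x[0]):
            rec = replace(rec)
            word = text[p:p + TSD_LEN]
            text = text[:p + TSD_LEN] + seq + text[p:]
            shift = TSD_LEN + len(seq)
            for other in placed:
                if other.start >= p:
                    other.start += shift
                    other.end += shift
            rec.start, rec.end = p + TSD_LEN, p + TSD_LEN + len(seq)
            rec.tsd = word
            placed.append(rec)
        placed.sort(key=lambda r: r.start)
        genome = {background.seq_id: GenomeSequence(background.seq_id, text)}
        return SimBundle(genome=genome, genes=[], repeats={}, truth=placed,
                         ac_ref=ac_ref, ds1_consensus=pool.ds1_filler,
                         pool=pool)

    a_items = shared_items + build_set(a_pos, [False] * n_private,
                                       [f"A-{i}" for i in range(n_private)])
    b_items = shared_items + build_set(b_pos, [False] * n_private,
                                       [f"B-{i}" for i in range(n_private)])
    return assemble(a_items), assemble(b_items)


def generate_junction_reads(truth: Sequence[TruthRecord], genome: Genome,
                            n: int, read_len: int = 150, seed: int = 0,
                            terminus_len: int = 30) -> dict[str, str]:
    """Transposon-display reads: host flank + element 5' terminus.

    Each read emulates an adaptor-ligation PCR product from sheared DNA: the
    host sequence immediately outside the element's 5' end (including the
    TSD copy) followed by ``terminus_len`` bases of the element starting at
    its TIR, trimmed to ``read_len``.  Sampling is without replacement when
    possible; ``n`` larger than the implant count falls back to sampling
    with replacement (logged).
    """
    rng = np.random.default_rng(seed)
    truth = list(truth)
    if n > len(truth):
        log.info("requested %d reads from %d implants; sampling with "
                 "replacement", n, len(truth))
        chosen = [truth[int(i)] for i in rng.integers(len(truth), size=n)]
    else:
        idx = rng.choice(len(truth), size=n, replace=False)
        chosen = [truth[int(i)] for i in idx]
    reads: dict[str, str] = {}
    for i, rec in enumerate(chosen):
        seq = genome[rec.seq_id].residues
        host_len = read_len - terminus_len
        if rec.strand == "+":
            host = seq[max(0, rec.start - host_len):rec.start]
            term = seq[rec.start:rec.start + terminus_len]
            read = host + term
        else:
            host = reverse_complement(seq[rec.end:rec.end + host_len])
            term = reverse_complement(seq[rec.end - terminus_len:rec.end])
            read = host + term
        reads[f"read{i + 1}_{rec.element_id}"] = read
    return reads
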