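"""Shared sequence/interval data model and file I/O for the Ac/Ds toolkit.

The toolkit works on plain DNA strings over the alphabet ``{A, C, G, T, N}``.
All internal coordinates are 0-based, half-open (BED convention); GFF3 output
is converted to 1-based inclusive on the way out.  ``N`` is treated as an
unknown base: it never matches a motif position and flanks that are mostly
``N`` are excluded from copy-number estimation.

The central domain objects are:

* :class:`GenomeSequence` -- one named DNA sequence (a chromosome, scaffold,
  or synthetic contig).
* :class:`Interval` -- a strand-aware genomic interval.
* :class:`AcReference` -- the autonomous Activator (Ac) element used as the
  homology reference: its 11-bp terminal inverted repeats (TIRs), the ~200-bp
  subterminal regions (STRs) that carry the transposase-binding AAACGG
  hexamers, and the segment covering transposase exons 2-3.

Catalogs of called elements travel as :class:`pandas.DataFrame` objects with
a fixed column set (:data:`CATALOG_COLUMNS`) and can be written as TSV, BED,
or GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("acds")

VALID_BASES = frozenset("ACGTN")

# IUPAC one-letter degeneracies used in motif scanning.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# The 11-bp terminal inverted repeat of Ac/Ds.  The 5' end tolerates C or T at
# its first position, so the scanning motif carries a Y there; symmetrically
# the 3' end ends in A or G (R).  The two motifs are mutual reverse
# complements.
TIR5_MOTIF = "YAGGGATGAAA"
TIR3_MOTIF = "TTTCATCCCTR"
TIR_LEN = 11
TSD_LEN = 8
HEXAMER = "AAACGG"


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed).

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(dna) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid DNA symbols: {sorted(bad)!r}")
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One named DNA sequence."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains invalid symbols: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


Genome = dict[str, GenomeSequence]


def get_residues(genome: Genome | Mapping[str, str] | GenomeSequence | str,
                 seq_id: str | None = None) -> str:
    """Fetch the residue string for ``seq_id`` from any genome-like object."""
    if isinstance(genome, str):
        return genome
    if isinstance(genome, GenomeSequence):
        return genome.residues
    rec = genome[seq_id]
    return rec.residues if isinstance(rec, GenomeSequence) else rec


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.seq_id == other.seq_id
                and self.start < other.end and other.start < self.end)


@dataclass
class AcReference:
    """Reference autonomous Ac element with annotated segments.

    ``tir5``/``tir3`` are the terminal 11-bp inverted repeats; ``str5``/``str3``
    the subterminal regions (<=200 bp each, containing the AAACGG hexamers);
    ``exon23`` covers transposase exons 2-3, the segment retained by decaying
    Ds-l3 elements.  Coordinates are on the element itself, 0-based half-open.
    """

    residues: str
    tir5: Interval
    tir3: Interval
    str5: Interval
    str3: Interval
    exon23: Interval
    hexamer: str = HEXAMER
    name: str = "Ac"

    def __post_init__(self) -> None:
        n = len(self.residues)
        for seg in (self.tir5, self.tir3, self.str5, self.str3, self.exon23):
            if seg.end > n:
                raise ValueError("reference segment extends past the sequence")
        if len(self.tir5) != TIR_LEN or len(self.tir3) != TIR_LEN:
            raise ValueError("TIR segments must be 11 bp")
        t5 = self.segment(self.tir5)
        t3 = self.segment(self.tir3)
        # the two TIRs must be reverse complements up to the degenerate
        # first/last position
        if reverse_complement(t3)[1:] != t5[1:]:
            raise ValueError("TIRs are not reverse complements")
        if not (self.tir5.end < self.exon23.start < self.exon23.end <= self.tir3.start):
            raise ValueError("exon 2-3 segment must lie strictly inside the TIRs")

    @property
    def total_length(self) -> int:
        return len(self.residues)

    def segment(self, iv: Interval) -> str:
        return self.residues[iv.start:iv.end]

    # --- persistence -----------------------------------------------------
    def write(self, fasta_path: str | Path, yaml_path: str | Path) -> None:
        write_fasta({self.name: GenomeSequence(self.name, self.residues)}, fasta_path)
        meta = {
            "name": self.name,
            "hexamer": self.hexamer,
            "segments": {
                key: [getattr(self, key).start, getattr(self, key).end]
                for key in ("tir5", "tir3", "str5", "str3", "exon23")
            },
        }
        Path(yaml_path).write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read(cls, fasta_path: str | Path, yaml_path: str | Path) -> "AcReference":
        genome = read_fasta(fasta_path)
        meta = yaml.safe_load(Path(yaml_path).read_text())
        name = meta.get("name") or next(iter(genome))
        seq = genome[name].residues
        segs = {k: Interval(name, int(v[0]), int(v[1]))
                for k, v in meta["segments"].items()}
        return cls(residues=seq, hexamer=meta.get("hexamer", HEXAMER),
                   name=name, **segs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a mapping of name -> :class:`GenomeSequence`.

    Lowercase and ``U`` are normalized; symbols outside ``{A,C,G,T,N}`` are
    rejected.  Duplicate identifiers and empty files are errors.
    """
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence identifier {rec.id!r} in {path}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome | Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    records = [
        SeqRecord(Seq(get_residues(genome, name)), id=name, description="")
        for name in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_intervals(path: str | Path,
                        feature_types: Iterable[str] = ("gene",)) -> list[Interval]:
    """Read intervals of the given feature types from a GFF3 file.

    GFF3 is 1-based inclusive; returned intervals are 0-based half-open.
    """
    wanted = set(feature_types)
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] not in wanted:
                continue
            strand = cols[6] if cols[6] in "+-" else "+"
            out.append(Interval(cols[0], int(cols[3]) - 1, int(cols[4]), strand))
    return out


def write_gff3_genes(genes: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes, 1):
            fh.write(
                f"{g.seq_id}\tacds\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene{i}\n"
            )


# ---------------------------------------------------------------------------
# Element catalogs
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "seq_id", "start", "end", "strand", "length",
    "tir5_mm", "tir3_mm", "tsd_left", "tsd_right", "tsd_mm", "flank_identity",
    "score",
    "label", "length_bin", "hexamers5", "hexamers3", "mobile_hexamer_flag",
    "term5_len", "term3_len", "str5_cov", "str3_cov", "exon23_cov",
    "exon23_block", "full_cov", "best_identity",
    "context", "nearest_gene_distance", "flank_copy",
]

_INT_COLUMNS = {"start", "end", "length", "tir5_mm", "tir3_mm", "tsd_mm",
                "flank_identity", "score", "hexamers5", "hexamers3",
                "term5_len", "term3_len", "exon23_block",
                "nearest_gene_distance"}


def _record(el) -> dict:
    """Flatten an ElementCall / ClassifiedElement / annotated element."""
    call = getattr(el, "call", el)
    loc = call.location
    tsd = call.tsd
    rec = {
        "seq_id": loc.seq_id, "start": loc.start, "end": loc.end,
        "strand": loc.strand, "length": len(loc),
        "tir5_mm": call.tir5.mismatches, "tir3_mm": call.tir3.mismatches,
        "tsd_left": tsd.left_word if tsd else "",
        "tsd_right": tsd.right_word if tsd else "",
        "tsd_mm": tsd.mismatches if tsd else "",
        "flank_identity": getattr(call, "flank_identity", None),
        "score": call.score,
    }
    profile = getattr(el, "profile", None)
    if profile is not None:
        rec.update({
            "label": el.label, "length_bin": el.length_bin,
            "hexamers5": el.hexamers5, "hexamers3": el.hexamers3,
            "mobile_hexamer_flag": el.mobile_hexamer_flag,
            "term5_len": profile.term5_len, "term3_len": profile.term3_len,
            "str5_cov": profile.str5_cov, "str3_cov": profile.str3_cov,
            "exon23_cov": profile.exon23_cov, "exon23_block": profile.exon23_block,
            "full_cov": profile.full_cov, "best_identity": profile.best_identity,
        })
    ctx = getattr(el, "context", None)
    if ctx is not None and not isinstance(ctx, str):
        rec.update({
            "context": ctx.category,
            "nearest_gene_distance": ctx.nearest_gene_distance,
            "flank_copy": ctx.flank_copy_estimate,
        })
    return rec


def catalog_to_frame(elements) -> pd.DataFrame:
    """Build a catalog DataFrame from element objects (or pass one through)."""
    if isinstance(elements, pd.DataFrame):
        return elements
    rows = [_record(el) for el in elements]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    return df


def write_catalog(elements, path: str | Path, format: str = "tsv") -> None:
    """Write an element catalog as ``tsv``, ``bed``, or ``gff3``.

    TSV holds every catalog column and round-trips through
    :func:`read_catalog`.  BED is 0-based half-open; GFF3 1-based inclusive
    with feature type ``terminal_inverted_repeat_element``.
    """
    df = catalog_to_frame(elements)
    path = Path(path)
    def present(value) -> bool:
        return isinstance(value, str) and bool(value)

    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for i, row in df.iterrows():
                name = row["label"] if present(row.get("label")) \
                    else f"element{i + 1}"
                fh.write(f"{row['seq_id']}\t{row['start']}\t{row['end']}\t"
                         f"{name}\t{row['score']}\t{row['strand']}\n")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, row in df.iterrows():
                attrs = [f"ID=element{i + 1}"]
                if present(row.get("label")):
                    attrs.append(f"class={row['label']}")
                if present(row.get("tsd_left")):
                    attrs.append(f"tsd={row['tsd_left']}")
                if pd.notna(row.get("hexamers5")):
                    attrs.append(
                        f"hexamers={row['hexamers5']},{row['hexamers3']}")
                fh.write(
                    f"{row['seq_id']}\tacds\tterminal_inverted_repeat_element\t"
                    f"{row['start'] + 1}\t{row['end']}\t{row['score']}\t"
                    f"{row['strand']}\t.\t{';'.join(attrs)}\n"
                )
    else:
        raise ValueError(f"unknown catalog format {format!r}")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a TSV catalog written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype=object, keep_default_na=False)
    for col in df.columns:
        if col in _INT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        elif col in ("str5_cov", "str3_cov", "exon23_cov", "full_cov",
                     "best_identity", "flank_copy"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        elif col == "mobile_hexamer_flag":
            df[col] = df[col].map({"True": True, "False": False}).astype(object)
    return df
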