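"""Insertion-context, internal-cargo, and cross-genome annotation.

Once elements are called and classified, this module characterizes:

* **insertion context** -- whether an element sits in or within 200 bp of a
  gene model, in repetitive DNA, or in unique intergenic DNA.
  Repetitiveness is measured self-containedly as the median genome-wide
  copy number of 20-mers in the 200-bp flanks (:class:`KmerIndex`), with a
  configurable threshold standing in for a repeat-masking protocol.
* **internal cargo** -- LTR retrotransposons, other DNA transposons, nested
  TIR elements, captured gene fragments (with a GT..AG intron check), and
  residual intergenic filler inside the element body.
* **compound structure** -- elements that trapped extraneous DNA between
  their outermost termini, recognized by internal copies of the element's
  own 8-bp target-site word; the element is tiled into a core, cargo blocks,
  and an optional trailing truncated duplicate of the core.
* **excision products** -- the predicted "empty site" left behind when an
  element excises (flank + a single TSD copy + flank), the template of the
  PCR assay used to score mobility.
* **junction reads** -- transposon-display products (host flank + element
  terminus) matched against a catalog to score insertion sites as shared
  between genomes, polymorphic, or unmapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from .core import (
    Genome, HEXAMER, IUPAC, Interval, TIR5_MOTIF, TIR_LEN, TSD_LEN,
    get_residues, reverse_complement,
)
from .classify import LocalAlignment, align_local, make_aligner
from .tir_scan import (
    ElementCall, ScanParams, TSDEvidence, hamming, scan_genome,
)

log = logging.getLogger("acds")


# ---------------------------------------------------------------------------
# Flank copy number (k-mer index)
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all k-mers of ``seq``; -1 where N occurs."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        codes = arr[i:i + n]
        valid &= codes >= 0
        fwd += np.where(codes >= 0, codes, 0) * weights[i]
        rev += np.where(codes >= 0, 3 - codes, 0) * weights[k - 1 - i]
    canon = np.minimum(fwd, rev)
    canon[~valid] = -1
    return canon


class KmerIndex:
    """Genome-wide canonical k-mer occurrence counts (strand-symmetric)."""

    def __init__(self, genome: Genome | str, k: int = 20):
        self.k = k
        parts = []
        names = ["seq"] if isinstance(genome, str) else list(genome)
        for name in names:
            codes = _encode_kmers(get_residues(genome, name), k)
            parts.append(codes[codes >= 0])
        allc = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        self._keys, self._counts = np.unique(allc, return_counts=True)

    def count(self, kmer: str) -> int:
        code = _encode_kmers(kmer, self.k)
        if len(code) != 1 or code[0] < 0:
            return 0
        i = np.searchsorted(self._keys, code[0])
        if i < len(self._keys) and self._keys[i] == code[0]:
            return int(self._counts[i])
        return 0

    def counts_of(self, seq: str) -> list[int]:
        codes = _encode_kmers(seq, self.k)
        out = []
        for c in codes:
            if c < 0:
                continue
            i = np.searchsorted(self._keys, c)
            if i < len(self._keys) and self._keys[i] == c:
                out.append(int(self._counts[i]))
            else:
                out.append(0)
        return out


def flank_copy_number(call: ElementCall, genome: Genome | str,
                      index: KmerIndex | None = None, k: int = 20,
                      flank: int = 200,
                      max_n_fraction: float = 0.1) -> float | None:
    """Median genome-wide copy number of the k-mers in the element's flanks.

    Flanks with more than ``max_n_fraction`` N are skipped; if both flanks
    are unavailable the estimate is absent (None).  Only k-mers lying wholly
    outside the element are used.
    """
    index = index or KmerIndex(genome, k)
    seq = get_residues(genome, call.location.seq_id)
    start, end = call.location.start, call.location.end
    counts: list[int] = []
    for lo, hi in ((max(0, start - flank), start), (end, min(len(seq), end + flank))):
        if hi - lo < index.k:
            continue
        window = seq[lo:hi]
        if window.count("N") / len(window) > max_n_fraction:
            continue
        counts.extend(index.counts_of(window))
    if not counts:
        return None
    return float(median(counts))


# ---------------------------------------------------------------------------
# Insertion context
# ---------------------------------------------------------------------------

@dataclass
class InsertionContext:
    """Where an element landed: genic, repetitive, or intergenic."""

    category: str
    nearest_gene_distance: int | None
    flank_copy_estimate: float | None


def insertion_context(call: ElementCall,
                      gene_models: Sequence[Interval] | None,
                      flank_copy: float | None,
                      repeat_threshold: float = 2.0,
                      gene_window: int = 200) -> InsertionContext:
    """Categorize an insertion site with precedence genic > repetitive > intergenic.

    ``genic`` means a gene model lies in or within ``gene_window`` bp of the
    element (strand ignored); ``repetitive`` means the flank copy-number
    estimate reaches ``repeat_threshold``.
    """
    nearest = None
    if gene_models:
        for g in gene_models:
            if g.seq_id != call.location.seq_id:
                continue
            if g.end <= call.location.start:
                d = call.location.start - g.end
            elif g.start >= call.location.end:
                d = g.start - call.location.end
            else:
                d = 0
            nearest = d if nearest is None else min(nearest, d)
    if nearest is not None and nearest <= gene_window:
        category = "genic"
    elif flank_copy is not None and flank_copy >= repeat_threshold:
        category = "repetitive"
    else:
        category = "intergenic"
    return InsertionContext(category, nearest, flank_copy)


# ---------------------------------------------------------------------------
# Internal cargo
# ---------------------------------------------------------------------------

@dataclass
class InternalFeature:
    """One annotated feature inside an element (element coordinates)."""

    kind: str                    # ltr_retro | dna_transposon | nested_element
    #                            # | gene_fragment | intergenic_filler
    start: int
    end: int
    donor: str | None = None
    intron_ok: bool | None = None
    score: float = 0.0


def _library_kind(record_id: str) -> str:
    if "#" in record_id:
        tag = record_id.rsplit("#", 1)[1].lower()
        if tag in ("ltr_retro", "ltr", "retro"):
            return "ltr_retro"
        if tag in ("dna_transposon", "dna", "tir"):
            return "dna_transposon"
    return "dna_transposon"


def internal_feature_scan(element_seq: str,
                          repeat_library: Mapping[str, str] | None = None,
                          gene_db: Mapping[str, str] | None = None,
                          scan_params: ScanParams | None = None,
                          min_identity: float = 0.8,
                          min_match_len: int = 100,
                          min_filler_len: int = 10) -> list[InternalFeature]:
    """Annotate the interior of an element (between its TIRs).

    Cargo features are local-alignment matches (identity >= ``min_identity``
    over >= ``min_match_len`` bp) of the interior against the repeat library
    and gene database; nested TIR elements come from a recursive scan.  Two
    exon matches of one donor separated by an interior segment with GT..AG
    termini are merged into a single gene fragment with ``intron_ok``.
    Overlaps are resolved best-score-first, then longest; residual interior
    runs are reported as intergenic filler.  Features never extend into the
    TIRs.
    """
    interior_start, interior_end = TIR_LEN, len(element_seq) - TIR_LEN
    interior = element_seq[interior_start:interior_end]
    if not interior:
        return []
    aligner = make_aligner()
    candidates: list[InternalFeature] = []

    def matches_of(db: Mapping[str, str], kind_of) -> list[InternalFeature]:
        found = []
        for rec_id in db or {}:
            target = get_residues(db, rec_id)
            aln = align_local(interior, target, aligner)
            if aln.empty:
                continue
            qs, qe = aln.query_interval
            if aln.identity >= min_identity and (qe - qs) >= min_match_len:
                found.append(InternalFeature(
                    kind=kind_of(rec_id), start=interior_start + qs,
                    end=interior_start + qe, donor=rec_id, score=aln.score))
        return found

    candidates.extend(matches_of(repeat_library, _library_kind))

    gene_matches = matches_of(gene_db, lambda _: "gene_fragment")
    # pair exon matches from the same donor gene and check the intron
    by_donor: dict[str, list[InternalFeature]] = {}
    for m in gene_matches:
        donor = m.donor.split(".")[0]
        by_donor.setdefault(donor, []).append(m)
    for donor, ms in by_donor.items():
        ms.sort(key=lambda m: m.start)
        merged: list[InternalFeature] = []
        i = 0
        while i < len(ms):
            m = ms[i]
            if i + 1 < len(ms):
                nxt = ms[i + 1]
                between = element_seq[m.end:nxt.start]
                if (len(between) >= 4 and between.startswith("GT")
                        and between.endswith("AG")):
                    merged.append(InternalFeature(
                        kind="gene_fragment", start=m.start, end=nxt.end,
                        donor=donor, intron_ok=True,
                        score=m.score + nxt.score))
                    i += 2
                    continue
            merged.append(replace(m, donor=donor, intron_ok=False))
            i += 1
        candidates.extend(merged)

    # nested TIR elements inside the interior
    nested_params = scan_params or ScanParams()
    for call in scan_genome(interior, nested_params):
        candidates.append(InternalFeature(
            kind="nested_element",
            start=interior_start + call.location.start,
            end=interior_start + call.location.end,
            score=float(call.length)))

    candidates.sort(key=lambda f: (-f.score, -(f.end - f.start), f.start))
    kept: list[InternalFeature] = []
    for cand in candidates:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda f: f.start)

    # residual interior = filler
    features: list[InternalFeature] = []
    cursor = interior_start
    for k in kept:
        if k.start - cursor >= min_filler_len:
            features.append(InternalFeature("intergenic_filler", cursor, k.start))
        features.append(k)
        cursor = k.end
    if interior_end - cursor >= min_filler_len:
        features.append(InternalFeature("intergenic_filler", cursor, interior_end))
    return features


# ---------------------------------------------------------------------------
# Compound decomposition
# ---------------------------------------------------------------------------

@dataclass
class CompoundSegment:
    role: str                  # core_element | cargo | truncated_duplicate
    start: int
    end: int


@dataclass
class CompoundDecomposition:
    """Tiling of a compound element into core, cargo, and duplicate."""

    segments: list[CompoundSegment]
    extra_tsd_positions: list[int]

    def lengths(self) -> list[int]:
        return [s.end - s.start for s in self.segments]


def _tir3_mismatches(window: str, motif: str = TIR5_MOTIF) -> int:
    pattern = reverse_complement(motif)
    return sum(w not in IUPAC[p] for w, p in zip(window, pattern))


def decompose_compound(element_seq: str, tsd: TSDEvidence | None,
                       tir_mm: int = 2,
                       dup_min_identity: float = 0.8,
                       dup_min_len: int = 50) -> CompoundDecomposition:
    """Tile a compound element at internal copies of its own TSD word.

    Serial insertion at a target site leaves extra copies of the 8-bp target
    word between the trapped blocks; each internal exact copy opens a new
    segment.  The first segment is the core element (it ends in a 3' TIR
    followed by the internal TSD copy); the last segment is labelled a
    truncated duplicate when it ends in a 3' TIR and locally aligns to the
    core.  Segments always tile the element without gaps or overlaps.
    """
    n = len(element_seq)
    if tsd is None:
        return CompoundDecomposition([CompoundSegment("core_element", 0, n)], [])
    word = tsd.left_word
    positions: list[int] = []
    i = element_seq.find(word, TIR_LEN + TSD_LEN)
    while i != -1:
        if i + TSD_LEN <= n - TIR_LEN:
            positions.append(i)
            i = element_seq.find(word, i + TSD_LEN)
        else:
            break
    if not positions:
        return CompoundDecomposition([CompoundSegment("core_element", 0, n)], [])

    bounds = [0] + positions + [n]
    segments = []
    aligner = make_aligner()
    core_seq = element_seq[bounds[0]:bounds[1]]
    for j in range(len(bounds) - 1):
        start, end = bounds[j], bounds[j + 1]
        if j == 0:
            role = "core_element"
        elif j == len(bounds) - 2:
            role = "cargo"
            tail = element_seq[start:end]
            if _tir3_mismatches(tail[-TIR_LEN:]) <= tir_mm:
                aln = align_local(tail, core_seq, aligner)
                qs, qe = aln.query_interval
                if (not aln.empty and aln.identity >= dup_min_identity
                        and (qe - qs) >= dup_min_len):
                    role = "truncated_duplicate"
        else:
            role = "cargo"
        segments.append(CompoundSegment(role, start, end))
    return CompoundDecomposition(segments, positions)


# ---------------------------------------------------------------------------
# Excision products and junction matching
# ---------------------------------------------------------------------------

def empty_site_sequence(call: ElementCall, genome: Genome | str,
                        flank: int = 500) -> str:
    """Predicted post-excision ("empty site") sequence at an element's locus.

    The excision footprint convention is a single intact TSD copy: the
    returned template is ``flank + TSD + flank`` (length ``2*flank + 8``).
    Elements without TSD evidence get their flanks joined directly, with a
    warning.
    """
    seq = get_residues(genome, call.location.seq_id)
    start, end = call.location.start, call.location.end
    if call.tsd is None:
        log.warning("element %s has no TSD; joining flanks directly", call.id)
        return seq[max(0, start - flank):start] + seq[end:end + flank]
    left = seq[max(0, start - TSD_LEN - flank):start - TSD_LEN]
    right = seq[end + TSD_LEN:end + TSD_LEN + flank]
    return left + call.tsd.left_word + right


def _motif_occurrences(read: str, motif: str = TIR5_MOTIF,
                       max_mm: int = 2) -> list[tuple[int, int]]:
    """(mismatches, position) of every 5'-TIR motif window in the read."""
    allowed = [IUPAC[s] for s in motif]
    out = []
    for i in range(len(read) - TIR_LEN + 1):
        window = read[i:i + TIR_LEN]
        if "N" in window:
            continue
        mm = sum(b not in a for b, a in zip(window, allowed))
        if mm <= max_mm:
            out.append((mm, i))
    return out


def match_junction(read: str, catalog: Sequence[ElementCall],
                   genome: Genome | str, min_flank_match: int = 30,
                   seed_len: int = 20, min_identity: float = 0.9,
                   slack: int = TSD_LEN) -> str:
    """Classify a transposon-display junction read against a catalog.

    The read is host flank followed by an element 5' terminus (beginning with
    the TIR).  The host portion is located in the genome (seed-and-verify,
    both orientations, identity >= ``min_identity`` over at least
    ``min_flank_match`` bp); the junction is ``shared`` when a cataloged
    element terminus lies within ``slack`` bp of the mapped junction point,
    ``polymorphic`` when the host maps but no element is adjacent, and
    ``unmapped`` otherwise.
    """
    if len(read) < min_flank_match + TIR_LEN:
        raise ValueError("read shorter than min_flank_match + TIR length")
    # candidate junction offsets: best motif match first, longer host
    # preferred (chance near-motif windows early in the flank lose out)
    occurrences = [(mm, i) for mm, i in _motif_occurrences(read)
                   if i >= min_flank_match]
    occurrences.sort(key=lambda x: (x[0], -x[1]))
    candidates = [i for _, i in occurrences]
    names = ["seq"] if isinstance(genome, str) else list(genome)

    def verify(seq: str, end_pos: int, template: str) -> bool:
        m = min(len(template), end_pos)
        if m < min_flank_match:
            return False
        genomic = seq[end_pos - m:end_pos]
        dist = hamming(genomic, template[-m:])
        return (m - dist) / m >= min_identity

    def map_host(host: str) -> list[tuple[str, int]]:
        junctions: list[tuple[str, int]] = []
        for name in names:
            seq = get_residues(genome, name)
            # forward orientation: host flank ends at the junction point
            seed = host[-seed_len:]
            k = seq.find(seed)
            while k != -1:
                end_pos = k + len(seed)
                if verify(seq, end_pos, host):
                    junctions.append((name, end_pos))
                k = seq.find(seed, k + 1)
            # reverse orientation: rc(host) begins at the junction point
            rc_host = reverse_complement(host)
            seed = rc_host[:seed_len]
            k = seq.find(seed)
            while k != -1:
                m = min(len(rc_host), len(seq) - k)
                if m >= min_flank_match:
                    dist = hamming(seq[k:k + m], rc_host[:m])
                    if (m - dist) / m >= min_identity:
                        junctions.append((name, k))
                k = seq.find(seed, k + 1)
        return junctions

    for j in candidates:
        junctions = map_host(read[:j])
        if not junctions:
            continue
        for name, pos in junctions:
            for call in catalog:
                if call.location.seq_id != name:
                    continue
                if (abs(call.location.start - pos) <= slack
                        or abs(call.location.end - pos) <= slack):
                    return "shared"
        return "polymorphic"
    return "unmapped"
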