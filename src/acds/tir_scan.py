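"""Mismatch-tolerant TIR motif scanning, TIR pairing, and TSD validation.

This is the discovery core of the toolkit.  Ac/Ds-family elements are bounded
by an 11-bp terminal inverted repeat (5' ``[C/T]AGGGATGAAA``, 3'
``TTTCATCCCT[A/G]``) and flanked by an 8-bp target-site duplication (TSD)
created on insertion.  Discovery proceeds in three steps:

1. :func:`scan_motif` finds every 11-bp window on both strands within a
   Hamming-distance budget of the (degenerate) TIR motif.  Because the two
   TIRs are mutual reverse complements, every motif match is simultaneously a
   5'-end hit of an element on one strand and a 3'-end hit of an element on
   the other; both interpretations are emitted.
2. :func:`pair_candidates` pairs 5' with 3' hits of the same element strand
   within a length window, requires a TSD (two 8-mers immediately outside the
   element within a mismatch budget), and resolves competing pairings
   innermost-first so that elements nested inside larger elements are still
   detected.
3. :func:`rescue_no_tsd` re-runs pairing without the TSD requirement and
   reports only calls absent from the primary catalog, annotated with the
   identity of the flanking 8-mers (decayed elements whose TSD has mutated
   away).  Without the TSD constraint a mismatch-tolerant motif scan pairs
   essentially at random on megabase-scale sequence, so the rescue scan
   demands perfect TIRs by default.

The degenerate motif position (Y/R) never counts as a mismatch, and windows
overlapping ``N`` runs are discarded.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    IUPAC, TIR5_MOTIF, TIR_LEN, TSD_LEN,
    Genome, Interval, get_residues, reverse_complement,
)

log = logging.getLogger("acds")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class TIRHit:
    """One strand-aware match of the TIR motif."""

    location: Interval
    end_type: str              # five_prime | three_prime, in element orientation
    element_strand: str        # strand of the element this hit would belong to
    mismatches: int
    matched_seq: str


@dataclass(frozen=True)
class TSDEvidence:
    """The two 8-mers immediately outside an element and their distance."""

    left_word: str
    right_word: str
    mismatches: int


@dataclass
class ElementCall:
    """A paired-TIR candidate element (TIR-inclusive, TSD-exclusive)."""

    location: Interval
    tir5: TIRHit
    tir3: TIRHit
    tsd: TSDEvidence | None
    score: int
    flank_identity: int | None = None

    @property
    def length(self) -> int:
        return len(self.location)

    @property
    def id(self) -> str:
        loc = self.location
        return f"{loc.seq_id}:{loc.start}-{loc.end}({loc.strand})"


@dataclass
class ScanParams:
    """All tunables of the discovery scan."""

    motif: str = TIR5_MOTIF
    tir_mm: int = 2
    tsd_mm: int = 2
    min_len: int = 50
    max_len: int = 30000
    require_tsd: bool = True
    rescue_tir_mm: int = 0


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _position_tables(motif: str) -> list[np.ndarray]:
    """Per-position byte lookup tables; N in the genome matches nothing."""
    tables = []
    for sym in motif:
        allowed = IUPAC.get(sym)
        if allowed is None:
            raise ValueError(f"invalid motif symbol {sym!r}")
        tab = np.zeros(256, dtype=bool)
        for b in allowed:
            tab[ord(b)] = True
        tab[ord("N")] = False
        tables.append(tab)
    return tables


def _window_mismatches(arr: np.ndarray, tables: list[np.ndarray]) -> np.ndarray:
    k = len(tables)
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for i, tab in enumerate(tables):
        mm += ~tab[arr[i:i + n]]
    # windows touching an N are discarded outright
    has_n = (arr == ord("N")).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(has_n)))
    n_in_window = cum[k:] - cum[:-k]
    mm[n_in_window > 0] = k + 1
    return mm


def scan_motif(genome: Genome | str, motif: str = TIR5_MOTIF,
               max_mm: int = 2) -> list[TIRHit]:
    """Find all TIR motif hits on both strands within ``max_mm`` mismatches.

    Each window matching the 5' motif is emitted both as a five_prime hit of
    a plus-strand element and a three_prime hit of a minus-strand element
    (and symmetrically for the reverse-complement motif).  Degenerate motif
    positions match their allowed set at zero cost.
    """
    if len(motif) != TIR_LEN:
        raise ValueError(f"TIR motif must be {TIR_LEN} bp, got {len(motif)}")
    if max_mm not in (0, 1, 2):
        raise ValueError(f"max_mm must be 0, 1 or 2, got {max_mm}")
    if isinstance(genome, str):
        genome = {"seq": genome}

    fwd_tables = _position_tables(motif)
    rev_tables = _position_tables(reverse_complement(motif))

    hits: list[TIRHit] = []
    for seq_id in genome:
        seq = get_residues(genome, seq_id)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for tables, roles in (
            (fwd_tables, ((FIVE_PRIME, "+"), (THREE_PRIME, "-"))),
            (rev_tables, ((THREE_PRIME, "+"), (FIVE_PRIME, "-"))),
        ):
            mm = _window_mismatches(arr, tables)
            for pos in np.flatnonzero(mm <= max_mm):
                pos = int(pos)
                window = seq[pos:pos + TIR_LEN]
                for end_type, strand in roles:
                    hits.append(TIRHit(
                        location=Interval(seq_id, pos, pos + TIR_LEN, strand),
                        end_type=end_type, element_strand=strand,
                        mismatches=int(mm[pos]), matched_seq=window,
                    ))
    hits.sort(key=lambda h: (h.location.seq_id, h.location.start,
                             h.element_strand, h.end_type))
    return hits


def detect_tsd(genome: Genome | str, seq_id: str, left_boundary: int,
               right_boundary: int, max_mm: int = 2) -> TSDEvidence | None:
    """TSD evidence for an element spanning [left_boundary, right_boundary).

    Returns the 8-mers at ``[start-8, start)`` and ``[end, end+8)`` with
    their Hamming distance, or None when the distance exceeds ``max_mm`` or a
    flank runs off the sequence.  Absence is a value, not an error.
    """
    seq = get_residues(genome, seq_id)
    if left_boundary - TSD_LEN < 0 or right_boundary + TSD_LEN > len(seq):
        return None
    left = seq[left_boundary - TSD_LEN:left_boundary]
    right = seq[right_boundary:right_boundary + TSD_LEN]
    mm = hamming(left, right)
    if mm > max_mm:
        return None
    return TSDEvidence(left, right, mm)


def _candidates(hits: Sequence[TIRHit], genome: Genome | str,
                params: ScanParams) -> list[ElementCall]:
    by_key: dict[tuple, list[TIRHit]] = {}
    for h in hits:
        by_key.setdefault(
            (h.location.seq_id, h.element_strand, h.end_type), []).append(h)

    tsd_budget = params.tsd_mm if params.require_tsd else TSD_LEN
    out: list[ElementCall] = []
    seqs = {key[0] for key in by_key}
    for seq_id in seqs:
        for strand in "+-":
            fives = by_key.get((seq_id, strand, FIVE_PRIME), [])
            threes = by_key.get((seq_id, strand, THREE_PRIME), [])
            if not fives or not threes:
                continue
            # left terminus of the element span: 5' hit on +, 3' hit on -
            lefts, rights = (fives, threes) if strand == "+" else (threes, fives)
            rights = sorted(rights, key=lambda h: h.location.start)
            starts = [h.location.start for h in rights]
            for left in lefts:
                lo = bisect_left(starts, left.location.end)
                hi = bisect_right(starts, left.location.start + params.max_len)
                for right in rights[lo:hi]:
                    start, end = left.location.start, right.location.end
                    if not (params.min_len <= end - start <= params.max_len):
                        continue
                    tsd = detect_tsd(genome, seq_id, start, end, tsd_budget)
                    if params.require_tsd and tsd is None:
                        continue
                    tir5, tir3 = (left, right) if strand == "+" else (right, left)
                    score = tir5.mismatches + tir3.mismatches + (
                        tsd.mismatches if tsd else 0)
                    out.append(ElementCall(
                        location=Interval(seq_id, start, end, strand),
                        tir5=tir5, tir3=tir3, tsd=tsd, score=score,
                        flank_identity=(TSD_LEN - tsd.mismatches) if tsd else None,
                    ))
    return out


def pair_candidates(hits: Sequence[TIRHit], genome: Genome | str,
                    params: ScanParams | None = None) -> list[ElementCall]:
    """Pair TIR hits into element calls with TSD validation.

    Among candidate calls sharing a TIR window, selection is innermost-first
    (shortest span), then lowest mismatch score, then leftmost, with the plus
    strand preferred on exact ties.  Each 11-bp genome window supports at most
    one emitted call, which both deduplicates the strand-symmetric
    interpretation of a perfect element and keeps nested elements visible.
    """
    params = params or ScanParams()
    cands = _candidates(hits, genome, params)
    cands.sort(key=lambda c: (c.length, c.score, c.location.start,
                              c.location.strand == "-"))
    used_windows: set[tuple[str, int]] = set()
    seen_spans: set[tuple[str, int, int]] = set()
    accepted: list[ElementCall] = []
    for c in cands:
        span = (c.location.seq_id, c.location.start, c.location.end)
        w5 = (c.location.seq_id, c.tir5.location.start)
        w3 = (c.location.seq_id, c.tir3.location.start)
        if span in seen_spans or w5 in used_windows or w3 in used_windows:
            continue
        seen_spans.add(span)
        used_windows.update((w5, w3))
        accepted.append(c)
    accepted.sort(key=lambda c: (c.location.seq_id, c.location.start))
    return accepted


def scan_genome(genome: Genome | str,
                params: ScanParams | None = None) -> list[ElementCall]:
    """Convenience: motif scan + pairing with one parameter set."""
    params = params or ScanParams()
    hits = scan_motif(genome, params.motif, params.tir_mm)
    return pair_candidates(hits, genome, params)


def rescue_no_tsd(genome: Genome | str, primary: Sequence[ElementCall],
                  params: ScanParams | None = None) -> list[ElementCall]:
    """Re-scan without the TSD requirement; report only novel calls.

    Calls overlapping the primary catalog are dropped.  Each rescued call is
    annotated with the identity of its flanking 8-mers out of 8
    (``flank_identity``), the signature of a decayed target-site duplication.
    Perfect TIRs are required by default (``params.rescue_tir_mm``).
    """
    params = params or ScanParams()
    rescue_params = replace(params, tir_mm=params.rescue_tir_mm,
                            require_tsd=False)
    hits = scan_motif(genome, rescue_params.motif, rescue_params.tir_mm)
    calls = pair_candidates(hits, genome, rescue_params)
    out = []
    for c in calls:
        if any(c.location.overlaps(p.location) for p in primary):
            continue
        out.append(c)
    return out


def verify_call(call: ElementCall, genome: Genome | str,
                params: ScanParams | None = None) -> bool:
    """Re-verify a call's TIR and TSD evidence directly against the genome."""
    params = params or ScanParams()
    seq = get_residues(genome, call.location.seq_id)
    for hit in (call.tir5, call.tir3):
        window = seq[hit.location.start:hit.location.end]
        if window != hit.matched_seq:
            return False
        pattern = (params.motif if (hit.end_type == FIVE_PRIME)
                   == (hit.element_strand == "+")
                   else reverse_complement(params.motif))
        mm = sum(w not in IUPAC[p] for w, p in zip(window, pattern))
        if mm != hit.mismatches or mm > max(params.tir_mm, params.rescue_tir_mm):
            return False
    if call.tsd is not None:
        left = seq[call.location.start - TSD_LEN:call.location.start]
        right = seq[call.location.end:call.location.end + TSD_LEN]
        if (left, right) != (call.tsd.left_word, call.tsd.right_word):
            return False
        if hamming(left, right) != call.tsd.mismatches:
            return False
    return True
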