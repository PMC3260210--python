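"""Homology-based classification of called elements against a reference Ac.

Nonautonomous Ds elements are deletion/decay derivatives of the autonomous
4.6-kb Ac element and are recognized by which parts of Ac they retain:

* ``Ac-like`` -- near-complete copies of Ac (small indels only);
* ``Ds2``     -- retain the ~200-bp subterminal regions (STRs) at both ends,
  with unrelated internal "filler" DNA;
* ``Ds-l3``   -- retain fragments of transposase exons 2-3 but not the STRs
  (decaying Ac remnants, ~4 kb on average);
* ``Ds1``     -- short (<500 bp) elements sharing a common family filler and
  essentially nothing with Ac beyond the TIRs;
* ``Ds-l4``   -- ~1-kb elements whose homology with Ac is limited to ~30 bp
  at either end, with variable filler.

A :class:`HomologyProfile` captures terminal identity-run lengths and local
alignment coverage of the reference STRs, the exon-2/3 segment, and the full
reference; :func:`assign_class` runs a first-match-wins decision cascade over
that profile.  The AAACGG transposase-binding hexamer is counted in the
200-bp subterminal windows of each element; three or more copies are the
classical mobility requirement.

Local alignments use Smith-Waterman scoring (match +1, mismatch -1, gap open
-2, gap extend -1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from intervaltree import IntervalTree

from .core import (
    AcReference, Genome, HEXAMER, Interval, catalog_to_frame, get_residues,
    reverse_complement,
)
from .tir_scan import ElementCall

log = logging.getLogger("acds")

CLASS_ORDER = ["Ds1", "Ds2", "Ds-l3", "Ds-l4", "Ac-like"]
LENGTH_BINS = ["<500", "500-1000", "1000-5000", ">5000"]


def make_aligner(match: float = 1, mismatch: float = -1,
                 gap_open: float = -2, gap_extend: float = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class LocalAlignment:
    """Summary of the maximal-scoring local alignment of query vs target."""

    score: float
    identity: float            # identities / alignment columns
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    identities: int
    columns: int               # alignment length including gaps
    target_matched: int        # target positions aligned to an identical base
    max_block: int             # longest gap-free aligned block (bp)

    @property
    def empty(self) -> bool:
        return self.columns == 0


_EMPTY_ALIGNMENT = LocalAlignment(0.0, 0.0, (0, 0), (0, 0), 0, 0, 0, 0)


def align_local(query: str, target: str,
                aligner: Align.PairwiseAligner | None = None) -> LocalAlignment:
    """Maximal-scoring local alignment (Smith-Waterman with affine gaps)."""
    if not query or not target:
        raise ValueError("align_local requires non-empty sequences")
    aligner = aligner or make_aligner()
    alns = aligner.align(target, query)
    score = alns.score
    if score <= 0:
        return _EMPTY_ALIGNMENT
    aln = next(iter(alns))
    t_blocks, q_blocks = aln.aligned
    identities = 0
    target_matched = 0
    max_block = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        block = sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
        identities += block
        target_matched += block
        max_block = max(max_block, te - ts)
    columns = aln.length
    return LocalAlignment(
        score=float(score),
        identity=identities / columns if columns else 0.0,
        query_interval=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        target_interval=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        identities=identities, columns=columns,
        target_matched=target_matched, max_block=max_block,
    )


@dataclass
class HomologyProfile:
    """How much of the reference Ac an element retains, and where."""

    term5_len: int
    term3_len: int
    str5_cov: float
    str3_cov: float
    exon23_cov: float
    exon23_block: int
    full_cov: float
    best_identity: float


@dataclass
class ClassifyParams:
    """Thresholds of the class decision cascade (all configurable)."""

    ac_full_cov: float = 0.9
    ac_identity: float = 0.9
    ds2_str_cov: float = 0.5
    dsl3_exon_cov: float = 0.1
    dsl3_min_block: int = 200
    ds1_max_len: int = 500
    ds1_consensus_identity: float = 0.7
    ds1_consensus_span: int = 100
    terminal_max: int = 40
    terminal_identity: float = 0.8
    hexamer_window: int = 200
    mobile_min_hexamers: int = 3


def _terminal_run(a: str, b: str, min_identity: float = 0.8,
                  block: int = 10) -> int:
    """Length of the contiguous terminal identity run between two strings.

    Ungapped comparison from position 0 in windows of ``block`` bp; the first
    window below ``min_identity`` stops the extension, after counting its
    leading exact matches.
    """
    n = min(len(a), len(b))
    run = 0
    for start in range(0, n, block):
        wa, wb = a[start:start + block], b[start:start + block]
        matches = sum(x == y for x, y in zip(wa, wb))
        if len(wa) and matches / len(wa) >= min_identity:
            run = start + len(wa)
            continue
        for x, y in zip(wa, wb):
            if x != y:
                break
            run += 1
        break
    else:
        run = n
    return run


def element_sequence(call: ElementCall, genome: Genome | str) -> str:
    """Element residues in element orientation (5' TIR first)."""
    seq = get_residues(genome, call.location.seq_id)
    sub = seq[call.location.start:call.location.end]
    return reverse_complement(sub) if call.location.strand == "-" else sub


def orient_element(element_seq: str, ac_ref: AcReference,
                   aligner: Align.PairwiseAligner | None = None) -> str:
    """Return the element in the orientation with more reference homology.

    The two TIRs are reverse complements of each other, so a discovered
    element is orientation-ambiguous; whichever orientation aligns better
    against the full reference is taken as the element's own 5'->3' strand.
    Ties (elements with no internal homology) keep the given orientation.
    """
    aligner = aligner or make_aligner()
    rc = reverse_complement(element_seq)
    fwd = align_local(element_seq, ac_ref.residues, aligner)
    rev = align_local(rc, ac_ref.residues, aligner)
    return rc if rev.score > fwd.score else element_seq


def homology_profile(element_seq: str, ac_ref: AcReference,
                     params: ClassifyParams | None = None,
                     aligner: Align.PairwiseAligner | None = None,
                     full_aln: LocalAlignment | None = None) -> HomologyProfile:
    """Profile an element's homology to the reference Ac.

    Terminal run lengths come from ungapped extension against the reference
    ends; coverages are identity-weighted fractions of each reference segment
    recovered by the maximal local alignment of the element against it.
    The element is assumed to be in its own 5'->3' orientation (see
    :func:`orient_element`).
    """
    if len(element_seq) < 2 * 11:
        raise ValueError("element shorter than two TIRs")
    params = params or ClassifyParams()
    aligner = aligner or make_aligner()
    ref = ac_ref.residues

    term5 = _terminal_run(element_seq, ref, params.terminal_identity)
    term3 = _terminal_run(element_seq[::-1], ref[::-1], params.terminal_identity)

    def seg_cov(segment: str) -> LocalAlignment:
        return align_local(element_seq, segment, aligner)

    a5 = seg_cov(ac_ref.segment(ac_ref.str5))
    a3 = seg_cov(ac_ref.segment(ac_ref.str3))
    ax = seg_cov(ac_ref.segment(ac_ref.exon23))
    af = full_aln if full_aln is not None else seg_cov(ref)
    return HomologyProfile(
        term5_len=term5, term3_len=term3,
        str5_cov=a5.target_matched / len(ac_ref.str5),
        str3_cov=a3.target_matched / len(ac_ref.str3),
        exon23_cov=ax.target_matched / len(ac_ref.exon23),
        exon23_block=ax.max_block,
        full_cov=af.target_matched / len(ref),
        best_identity=af.identity,
    )


def count_hexamers(element_seq: str, hexamer: str = HEXAMER,
                   window: int = 200) -> tuple[int, int]:
    """Count hexamer copies in the two subterminal windows of an element.

    Each window is read inward from its end on the element's own strand (the
    3' window on the reverse complement).  Elements shorter than two windows
    use their two halves.  AAACGG cannot overlap itself, so a plain substring
    count is exact.
    """
    w = min(window, len(element_seq) // 2)
    five = element_seq[:w].count(hexamer)
    three = reverse_complement(element_seq[-w:]).count(hexamer) if w else 0
    return five, three


def assign_class(element_seq: str, profile: HomologyProfile,
                 params: ClassifyParams | None = None,
                 ds1_consensus: str | None = None,
                 aligner: Align.PairwiseAligner | None = None) -> str:
    """First-match-wins decision cascade over a homology profile.

    Order: Ac-like (near-full coverage at high identity), Ds2 (both STRs),
    Ds-l3 (exon 2-3 block), Ds1 (short, family-consensus match or short
    termini), Ds-l4 (terminal homology only), else unclassified.
    """
    params = params or ClassifyParams()
    length = len(element_seq)
    if (profile.full_cov >= params.ac_full_cov
            and profile.best_identity >= params.ac_identity):
        return "Ac-like"
    if (profile.str5_cov >= params.ds2_str_cov
            and profile.str3_cov >= params.ds2_str_cov):
        return "Ds2"
    if (profile.exon23_cov >= params.dsl3_exon_cov
            and profile.exon23_block >= params.dsl3_min_block):
        return "Ds-l3"
    if length < params.ds1_max_len:
        if ds1_consensus is not None:
            aln = align_local(element_seq, ds1_consensus, aligner or make_aligner())
            span = aln.columns
            if (aln.identity >= params.ds1_consensus_identity
                    and span >= params.ds1_consensus_span):
                return "Ds1"
        else:
            log.warning("no Ds1 family consensus supplied; falling back to "
                        "length + terminal-homology rule for Ds1")
        if (profile.term5_len <= params.terminal_max
                and profile.term3_len <= params.terminal_max):
            return "Ds1"
    if (profile.term5_len <= params.terminal_max
            and profile.term3_len <= params.terminal_max):
        return "Ds-l4"
    return "unclassified"


def length_bin(length: int) -> str:
    if length < 500:
        return "<500"
    if length <= 1000:
        return "500-1000"
    if length <= 5000:
        return "1000-5000"
    return ">5000"


@dataclass
class ClassifiedElement:
    """An element call plus its homology profile and class label."""

    call: ElementCall
    profile: HomologyProfile
    hexamers5: int
    hexamers3: int
    length_bin: str
    label: str
    mobile_hexamer_flag: bool
    context: object | None = None


def classify_catalog(calls: Sequence[ElementCall], genome: Genome | str,
                     ac_ref: AcReference, ds1_consensus: str | None = None,
                     params: ClassifyParams | None = None) -> list[ClassifiedElement]:
    """Classify every call in a catalog; deterministic and order-independent.

    The mobility flag pools the hexamer counts of both subterminal windows
    (>= 3 copies overall); the per-end counts are recorded separately.
    """
    params = params or ClassifyParams()
    aligner = make_aligner()
    out = []
    for call in calls:
        seq = element_sequence(call, genome)
        rc = reverse_complement(seq)
        fwd_aln = align_local(seq, ac_ref.residues, aligner)
        rev_aln = align_local(rc, ac_ref.residues, aligner)
        full_aln = fwd_aln
        if rev_aln.score > fwd_aln.score:
            seq, full_aln = rc, rev_aln
        profile = homology_profile(seq, ac_ref, params, aligner, full_aln)
        h5, h3 = count_hexamers(seq, ac_ref.hexamer, params.hexamer_window)
        label = assign_class(seq, profile, params, ds1_consensus, aligner)
        out.append(ClassifiedElement(
            call=call, profile=profile, hexamers5=h5, hexamers3=h3,
            length_bin=length_bin(call.length), label=label,
            mobile_hexamer_flag=(h5 + h3) >= params.mobile_min_hexamers,
        ))
    return out


# ---------------------------------------------------------------------------
# Census tables and distribution statistics
# ---------------------------------------------------------------------------

def _chrom_sort_key(name: str):
    s = str(name)
    digits = "".join(ch for ch in s if ch.isdigit())
    return (0, int(digits)) if digits else (1, s)


def summarize_counts(catalog, rows: str = "chromosome",
                     cols: str = "class") -> pd.DataFrame:
    """Contingency table of element counts with 'Total' margins.

    ``rows``/``cols`` may be any of chromosome, class, length_bin,
    hexamer_flag.  Margins always equal the sum of cells.
    """
    df = catalog_to_frame(catalog)
    field_map = {"chromosome": "seq_id", "class": "label",
                 "length_bin": "length_bin", "context": "context",
                 "hexamer_flag": "mobile_hexamer_flag"}
    for axis in (rows, cols):
        if axis not in field_map:
            raise ValueError(f"unknown grouping {axis!r}")
    if df.empty:
        return pd.DataFrame({"Total": [0]}, index=pd.Index(["Total"], name=rows))
    table = pd.crosstab(df[field_map[rows]], df[field_map[cols]],
                        margins=True, margins_name="Total")
    table.index.name, table.columns.name = rows, cols
    order = [i for i in sorted(table.index[:-1], key=_chrom_sort_key)]
    col_order = [c for c in CLASS_ORDER if c in table.columns]
    col_order += [c for c in table.columns
                  if c not in col_order and c != "Total"]
    table = table.loc[order + ["Total"], col_order + ["Total"]]
    return table


def percentage_table(table: pd.DataFrame, of: str = "row") -> pd.DataFrame:
    """Rounded integer percentages of a count table (cells / margin).

    ``of='row'`` expresses each cell as a percent of its row total, the form
    used for insertion-context summaries (e.g. the share of each class found
    in or within 200 bp of a gene).  Rounding is half-up to whole percents.
    """
    counts = table.drop(index="Total", errors="ignore")
    denom = counts.get("Total")
    if of == "row" and denom is not None:
        body = counts.drop(columns="Total")
        pct = body.div(denom, axis=0) * 100
    else:
        total = counts.drop(columns="Total", errors="ignore").to_numpy().sum()
        pct = counts.drop(columns="Total", errors="ignore") / total * 100
    return pct.map(lambda x: int(math.floor(x + 0.5)))


def chi_square_distribution_test(observed: Mapping[str, int],
                                 chrom_lengths: Mapping[str, float]) -> tuple[float, int]:
    """Goodness-of-fit of per-chromosome counts vs chromosome length.

    Expected counts are proportional to chromosome length; elements on
    sequences absent from ``chrom_lengths`` (unplaced scaffolds) are excluded.
    Returns ``(chi2, df)`` with ``df = #chromosomes - 1``.
    """
    keys = [k for k in observed if k in chrom_lengths]
    if not keys:
        raise ValueError("no chromosomes in common between observed and lengths")
    for k in keys:
        if chrom_lengths[k] <= 0:
            raise ValueError(f"non-positive length for chromosome {k!r}")
    total = sum(observed[k] for k in keys)
    total_len = sum(chrom_lengths[k] for k in keys)
    chi2 = 0.0
    for k in keys:
        expected = total * chrom_lengths[k] / total_len
        chi2 += (observed[k] - expected) ** 2 / expected
    return chi2, len(keys) - 1


def compare_to_annotation(catalog, prior: Sequence[Interval],
                          full_threshold: float = 0.9) -> list[str]:
    """Per-element annotation status vs a prior feature set.

    ``full`` when a prior feature reciprocally overlaps >= ``full_threshold``
    of both intervals, ``partial`` for any lesser overlap, ``new`` otherwise.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in prior:
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
    df = catalog_to_frame(catalog)
    statuses = []
    for _, row in df.iterrows():
        tree = trees.get(row["seq_id"])
        status = "new"
        if tree is not None:
            start, end = int(row["start"]), int(row["end"])
            for hit in tree.overlap(start, end):
                ov = min(end, hit.end) - max(start, hit.begin)
                if ov <= 0:
                    continue
                if (ov >= full_threshold * (end - start)
                        and ov >= full_threshold * (hit.end - hit.begin)):
                    status = "full"
                    break
                status = "partial"
        statuses.append(status)
    return statuses
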