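"""Insertion context, internal cargo, compound tiling, excision, junctions."""

import numpy as np
import pytest

import acds
from acds.annotate import (
    KmerIndex, decompose_compound, empty_site_sequence, flank_copy_number,
    insertion_context, internal_feature_scan, match_junction,
)
from acds.core import Interval, reverse_complement
from acds.synthetic import (
    BackgroundSpec, ImplantSpec, build_compound_element, build_element,
    embed_cargo, generate_junction_reads, implant_genome, make_genome_pair,
)
from acds.tir_scan import (
    ElementCall, ScanParams, TIRHit, TSDEvidence, scan_genome, scan_motif,
)

from conftest import EXACT_SCAN, random_dna_py


def call_at(seq_id, start, end, tsd=None, strand="+"):
    loc = Interval(seq_id, start, end, strand)
    t5 = TIRHit(Interval(seq_id, start, start + 11, strand),
                "five_prime", strand, 0, "")
    t3 = TIRHit(Interval(seq_id, end - 11, end, strand),
                "three_prime", strand, 0, "")
    evidence = TSDEvidence(tsd, tsd, 0) if tsd else None
    return ElementCall(loc, t5, t3, evidence, 0)


class TestFlankCopyNumber:
    def test_unique_flanks(self, rng):
        genome = {"c": random_dna_py(rng, 50_000)}
        call = call_at("c", 20_000, 21_000)
        assert flank_copy_number(call, genome) == 1.0

    def test_copied_flank_counts_copies(self, rng):
        # a locus (flank + element + flank) pasted 10x: both flanks of the
        # first instance occur ~10 times genome-wide
        element = "TAGGGATGAAA" + random_dna_py(rng, 300) + "TTTCATCCCTA"
        locus = random_dna_py(rng, 200) + element + random_dna_py(rng, 200)
        background = random_dna_py(rng, 40_000)
        genome_seq = background
        for i in range(10):
            p = 2000 + i * 3000
            genome_seq = genome_seq[:p] + locus + genome_seq[p + len(locus):]
        genome = {"c": genome_seq}
        call = call_at("c", 2200, 2200 + len(element))
        fc = flank_copy_number(call, genome)
        assert 9 <= fc <= 11

    def test_invariant_under_reverse_complement(self, rng):
        genome_seq = random_dna_py(rng, 30_000)
        call = call_at("c", 10_000, 10_500)
        fc1 = flank_copy_number(call, {"c": genome_seq})
        n = len(genome_seq)
        rc_call = call_at("c", n - 10_500, n - 10_000)
        fc2 = flank_copy_number(rc_call, {"c": reverse_complement(genome_seq)})
        assert fc1 == fc2

    def test_flank_off_end_uses_available_side(self, rng):
        genome = {"c": random_dna_py(rng, 1000)}
        call = call_at("c", 3, 800)        # no left flank
        assert flank_copy_number(call, genome) is not None


class TestInsertionContext:
    def test_gene_within_window_is_genic(self):
        call = call_at("c", 1000, 1500)
        genes = [Interval("c", 1650, 3000)]    # 150 bp downstream
        ctx = insertion_context(call, genes, flank_copy=1.0)
        assert ctx.category == "genic" and ctx.nearest_gene_distance == 150

    def test_gene_just_outside_window_with_unique_flanks(self):
        call = call_at("c", 1000, 1500)
        genes = [Interval("c", 1701, 3000)]    # 201 bp away
        ctx = insertion_context(call, genes, flank_copy=1.0)
        assert ctx.category == "intergenic"

    def test_repetitive_flanks(self):
        ctx = insertion_context(call_at("c", 10, 100), [], flank_copy=5.0)
        assert ctx.category == "repetitive"

    def test_no_gene_models_never_genic(self):
        ctx = insertion_context(call_at("c", 10, 100), None, flank_copy=1.0)
        assert ctx.category == "intergenic"

    def test_categories_partition_synthetic_catalog(self):
        bundle = implant_genome(
            [ImplantSpec("Ds1", 4, context="genic"),
             ImplantSpec("Ds-l4", 4, context="repeat_array"),
             ImplantSpec("Ds2", 4, context="unique")],
            BackgroundSpec(length=300_000, gene_count=6, repeat_families=2,
                           repeat_copies=6),
            seed=13)
        calls = scan_genome(bundle.genome, EXACT_SCAN)
        index = KmerIndex(bundle.genome)
        want = {"genic": "genic", "repeat_array": "repetitive",
                "unique": "intergenic"}
        truth = {(t.start, t.end): t for t in bundle.truth}
        got = []
        for c in calls:
            fc = flank_copy_number(c, bundle.genome, index)
            ctx = insertion_context(c, bundle.genes, fc)
            got.append(ctx.category)
            assert ctx.category == want[truth[(c.location.start,
                                               c.location.end)].context]
        assert len(got) == len(bundle.truth)


class TestInternalFeatureScan:
    def test_gene_fragment_with_intron(self, ac_ref, pool, rng):
        seq = build_element("Ds2", ac_ref, rng, pool)
        seq, rec, donor_db = embed_cargo(seq, "gene_fragment", rng, pool)
        feats = internal_feature_scan(seq, gene_db=donor_db)
        frags = [f for f in feats if f.kind == "gene_fragment"]
        assert len(frags) == 1
        assert frags[0].intron_ok is True
        assert frags[0].donor == "donor1"
        assert (frags[0].start, frags[0].end) == (rec["start"], rec["end"])

    def test_ltr_retro_cargo(self, ac_ref, pool, rng):
        seq = build_element("Ds-l4", ac_ref, rng, pool)
        seq, rec, _ = embed_cargo(seq, "ltr_retro", rng, pool)
        feats = internal_feature_scan(
            seq, repeat_library={"famA#ltr_retro": pool.retro_family})
        retro = [f for f in feats if f.kind == "ltr_retro"]
        assert len(retro) == 1
        assert retro[0].start <= rec["start"] + 10
        assert retro[0].end >= rec["end"] - 10

    def test_nested_element_detected(self, ac_ref, pool, rng):
        seq = build_element("Ds-l3", ac_ref, rng, pool)
        seq, rec, _ = embed_cargo(seq, "nested_element", rng, pool)
        feats = internal_feature_scan(seq)
        nested = [f for f in feats if f.kind == "nested_element"]
        assert [(f.start, f.end) for f in nested] == [(rec["start"], rec["end"])]

    def test_plain_filler(self, ac_ref, pool, rng):
        seq = build_element("Ds1", ac_ref, rng, pool)
        feats = internal_feature_scan(seq)
        assert [f.kind for f in feats] == ["intergenic_filler"]
        assert (feats[0].start, feats[0].end) == (11, len(seq) - 11)

    def test_features_never_extend_into_tirs(self, ac_ref, pool, rng):
        for kind in ("ltr_retro", "gene_fragment", "nested_element"):
            seq = build_element("Ds-l3", ac_ref, rng, pool)
            seq, _, db = embed_cargo(seq, kind, rng, pool)
            feats = internal_feature_scan(
                seq, repeat_library={"fam#ltr_retro": pool.retro_family},
                gene_db=db)
            for f in feats:
                assert f.start >= 11 and f.end <= len(seq) - 11


class TestDecomposeCompound:
    def test_published_segment_architecture(self, ac_ref, rng, pool):
        seq, tsd, bounds = build_compound_element(ac_ref, rng, pool)
        assert len(seq) == 7344
        dec = decompose_compound(seq, TSDEvidence(tsd, tsd, 0))
        assert dec.lengths() == [987, 663, 4887, 807]
        assert [s.role for s in dec.segments] == \
            ["core_element", "cargo", "cargo", "truncated_duplicate"]
        assert sum(dec.lengths()) == 7344

    def test_simple_element_single_core(self, ac_ref, pool, rng):
        seq = build_element("Ds-l4", ac_ref, rng, pool)
        dec = decompose_compound(seq, TSDEvidence("ACGTACGT", "ACGTACGT", 0))
        assert [s.role for s in dec.segments] == ["core_element"]
        assert dec.lengths() == [len(seq)]

    def test_tiling_exact_on_random_compounds(self, ac_ref, pool):
        rng = np.random.default_rng(555)
        for _ in range(15):
            k = int(rng.integers(0, 3))
            lengths = [int(rng.integers(400, 1200))] \
                + [int(rng.integers(200, 2000)) for _ in range(k)] \
                + [int(rng.integers(150, 400))]
            seq, tsd, bounds = build_compound_element(
                ac_ref, rng, pool, segment_lengths=lengths)
            dec = decompose_compound(seq, TSDEvidence(tsd, tsd, 0))
            assert dec.lengths() == lengths
            cursor = 0
            for seg in dec.segments:
                assert seg.start == cursor
                cursor = seg.end
            assert cursor == len(seq)


class TestEmptySite:
    def setup_call(self, rng, flank=500):
        bundle = implant_genome(
            [ImplantSpec("Ds1", 4)],
            BackgroundSpec(length=100_000, gene_count=0, repeat_families=0),
            seed=33)
        calls = scan_genome(bundle.genome, EXACT_SCAN)
        return bundle, calls

    def test_length_and_single_tsd_copy(self, rng):
        bundle, calls = self.setup_call(rng)
        for call in calls:
            site = empty_site_sequence(call, bundle.genome, flank=500)
            assert len(site) == 1008
            # exactly one TSD copy at the junction
            assert site[500:508] == call.tsd.left_word

    def test_no_tir_hits_at_junction(self, rng):
        bundle, calls = self.setup_call(rng)
        for call in calls:
            site = empty_site_sequence(call, bundle.genome, flank=500)
            # the excised element's (perfect) TIRs must be gone
            near = [h for h in scan_motif(site, max_mm=0)
                    if 450 <= h.location.start <= 560]
            assert near == []


@pytest.fixture(scope="module")
def pair():
    A, B = make_genome_pair(seed=17, n_shared=6, n_private=6)
    catalog = scan_genome(A.genome, EXACT_SCAN)
    return A, B, catalog


class TestMatchJunction:
    def test_shared_and_polymorphic(self, pair):
        A, B, catalog = pair
        reads = generate_junction_reads(B.truth, B.genome, n=12, seed=17)
        truth = {t.element_id: t.shared for t in B.truth}
        for name, read in reads.items():
            expected = "shared" if truth[name.split("_", 1)[1]] \
                else "polymorphic"
            assert match_junction(read, catalog, A.genome) == expected

    def test_foreign_read_unmapped(self, pair, rng):
        A, _, catalog = pair
        read = random_dna_py(rng, 120) + "TAGGGATGAAA" \
            + random_dna_py(rng, 19)
        assert match_junction(read, catalog, A.genome) == "unmapped"

    def test_short_read_rejected(self, pair):
        A, _, catalog = pair
        with pytest.raises(ValueError):
            match_junction("ACGT" * 5, catalog, A.genome)
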