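"""Local alignment, homology profiling, class assignment, and census tables."""

import numpy as np
import pandas as pd
import pytest

import acds
from acds.classify import (
    ClassifyParams, align_local, assign_class, chi_square_distribution_test,
    compare_to_annotation, count_hexamers, homology_profile, length_bin,
    orient_element, percentage_table, summarize_counts,
)
from acds.core import Interval, reverse_complement
from acds.datasets import (
    catalog_from_counts, load_b73_census, load_b73_insertion_context,
)
from acds.synthetic import build_element

from conftest import random_dna_py


def smith_waterman_affine(a: str, b: str, match=1, mismatch=-1,
                          gap_open=-2, gap_extend=-1) -> float:
    """Quadratic-time affine-gap local alignment score (independent oracle).

    The first base of a gap scores ``gap_open``; each further base
    ``gap_extend``.
    """
    n, m = len(a), len(b)
    neg = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    F = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestAlignLocal:
    def test_identical_sequences(self, rng):
        s = random_dna_py(rng, 100)
        aln = align_local(s, s)
        assert aln.score == 100
        assert aln.identity == 1.0
        assert aln.target_interval == (0, 100)

    def test_disjoint_alphabets(self):
        aln = align_local("A" * 40, "C" * 40)
        assert aln.score == 0 and aln.empty

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "ACGT")

    def test_score_matches_dp_oracle(self):
        rng = np.random.default_rng(2718)
        for _ in range(40):
            n = int(rng.integers(10, 120))
            a = random_dna_py(rng, n)
            # mix of related and unrelated pairs
            if rng.random() < 0.5:
                b = random_dna_py(rng, int(rng.integers(10, 120)))
            else:
                cut = int(rng.integers(0, n))
                b = a[:cut] + random_dna_py(rng, 20) + a[cut:]
            assert align_local(a, b).score == smith_waterman_affine(a, b)


class TestCountHexamers:
    def test_three_copies_in_five_prime_window(self, rng):
        head = ("AAACGG" + "T" * 20) * 3
        seq = head + random_dna_py(rng, 400)
        seq = seq.replace("AAACGG", "AAACGG", 3)
        h5, _ = count_hexamers(head + "T" * 400)
        assert h5 == 3

    def test_zero_hexamers(self):
        assert count_hexamers("T" * 500) == (0, 0)

    def test_three_prime_window_counted_on_reverse_complement(self):
        seq = "T" * 400 + "CCGTTT" + "T" * 20   # rc(AAACGG) near the 3' end
        assert count_hexamers(seq) == (0, 1)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            seq = random_dna_py(rng, int(rng.integers(100, 800)))
            h5, h3 = count_hexamers(seq)
            w = min(200, len(seq) // 2)
            assert h5 == seq[:w].count("AAACGG")
            assert h3 == reverse_complement(seq[-w:]).count("AAACGG")


class TestHomologyProfile:
    def test_exact_reference_copy(self, ac_ref):
        p = homology_profile(ac_ref.residues, ac_ref)
        assert p.full_cov > 0.99 and p.best_identity > 0.99
        assert p.str5_cov > 0.99 and p.str3_cov > 0.99
        assert p.exon23_cov > 0.99

    def test_str_retaining_architecture(self, ac_ref, rng):
        # both 200-bp subterminal regions + unrelated filler
        seq = (ac_ref.residues[:200] + random_dna_py(rng, 1000)
               + ac_ref.residues[-200:])
        p = homology_profile(seq, ac_ref)
        assert p.str5_cov >= 0.9 and p.str3_cov >= 0.9
        assert p.exon23_cov < 0.1

    def test_terminal_only_architecture(self, ac_ref, rng):
        seq = (ac_ref.residues[:30] + random_dna_py(rng, 1000)
               + ac_ref.residues[-30:])
        p = homology_profile(seq, ac_ref)
        assert 11 <= p.term5_len <= 40 and 11 <= p.term3_len <= 40
        assert p.str5_cov < 0.3 and p.full_cov < 0.1

    def test_too_short_rejected(self, ac_ref):
        with pytest.raises(ValueError):
            homology_profile("ACGTACGTACGTACGTACGT", ac_ref)

    def test_orientation_recovery(self, ac_ref, rng):
        seq = (ac_ref.residues[:200] + random_dna_py(rng, 800)
               + ac_ref.residues[-200:])
        assert orient_element(reverse_complement(seq), ac_ref) == seq


class TestAssignClass:
    @pytest.mark.parametrize("label", ["Ds1", "Ds2", "Ds-l3", "Ds-l4", "Ac-like"])
    def test_clean_exemplars_recover_their_label(self, label, ac_ref, pool):
        rng = np.random.default_rng(hash(label) % 2 ** 31)
        for _ in range(8):
            seq = build_element(label, ac_ref, rng, pool)
            profile = homology_profile(seq, ac_ref)
            assert assign_class(seq, profile, ds1_consensus=pool.ds1_filler) \
                == label

    def test_zero_coverage_kilobase_element_is_dsl4(self, ac_ref, rng):
        seq = "TAGGGATGAAA" + random_dna_py(rng, 978) + "TTTCATCCCTA"
        profile = homology_profile(seq, ac_ref)
        assert assign_class(seq, profile) == "Ds-l4"

    def test_full_coverage_is_ac_like(self, ac_ref):
        profile = homology_profile(ac_ref.residues, ac_ref)
        assert assign_class(ac_ref.residues, profile) == "Ac-like"

    def test_str_erosion_moves_ds2_to_dsl4_monotonically(self, ac_ref, rng):
        # progressively randomize the subterminal regions of a Ds2-style
        # element; the label may change Ds2 -> Ds-l4 but never to Ds1
        filler = random_dna_py(rng, 1000)
        seen = []
        for keep in (200, 120, 60, 20):
            seq = (ac_ref.residues[:keep]
                   + random_dna_py(rng, 200 - keep) + filler
                   + random_dna_py(rng, 200 - keep)
                   + ac_ref.residues[-keep:])
            seq = "TAGGGATGAAA" + seq[11:-11] + "TTTCATCCCTA"
            profile = homology_profile(seq, ac_ref)
            seen.append(assign_class(seq, profile))
        assert seen[0] == "Ds2" and seen[-1] == "Ds-l4"
        assert "Ds1" not in seen
        # once left, Ds2 never reappears
        first_non_ds2 = next(i for i, s in enumerate(seen) if s != "Ds2")
        assert all(s != "Ds2" for s in seen[first_non_ds2:])

    def test_length_bins(self):
        assert [length_bin(x) for x in (499, 500, 1000, 1001, 5000, 5001)] == \
            ["<500", "500-1000", "500-1000", "1000-5000", "1000-5000", ">5000"]


class TestSummarizeCounts:
    def test_census_fixture_reproduces_published_totals(self):
        catalog = catalog_from_counts(load_b73_census())
        table = summarize_counts(catalog)
        assert table.loc["Total", "Total"] == 903
        assert list(table.loc["Total", ["Ds1", "Ds2", "Ds-l3", "Ds-l4",
                                        "Ac-like"]]) == [331, 39, 44, 486, 3]
        assert table.loc["1", "Total"] == 144

    def test_empty_catalog(self):
        table = summarize_counts(pd.DataFrame())
        assert table.loc["Total", "Total"] == 0

    def test_margins_equal_cell_sums_on_random_catalogs(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 200))
            df = pd.DataFrame({
                "seq_id": [f"c{i}" for i in rng.integers(1, 5, size=n)],
                "label": [["Ds1", "Ds2", "Ds-l4"][i]
                          for i in rng.integers(0, 3, size=n)],
            })
            table = summarize_counts(df)
            body = table.drop(index="Total").drop(columns="Total")
            assert (body.sum(axis=0) == table.drop(columns="Total")
                    .loc["Total"]).all()
            assert (body.sum(axis=1) == table.drop(index="Total")
                    ["Total"]).all()
            assert table.loc["Total", "Total"] == n

    def test_genic_percentages_match_published_rounding(self):
        catalog = catalog_from_counts(load_b73_insertion_context(),
                                      row_field="label",
                                      col_field="context")
        table = summarize_counts(catalog, rows="class", cols="context")
        pct = percentage_table(table)
        assert pct.loc["Ds1", "genic"] == 11
        assert pct.loc["Ds2", "genic"] == 13
        assert pct.loc["Ds-l3", "genic"] == 5
        assert pct.loc["Ds-l4", "genic"] == 7


class TestChiSquare:
    def test_uniform_is_exactly_zero(self):
        chi2, df = chi_square_distribution_test(
            {"1": 10, "2": 10, "3": 10}, {"1": 1e6, "2": 1e6, "3": 1e6})
        assert chi2 == 0.0 and df == 2

    def test_proportional_counts_are_zero(self):
        chi2, _ = chi_square_distribution_test(
            {"1": 10, "2": 20, "3": 30}, {"1": 1e6, "2": 2e6, "3": 3e6})
        assert chi2 == 0.0

    def test_hand_arithmetic_toy(self):
        # obs 30/20/10 with lengths 1/2/3 Mb: expected 10/20/30,
        # chi2 = 400/10 + 0 + 400/30
        chi2, df = chi_square_distribution_test(
            {"1": 30, "2": 20, "3": 10}, {"1": 1e6, "2": 2e6, "3": 3e6})
        assert chi2 == pytest.approx(400 / 10 + 400 / 30)
        assert df == 2

    def test_unplaced_excluded_and_zero_length_rejected(self):
        chi2, df = chi_square_distribution_test(
            {"1": 5, "Unknown": 99}, {"1": 1e6, "2": 1e6})
        assert df == 0 and chi2 == 0.0
        with pytest.raises(ValueError):
            chi_square_distribution_test({"1": 5}, {"1": 0})


class TestCompareToAnnotation:
    def frame(self, spans):
        return pd.DataFrame([{"seq_id": "c", "start": s, "end": e}
                             for s, e in spans])

    def test_exact_match_is_full(self):
        prior = [Interval("c", 100, 200)]
        assert compare_to_annotation(self.frame([(100, 200)]), prior) == ["full"]

    def test_thirty_percent_overlap_is_partial(self):
        prior = [Interval("c", 0, 100)]
        assert compare_to_annotation(self.frame([(70, 170)]), prior) == ["partial"]

    def test_no_overlap_is_new(self):
        prior = [Interval("c", 0, 50)]
        assert compare_to_annotation(self.frame([(60, 160)]), prior) == ["new"]

    def test_status_counts_sum_to_class_totals(self, rng):
        # a fixture mirroring the published marginal structure: per class,
        # the new/partial/full counts sum to the class census total
        from acds.datasets import load_b73_annotation_status
        status = load_b73_annotation_status()
        census = load_b73_census()
        assert (status.sum(axis=1) == census.sum(axis=0)).all()
        assert status.to_numpy().sum() == 903
        assert list(status.sum(axis=0)) == [580, 137, 186]
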