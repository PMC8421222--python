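"""Adapter trimming, pair merging, primer-region profiling and the
observed/expected and penalty tables."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primedit import (
    AbundanceTable,
    EditingProfile,
    PenaltyProfile,
    SimConfig,
    error_floor,
    expected_edit_proportions,
    merge_pair,
    merge_pairs,
    observed_over_expected,
    penalty_analysis,
    profile_primer_region,
    simulate_standards_run,
    trim_adapters,
    trim_read_3prime,
)
from primedit.profiling import ProfileError
from primedit.schemes import revcomp

ADAPTER = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"  # rev tail read-through
PRIMER = "GTGCCAGCAGCCGCGGTAA"


def _rand_seq(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestTrimAdapters:
    def test_full_read_through_removed(self):
        insert = _rand_seq(60, 1)
        seq = insert + ADAPTER
        out, qual = trim_read_3prime(seq, "I" * len(seq), ADAPTER)
        assert out == insert
        assert len(qual) == len(out)

    def test_read_without_adapter_unchanged(self):
        seq = _rand_seq(80, 2)
        out, _ = trim_read_3prime(seq, "I" * 80, ADAPTER)
        assert out == seq

    def test_partial_overlap_with_one_mismatch_trimmed(self):
        # 10-base adapter prefix at the read end with 1 mismatch: 1/10 <= 0.1
        insert = _rand_seq(50, 3)
        partial = list(ADAPTER[:10])
        partial[4] = "A" if partial[4] != "A" else "C"
        seq = insert + "".join(partial)
        out, _ = trim_read_3prime(seq, "I" * len(seq), ADAPTER)
        assert out == insert

    def test_reads_never_lengthened(self):
        seq = _rand_seq(40, 4)
        out, _ = trim_read_3prime(seq, "I" * 40, ADAPTER)
        assert len(out) <= len(seq)

    def test_paired_wrapper_trims_both_mates(self, scheme):
        insert = _rand_seq(60, 5)
        r1 = [("r", insert + revcomp(scheme.rev_tail), "I" * (60 + 34))]
        r2 = [("r", insert + revcomp(scheme.fwd_tail), "I" * (60 + 33))]
        t1, t2 = trim_adapters(r1, r2, scheme)
        assert t1[0][1] == insert
        assert t2[0][1] == insert


class TestMergePairs:
    def _pair_from_amplicon(self, amplicon, read_len):
        r1 = amplicon[:read_len]
        r2 = revcomp(amplicon)[:read_len]
        return (
            ("m", r1, "I" * len(r1)),
            ("m", r2, "I" * len(r2)),
        )

    def test_fully_overlapping_pair_merges_to_amplicon(self):
        amplicon = _rand_seq(332, 6)
        r1, r2 = self._pair_from_amplicon(amplicon, 332)
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert merged[1] == amplicon
        assert len(merged[1]) == 332

    def test_staggered_overlap_length_arithmetic(self):
        amplicon = _rand_seq(300, 7)
        r1, r2 = self._pair_from_amplicon(amplicon, 200)  # 100-base overlap
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert merged[1] == amplicon  # 200 + 200 - 100

    def test_disjoint_sequences_unmerged(self):
        r1 = ("x", _rand_seq(100, 8), "I" * 100)
        r2 = ("x", _rand_seq(100, 9), "I" * 100)
        assert merge_pair(r1, r2) is None

    def test_conflict_resolved_by_higher_quality(self):
        amplicon = _rand_seq(120, 10)
        r1_seq = amplicon
        # error in R2 at amplicon position 50, with lower quality
        r2_src = list(amplicon)
        r2_src[50] = "A" if r2_src[50] != "A" else "G"
        r2_seq = revcomp("".join(r2_src))
        r1 = ("c", r1_seq, "I" * 120)
        r2 = ("c", r2_seq, "#" * 120)  # low quality
        merged = merge_pair(r1, r2)
        assert merged[1] == amplicon
        # now make R2 the high-quality mate: its base wins
        merged2 = merge_pair(("c", r1_seq, "#" * 120), ("c", r2_seq, "I" * 120))
        assert merged2[1] == "".join(r2_src)

    def test_merge_pairs_tallies_unmerged(self):
        amp = _rand_seq(200, 11)
        good = self._pair_from_amplicon(amp, 150)
        bad = (("b", _rand_seq(80, 12), "I" * 80), ("b", _rand_seq(80, 13), "I" * 80))
        merged, unmerged = merge_pairs([good[0], bad[0]], [good[1], bad[1]])
        assert len(merged) == 1
        assert unmerged == 1


class TestMergeProperties:
    @given(
        seed=st.integers(min_value=0, max_value=10**6),
        amp_len=st.integers(min_value=80, max_value=200),
        read_len=st.integers(min_value=60, max_value=200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_error_free_pair_reconstructs_amplicon(self, seed, amp_len, read_len):
        """Any error-free pair covering a (non-repetitive) amplicon with
        >= min_overlap merges back to exactly the amplicon."""
        amplicon = _rand_seq(amp_len, seed)
        read_len = min(read_len, len(amplicon))
        if 2 * read_len - len(amplicon) < 20:  # below min_overlap
            return
        r1 = ("h", amplicon[:read_len], "I" * read_len)
        r2 = ("h", revcomp(amplicon)[:read_len], "I" * read_len)
        merged = merge_pair(r1, r2)
        assert merged is not None
        assert merged[1] == amplicon


class TestProfilePrimerRegion:
    def test_reference_reads_count_reference_bases(self):
        reads = [PRIMER + _rand_seq(50, 1)] * 10
        m = profile_primer_region(reads, PRIMER)
        assert m.reads_pass_filter == 10
        assert m.reads_failed_filter == 0
        assert np.all(m.nonref_proportions() == 0.0)
        assert np.all(m.counts.sum(axis=1) == 10)

    def test_single_terminal_variant_counted(self):
        edited = PRIMER[:-1] + "C"
        m = profile_primer_region([PRIMER, edited], PRIMER)
        assert m.reads_pass_filter == 2
        df = m.to_frame()
        terminal = df[df.distance_from_3prime == 1].iloc[0]
        assert terminal["C"] == 1 and terminal["A"] == 1
        assert m.nonref_at_3prime_distance(1) == 0.5

    def test_read_with_four_mismatches_excluded(self):
        bad = list(PRIMER)
        for i in (0, 5, 10, 15):
            bad[i] = "A" if bad[i] != "A" else "C"
        m = profile_primer_region([PRIMER, "".join(bad)], PRIMER, max_mm=3)
        assert m.reads_pass_filter == 1
        assert m.reads_failed_filter == 1
        assert m.reads_evaluated == 2

    def test_three_mismatches_still_pass(self):
        ok = list(PRIMER)
        for i in (0, 5, 10):
            ok[i] = "A" if ok[i] != "A" else "C"
        m = profile_primer_region(["".join(ok)], PRIMER, max_mm=3)
        assert m.reads_pass_filter == 1

    def test_short_read_skipped_with_tally(self):
        m = profile_primer_region([PRIMER[:10]], PRIMER)
        assert m.reads_short == 1
        assert m.reads_pass_filter == 0

    def test_degenerate_reference_matches_compatible_bases(self):
        # the degenerate 515F primer carries M (A or C) at position 9
        ref = "GTGCCAGCMGCCGCGGTAA"
        read_a = "GTGCCAGCAGCCGCGGTAA"
        read_c = "GTGCCAGCCGCCGCGGTAA"
        read_t = "GTGCCAGCTGCCGCGGTAA"
        m = profile_primer_region([read_a, read_c, read_t], ref, max_mm=0)
        # T is incompatible with M -> that read fails the 0-mismatch filter
        assert m.reads_pass_filter == 2
        nonref = m.nonref_proportions()
        assert np.isnan(nonref[8])  # no single reference base at M
        assert np.nansum(nonref) == 0.0

    def test_n_bases_count_as_mismatch_and_tallied(self):
        read = "N" * 4 + PRIMER[4:]
        m = profile_primer_region([read], PRIMER, max_mm=3)
        assert m.reads_failed_filter == 1


class TestObservedOverExpected:
    def test_ratio_identity(self):
        reads = [PRIMER] * 28 + [PRIMER[:-1] + "C"] * 3
        m = profile_primer_region(reads, PRIMER)
        table = observed_over_expected(m, {1: 3 / 31})
        row = table[table.distance_from_3prime == 1].iloc[0]
        assert row["observed"] == pytest.approx(3 / 31)
        assert row["ratio"] == pytest.approx(1.0)

    def test_expected_zero_is_undefined_not_zero(self):
        m = profile_primer_region([PRIMER] * 5, PRIMER)
        table = observed_over_expected(m, {1: 0.1})
        assert np.isnan(table[table.distance_from_3prime == 2]["ratio"]).all()

    def test_position_coverage_mismatch_raises(self):
        m = profile_primer_region([PRIMER] * 5, PRIMER)
        with pytest.raises(ProfileError):
            observed_over_expected(m, {25: 0.1})

    def test_expected_proportions_from_construct_metadata(
        self, constructs, even_abundance
    ):
        expected = expected_edit_proportions(even_abundance, constructs)
        assert set(expected) == set(range(1, 11))
        for v in expected.values():
            assert v == pytest.approx(3 / 31)

    def test_error_floor_from_positions_outside_window(self):
        reads = [PRIMER] * 99 + ["A" + PRIMER[1:]]  # one 5'-end mismatch
        m = profile_primer_region(reads, PRIMER)
        floor = error_floor(m, window=10)
        assert floor == pytest.approx(0.01 / 9)
        assert error_floor(m, window=19) != floor or math.isnan(
            error_floor(m, window=19)
        )


class TestPenaltyAnalysis:
    def _reads(self, scheme, spec):
        """spec: mapping primer-region sequence -> count."""
        tail = _rand_seq(40, 14)
        reads = []
        for region, n in spec.items():
            reads.extend([region + tail] * n)
        return reads

    def test_counts_proportional_to_expected_give_unit_folds(self, scheme):
        from primedit import enumerate_variants

        spec = {site: 10 for _, _, site in enumerate_variants(scheme.fwd_locus, 10)}
        reads = self._reads(scheme, spec)
        for anchor in ("wild_type", "whole_pool"):
            res = penalty_analysis(reads, scheme, 10, anchor=anchor)
            assert np.allclose(res.per_variant["fold"], 1.0)
            assert np.allclose(res.per_position["fold"], 1.0)

    def test_absent_variant_has_zero_fold(self, scheme):
        from primedit import enumerate_variants

        spec = {
            site: 10
            for pos, _, site in enumerate_variants(scheme.fwd_locus, 10)
            if pos != 1
        }
        res = penalty_analysis(self._reads(scheme, spec), scheme, 10)
        assert res.fold_at(1) == 0.0
        assert res.fold_at(2) == pytest.approx(1.0)

    def test_multi_mismatch_reads_are_other(self, scheme):
        two_mm = list(scheme.fwd_locus)
        two_mm[0] = "A" if two_mm[0] != "A" else "C"
        two_mm[-1] = "C"
        reads = self._reads(scheme, {scheme.fwd_locus: 5, "".join(two_mm): 2})
        res = penalty_analysis(reads, scheme, 10)
        assert res.n_wild_type == 5
        assert res.n_other == 2

    def test_zero_wild_type_warns_and_undefines_folds(self, scheme):
        region = scheme.fwd_locus[:-1] + "C"
        with pytest.warns(UserWarning, match="wild-type"):
            res = penalty_analysis(self._reads(scheme, {region: 4}), scheme, 10)
        assert np.isnan(res.fold_at(2))

    def test_write_round_trip(self, scheme, tmp_path):
        from primedit import enumerate_variants

        spec = {site: 4 for _, _, site in enumerate_variants(scheme.fwd_locus, 3)}
        res = penalty_analysis(self._reads(scheme, spec), scheme, 3)
        path = tmp_path / "penalty.tsv"
        res.write(path)
        df = pd.read_csv(path, sep="\t")
        assert set(df.columns) == {"position", "base", "count", "expected", "fold"}
        assert (df["base"] == "all").sum() == 3


class TestEndToEndProfiles:
    def test_reverse_primer_region_clean_in_standards_run(
        self, constructs, even_abundance, scheme
    ):
        """The standards all match the reverse primer, so profiling the
        reverse region shows nothing above the sequencing-error floor."""
        cfg = SimConfig(n_reads=5_000, error_rate=0.002, seed=21)
        sim = simulate_standards_run(
            constructs, even_abundance, EditingProfile.complete(6),
            PenaltyProfile.none(), cfg,
        )
        # reverse-region profile: orient merged reads from the reverse primer
        rev_views = [revcomp(seq)[: scheme.rev_len] for _, seq, _ in sim.r1]
        m = profile_primer_region(rev_views, scheme.rev_locus)
        nonref = m.nonref_proportions()
        se = math.sqrt(0.002 * 0.998 / cfg.n_reads)
        assert np.nanmax(nonref) <= 0.002 + 3 * se
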