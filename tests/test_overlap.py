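"""Overlap engine: offset search, adapter cutting, correction, error stats."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairqc.fastq_io import PHRED_OFFSET, ReadPair, SequenceRead
from pairqc.overlap import (TRANSFORMS, ErrorStats, accumulate_error_stats,
                            correct_pair, cut_adapters, edit_distance,
                            find_overlap, merge_overlap)
from pairqc.qc_profiler import reverse_complement
from pairqc.simulate import SimulationConfig, simulate_pairs

from conftest import make_read
from helpers import dp_edit_distance, exhaustive_overlap, revcomp


def make_pair(r1_bases, r2_bases, q1=36, q2=36):
    return ReadPair(r1=make_read(r1_bases, qual=q1, name="p/1"),
                    r2=make_read(r2_bases, qual=q2, name="p/2"))


def pair_from_template(template, S, rng=None):
    """Error-free pair from a template (template must be >= S long)."""
    r1 = template[:S]
    r2 = revcomp(template)[:S]
    return make_pair(r1, r2)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("", "ACGT", 4),
        ("ACGT", "", 4),
        ("ACGT", "ACGT", 0),
        ("ACGT", "AGGT", 1),
        ("ACGT", "CGT", 1),
    ])
    def test_known_values(self, a, b, expected):
        assert edit_distance(a, b) == expected

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="ACGT", max_size=25),
           st.text(alphabet="ACGT", max_size=25))
    def test_agrees_with_dp_oracle(self, a, b):
        assert edit_distance(a, b) == dp_edit_distance(a, b)


class TestFindOverlap:
    def test_partial_overlap_geometry(self, rng):
        # 60 bp template sequenced 2x50: 40 bp overlap at offset 10
        template = "".join(rng.choice("ACGT") for _ in range(60))
        result = find_overlap(pair_from_template(template, 50))
        assert (result.offset, result.overlap_len, result.edit_dist) == (10, 40, 0)
        assert result.overlapped and result.hamming_dist == 0

    def test_one_substitution_in_overlap(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        pair = pair_from_template(template, 50)
        # flip one r2 base inside the overlap (r2 positions 10..49 cover it)
        b = list(pair.r2.bases)
        b[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[20]]
        pair = ReadPair(r1=pair.r1, r2=SequenceRead("p/2", "".join(b),
                                                    pair.r2.quals))
        result = find_overlap(pair)
        assert (result.offset, result.overlap_len, result.edit_dist) == (10, 40, 1)
        assert len(result.mismatch_positions) == 1

    def test_long_template_does_not_overlap(self, rng):
        for _ in range(5):
            template = "".join(rng.choice("ACGT") for _ in range(120))
            assert not find_overlap(pair_from_template(template, 50)).overlapped

    def test_short_template_negative_offset(self, rng):
        r1, r2, truth = simulate_pairs(SimulationConfig(
            seed=11, n_pairs=5, read_len=50, template_len=30, error_rate=0.0))
        for a, b in zip(r1, r2):
            result = find_overlap(ReadPair(r1=a, r2=b))
            assert result.overlapped
            assert result.offset == -20 and result.overlap_len == 30

    def test_full_overlap_at_t_equals_s(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(50))
        result = find_overlap(pair_from_template(template, 50))
        assert result.offset == 0 and result.overlap_len == 50

    @settings(deadline=None, max_examples=60)
    @given(st.integers(30, 90), st.data())
    def test_matches_exhaustive_scan_on_random_templates(self, T, data):
        template = data.draw(st.text(alphabet="ACGT", min_size=T, max_size=T))
        S = 50
        pair = pair_from_template(template + "A" * max(0, S - T), max(S, 1))
        result = find_overlap(pair, min_overlap=20, max_ed_fraction=0.1)
        off, length, ed, overlapped = exhaustive_overlap(
            pair.r1.bases, pair.r2.bases, 20, 0.1)
        assert (result.offset, result.overlap_len, result.edit_dist) == (
            off, length, ed)
        assert result.overlapped == overlapped

    @settings(deadline=None, max_examples=40)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=60),
           st.text(alphabet="ACGT", min_size=30, max_size=60))
    def test_matches_exhaustive_scan_on_unrelated_reads(self, a, b):
        result = find_overlap(make_pair(a, b), min_overlap=15,
                              max_ed_fraction=0.05)
        off, length, ed, overlapped = exhaustive_overlap(a, b, 15, 0.05)
        assert (result.offset, result.overlap_len, result.edit_dist,
                result.overlapped) == (off, length, ed, overlapped)


class TestCutAdapters:
    ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

    def test_planted_adapter_removed_for_every_short_template(self):
        for T in range(20, 50):
            r1s, r2s, truth = simulate_pairs(SimulationConfig(
                seed=100 + T, n_pairs=3, read_len=50, template_len=T,
                error_rate=0.0))
            for a, b, info in zip(r1s, r2s, truth["pairs"]):
                pair = ReadPair(r1=a, r2=b)
                result = find_overlap(pair, min_overlap=min(30, T))
                assert result.offset == T - 50
                removed = a.bases[T:]
                cut = cut_adapters(pair, result)
                assert len(cut.r1.bases) == T and len(cut.r2.bases) == T
                assert cut.r1.bases == info["template"]
                assert removed[: min(50 - T, len(self.ADAPTER))] == \
                    self.ADAPTER[: min(50 - T, len(self.ADAPTER))]

    def test_one_base_adapter(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(49))
        pair = make_pair(template + "A", revcomp(template) + "A")
        result = find_overlap(pair)
        assert result.offset == -1
        cut = cut_adapters(pair, result)
        assert len(cut.r1.bases) == 49 and len(cut.r2.bases) == 49

    def test_recut_pair_overlaps_fully(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(30))
        pair = make_pair(template + "AGATCGGAAGAGCACACGTC",
                         revcomp(template) + "AGATCGGAAGAGCGTCGTGT")
        result = find_overlap(pair)
        cut = cut_adapters(pair, result)
        again = find_overlap(cut, min_overlap=30)
        assert again.offset == 0 and again.overlap_len == 30
        assert again.edit_dist == 0

    def test_non_negative_offset_rejected(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        pair = pair_from_template(template, 50)
        result = find_overlap(pair)
        with pytest.raises(ValueError):
            cut_adapters(pair, result)


class TestCorrectPair:
    def _mismatch_pair(self, rng, q_r1=38, q_r2=8):
        """60 bp template, 2x50; one planted mismatch in r2's overlap."""
        template = "".join(rng.choice("ACGT") for _ in range(60))
        r1 = template[:50]
        r2 = list(revcomp(template)[:50])
        r2[20] = {"A": "T", "T": "A", "C": "G", "G": "C"}[r2[20]]  # substitution
        pair = ReadPair(
            r1=make_read(r1, qual=q_r1, name="p/1"),
            r2=SequenceRead("p/2", "".join(r2),
                            chr(q_r2 + PHRED_OFFSET) * 50))
        return template, pair

    def test_high_low_asymmetry_corrected(self, rng):
        template, pair = self._mismatch_pair(rng)
        result = find_overlap(pair)
        assert result.edit_dist == 1
        fixed, corrected, uncorrectable = correct_pair(pair, result)
        assert corrected == 1 and not uncorrectable
        assert fixed.r2.bases == revcomp(template)[:50]
        # the fixed base inherits the high-quality mate's quality
        assert fixed.r2.quals[20] == chr(38 + PHRED_OFFSET)
        assert find_overlap(fixed).edit_dist == 0

    def test_balanced_quality_uncorrectable(self, rng):
        _, pair = self._mismatch_pair(rng, q_r1=30, q_r2=29)
        result = find_overlap(pair)
        fixed, corrected, uncorrectable = correct_pair(pair, result)
        assert corrected == 0 and uncorrectable
        assert fixed == pair

    def test_low_quality_r1_corrected_from_r2(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        r1 = list(template[:50])
        r1[30] = {"A": "T", "T": "A", "C": "G", "G": "C"}[r1[30]]
        quals1 = [chr(38 + PHRED_OFFSET)] * 50
        quals1[30] = chr(5 + PHRED_OFFSET)
        pair = ReadPair(
            r1=SequenceRead("p/1", "".join(r1), "".join(quals1)),
            r2=make_read(revcomp(template)[:50], qual=38, name="p/2"))
        result = find_overlap(pair)
        fixed, corrected, uncorrectable = correct_pair(pair, result)
        assert corrected == 1 and not uncorrectable
        assert fixed.r1.bases == template[:50]

    def test_simulated_errors_all_removed(self):
        r1s, r2s, _ = simulate_pairs(SimulationConfig(
            seed=21, n_pairs=1000, read_len=50, template_len=60,
            error_rate=0.005, error_qual=8, base_qual=36))
        residual = 0
        for a, b in zip(r1s, r2s):
            pair = ReadPair(r1=a, r2=b)
            # lax mismatch budget so even many-error pairs are admitted
            result = find_overlap(pair, max_ed_fraction=0.2)
            assert result.overlapped
            if result.edit_dist == 0:
                continue
            fixed, _, _ = correct_pair(pair, result)
            residual += find_overlap(fixed).edit_dist
        assert residual == 0

    def test_zero_edit_distance_rejected(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        pair = pair_from_template(template, 50)
        with pytest.raises(ValueError):
            correct_pair(pair, find_overlap(pair))


class TestErrorStats:
    def test_clean_overlap_counts_total_only(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(140))
        pair = pair_from_template(template, 100)
        result = find_overlap(pair)
        stats = accumulate_error_stats(result, ErrorStats())
        assert stats.total_overlapped_bases == 60
        assert stats.mismatched_bases == 0

    def test_transform_orientation(self, rng):
        # T=140, 2x100: overlap covers template[40:100]. Plant a low-quality
        # error in r2 at the position pairing with r1 position 50, forcing a
        # C there so the transform reads (r1 base) -> comp(r2 base).
        template = "".join(rng.choice("ACGT") for _ in range(140))
        template = template[:50] + "C" + template[51:]
        r2 = list(revcomp(template)[:100])
        # r2[i] reads comp(template[139 - i]); r1 pos 50 pairs with r2 pos 89
        r2[89] = "C"  # observed base in r1 orientation: G
        pair = ReadPair(r1=make_read(template[:100], qual=40, name="p/1"),
                        r2=SequenceRead("p/2", "".join(r2),
                                        chr(5 + PHRED_OFFSET) * 100))
        result = find_overlap(pair)
        assert result.edit_dist == 1
        stats = accumulate_error_stats(result, ErrorStats())
        assert stats.transform_counts["C->G"] == 1
        assert stats.mismatched_bases == 1

    def test_balanced_mismatch_is_unprofiled(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(140))
        r2 = list(revcomp(template)[:100])
        r2[50] = {"A": "T", "T": "A", "C": "G", "G": "C"}[r2[50]]
        pair = make_pair(template[:100], "".join(r2), q1=25, q2=25)
        result = find_overlap(pair)
        stats = accumulate_error_stats(result, ErrorStats())
        assert stats.unprofiled_mismatches == 1
        assert sum(stats.transform_counts.values()) == 0

    def test_short_overlap_rejected(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(160))
        pair = pair_from_template(template, 100)
        result = find_overlap(pair)
        assert result.overlap_len == 40
        with pytest.raises(ValueError):
            accumulate_error_stats(result, ErrorStats(), min_profile_overlap=50)

    def test_conservation_over_simulation(self):
        r1s, r2s, _ = simulate_pairs(SimulationConfig(
            seed=31, n_pairs=300, read_len=100, template_len=130,
            error_rate=0.01, error_qual=8, base_qual=36))
        stats = ErrorStats()
        for a, b in zip(r1s, r2s):
            result = find_overlap(ReadPair(r1=a, r2=b))
            if result.overlapped and result.overlap_len > 50 \
                    and result.hamming_dist == result.edit_dist:
                accumulate_error_stats(result, stats)
        assert (sum(stats.transform_counts.values())
                + stats.unprofiled_mismatches == stats.mismatched_bases)
        assert stats.mismatched_bases > 0

    def test_error_rate_recovery_three_sigma(self):
        from pairqc.simulate import expected_mismatch_fraction

        for e in (0.002, 0.005, 0.01):
            r1s, r2s, _ = simulate_pairs(SimulationConfig(
                seed=41, n_pairs=2000, read_len=100, template_len=130,
                error_rate=e, error_on="r2", error_qual=8, base_qual=36))
            stats = ErrorStats()
            for a, b in zip(r1s, r2s):
                result = find_overlap(ReadPair(r1=a, r2=b))
                if result.overlapped and result.overlap_len > 50 \
                        and result.hamming_dist == result.edit_dist:
                    accumulate_error_stats(result, stats)
            p = expected_mismatch_fraction(e, "r2")
            n = stats.total_overlapped_bases
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(stats.error_rate - p) < 3 * sd + 1e-12


class TestMergeOverlap:
    def test_merged_equals_template_slice(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        pair = pair_from_template(template, 50)
        merged = merge_overlap(pair, find_overlap(pair))
        assert merged.bases == template[10:50]
        assert merged.name.endswith(" merged")

    def test_full_overlap_length(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(50))
        pair = pair_from_template(template, 50)
        merged = merge_overlap(pair, find_overlap(pair))
        assert len(merged.bases) == 50

    def test_quality_is_positionwise_max(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        pair = ReadPair(r1=make_read(template[:50], qual=20, name="p/1"),
                        r2=make_read(revcomp(template)[:50], qual=35, name="p/2"))
        merged = merge_overlap(pair, find_overlap(pair))
        assert set(merged.quals) == {chr(35 + PHRED_OFFSET)}

    def test_uncorrectable_position_keeps_r1_base(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(60))
        r2 = list(revcomp(template)[:50])
        r2[20] = {"A": "T", "T": "A", "C": "G", "G": "C"}[r2[20]]
        pair = make_pair(template[:50], "".join(r2), q1=25, q2=25)
        result = find_overlap(pair)
        merged = merge_overlap(pair, result)
        assert merged.bases == template[10:50]  # r1's call everywhere

    def test_non_overlapped_rejected(self, rng):
        template = "".join(rng.choice("ACGT") for _ in range(120))
        pair = pair_from_template(template, 50)
        result = find_overlap(pair)
        with pytest.raises(ValueError):
            merge_overlap(pair, result)
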