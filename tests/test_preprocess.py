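"""Tests for trimming, merging, filtering and UMI deduplication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhdamp import (
    FilterParams,
    MergedRead,
    ReadPair,
    Rejection,
    SimConfig,
    dedup_umi,
    extract_umi,
    merge_pair,
    quality_filter,
    reverse_complement,
    simulate_reads,
    size_filter,
    trim_adaptors,
)
from rhdamp.pipeline import preprocess_pairs
from rhdamp.preprocess import DEFAULT_ADAPTOR_R1, DEFAULT_ADAPTOR_R2

DNA = st.text(alphabet="ACGT", min_size=1)


def _pair(r1, r2, q1=None, q2=None, id="p"):
    return ReadPair(id, r1, q1 or "I" * len(r1), r2, q2 or "I" * len(r2))


def _read(seq, quals=None, **kw):
    return MergedRead("r", seq, quals or "I" * len(seq), **kw)


class TestTrimAdaptors:
    def test_no_adaptor_unchanged(self):
        pair = _pair("ACGT" * 20, "TGCA" * 20)
        assert trim_adaptors(pair) is pair

    @settings(max_examples=25, derandomize=True)
    @given(insert=st.text(alphabet="ACGT", min_size=50, max_size=110))
    def test_read_through_trimmed_at_string_search_oracle(self, insert):
        read1 = (insert + DEFAULT_ADAPTOR_R1 + "G" * 151)[:151]
        pair = _pair(read1, reverse_complement(insert))
        trimmed = trim_adaptors(pair)
        # oracle: plain substring search for the adaptor
        cut = read1.find(DEFAULT_ADAPTOR_R1[: min(len(DEFAULT_ADAPTOR_R1), 151 - len(insert))])
        assert trimmed.read1_seq == read1[:cut] == insert[:cut]
        assert len(trimmed.read1_quals) == len(trimmed.read1_seq)

    def test_single_mismatch_in_adaptor_still_trimmed(self):
        insert = "ACGTACGTAC" * 10  # 100 bases
        adaptor = DEFAULT_ADAPTOR_R1
        corrupted = adaptor[:5] + ("A" if adaptor[5] != "A" else "C") + adaptor[6:]
        read1 = (insert + corrupted + "G" * 151)[:151]
        trimmed = trim_adaptors(_pair(read1, "ACGT" * 10))
        assert trimmed.read1_seq == insert

    def test_all_adaptor_read_becomes_empty(self):
        read1 = (DEFAULT_ADAPTOR_R1 + "G" * 151)[:151]
        trimmed = trim_adaptors(_pair(read1, "ACGT"))
        assert trimmed.read1_seq == ""
        # and the empty read is rejected downstream, not an exception
        assert isinstance(
            merge_pair(trimmed, FilterParams()), Rejection
        )

    def test_three_base_remnant_trimmed(self):
        # a 148-base insert in a 151-base read leaves a 3-base remnant
        insert = "ACGT" * 37  # 148
        read1 = insert + DEFAULT_ADAPTOR_R1[:3]
        trimmed = trim_adaptors(_pair(read1, "ACGT"))
        assert trimmed.read1_seq == insert


class TestMergePair:
    def test_identity_overlap(self):
        seq = "ACGTTGCAACGTTGCAACGT"
        merged = merge_pair(_pair(seq, reverse_complement(seq)), FilterParams())
        assert isinstance(merged, MergedRead)
        assert merged.sequence == seq

    @pytest.mark.parametrize("pos", [0, 7, 19])
    def test_single_mismatch_rejected_at_zero_density(self, pos):
        # aperiodic sequence: no shorter shifted overlap can rescue the pair
        seq = "ACGTTGCAAGCTTACGGATC"
        other = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        merged = merge_pair(_pair(seq, reverse_complement(other)), FilterParams())
        assert isinstance(merged, Rejection)
        assert merged.stage == "merge"

    def test_overlap_below_min_overlap_rejected(self):
        left = "ACGTACGTAAATTTCCCGG"[:15]
        overlap = "GATTACAGA"  # 9 bases
        r1 = left + overlap
        rc2 = overlap + "TTTTTT"
        merged = merge_pair(
            _pair(r1, reverse_complement(rc2)), FilterParams(min_overlap=10)
        )
        assert isinstance(merged, Rejection)

    def test_staggered_overlap_extends_read(self):
        # molecule longer than the read: each mate covers one end
        molecule = "ACGATCGATTACAGGGCCCTTTAAACGTACGTAGCT"  # 36 bases
        r1 = molecule[:30]
        r2 = reverse_complement(molecule[6:])
        merged = merge_pair(_pair(r1, r2), FilterParams())
        assert isinstance(merged, MergedRead)
        assert merged.sequence == molecule

    def test_overlap_quality_is_positionwise_max(self):
        seq = "ACGTACGTACGTACGT"
        q1 = "5" * len(seq)  # Q20
        q2 = "I" * len(seq)  # Q40
        merged = merge_pair(
            _pair(seq, reverse_complement(seq), q1=q1, q2=q2), FilterParams()
        )
        assert merged.quals == "I" * len(seq)

    @settings(max_examples=30, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=12, max_size=60))
    def test_idempotent_on_own_output(self, seq):
        params = FilterParams()
        merged = merge_pair(_pair(seq, reverse_complement(seq)), params)
        assert isinstance(merged, MergedRead)
        again = merge_pair(
            _pair(merged.sequence, reverse_complement(merged.sequence)), params
        )
        assert again.sequence == merged.sequence


class TestSizeAndQualityFilters:
    @pytest.mark.parametrize(
        "length, passes", [(105, True), (104, False), (148, True), (149, False)]
    )
    def test_size_boundaries(self, length, passes):
        result = size_filter(_read("A" * length))
        assert isinstance(result, MergedRead) is passes

    def test_quality_boundaries(self):
        params = FilterParams()
        q30 = chr(30 + 33) * 100
        q20 = chr(20 + 33) * 100
        assert isinstance(quality_filter(_read("A" * 100, q30), params), MergedRead)
        assert isinstance(quality_filter(_read("A" * 100, q20), params), Rejection)
        # mean exactly 25 passes (boundary inclusive)
        half = chr(20 + 33) * 50 + chr(30 + 33) * 50
        assert isinstance(quality_filter(_read("A" * 100, half), params), MergedRead)


class TestExtractUmi:
    def test_umi_split(self):
        params = FilterParams(umi_mode=True)
        read = _read("ACGTACGTACGT" + "T" * 105)
        out = extract_umi(read, params)
        assert out.umi == "ACGTACGTACGT"
        assert len(out.sequence) == 105
        assert len(out.quals) == 105

    def test_umi_only_read_leaves_empty_amplicon(self):
        out = extract_umi(_read("ACGTACGTACGT"), FilterParams(umi_mode=True))
        assert out.umi is not None and out.sequence == ""
        assert isinstance(size_filter(out), Rejection)

    def test_umi_mode_off_is_identity(self):
        read = _read("ACGT" * 30)
        assert extract_umi(read, FilterParams(umi_mode=False)) is read

    def test_too_short_read_rejected(self):
        out = extract_umi(_read("ACGT"), FilterParams(umi_mode=True))
        assert isinstance(out, Rejection)


class TestDedupUmi:
    U1 = "A" * 12
    U2 = "C" * 12

    def _mr(self, seq, umi, id="r"):
        return MergedRead(id, seq, "I" * len(seq), umi=umi)

    def test_triplicate_collapses_to_one(self):
        reads = [self._mr("ACGT", self.U1, f"r{i}") for i in range(3)]
        out, stats = dedup_umi(reads)
        assert len(out) == 1
        assert stats.duplicates_removed == 2
        assert stats.reads_per_molecule == {3: 1}

    def test_plurality_sequence_wins(self):
        reads = [
            self._mr("AAAA", self.U1, "x1"),
            self._mr("CCCC", self.U1, "y"),
            self._mr("AAAA", self.U1, "x2"),
        ]
        out, _ = dedup_umi(reads)
        assert [r.sequence for r in out] == ["AAAA"]

    def test_tie_broken_by_lexicographic_order(self):
        reads = [self._mr("TTTT", self.U1), self._mr("AAAA", self.U1)]
        out, _ = dedup_umi(reads)
        assert out[0].sequence == "AAAA"

    def test_distinct_umis_are_distinct_molecules(self):
        reads = [self._mr("ACGT", self.U1), self._mr("ACGT", self.U2)]
        out, stats = dedup_umi(reads)
        assert len(out) == 2 and stats.duplicates_removed == 0

    def test_same_umi_different_length_class_kept_separate(self):
        reads = [self._mr("A" * 105, self.U1), self._mr("A" * 148, self.U1)]
        out, stats = dedup_umi(reads)
        assert len(out) == 2
        assert stats.unique_umis == 1

    def test_missing_umi_is_contract_violation(self):
        with pytest.raises(ValueError):
            dedup_umi([MergedRead("r", "ACGT", "IIII")])

    @settings(max_examples=30, derandomize=True)
    @given(
        umis=st.lists(
            st.text(alphabet="AC", min_size=12, max_size=12), min_size=1, max_size=20
        )
    )
    def test_output_count_bounds(self, umis):
        reads = [self._mr("ACGT", u, f"r{i}") for i, u in enumerate(umis)]
        out, stats = dedup_umi(reads)
        assert len(out) <= len(reads)
        assert (len(out) == len(reads)) == (len(set(umis)) == len(umis))
        assert stats.input_reads == len(reads)
        assert stats.unique_molecules + stats.duplicates_removed == len(reads)


def test_preprocess_ledger_conservation(refs, model):
    config = SimConfig(
        seed=5, molecules_per_group=300, duplication_mean=2.0, umi_mode=True
    )
    pairs, _ = simulate_reads(config, refs, model)
    reads, ledger, rejections = preprocess_pairs(pairs, FilterParams(umi_mode=True))
    assert ledger["input_pairs"] == len(pairs)
    assert ledger["merged"] + ledger["merge_rejected"] == ledger["input_pairs"]
    assert (
        ledger["size_passed"] + ledger["size_rejected"] + ledger["umi_rejected"]
        == ledger["merged"]
    )
    assert ledger["quality_passed"] + ledger["quality_rejected"] == ledger["size_passed"]
    assert len(reads) == ledger["quality_passed"]
    assert len(rejections) == ledger["input_pairs"] - len(reads)
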