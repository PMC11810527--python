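"""Adapter trimming, quality filtering, and pair merging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heaa.amplicons import reverse_complement
from heaa.reads import ReadRecord, merge_pair, quality_filter, trim_adapter

ADAPTER = "AGATCGGAAGAGC"


def make_read(bases, qual=35, read_id="r"):
    return ReadRecord(read_id, bases, tuple([qual] * len(bases)))


def brute_force_suffix_trim(bases, adapter, min_match):
    """Oracle: longest k with read suffix == adapter prefix, else len(read)."""
    best = len(bases)
    for k in range(min_match, min(len(bases), len(adapter) - 1) + 1):
        if bases.endswith(adapter[:k]):
            best = len(bases) - k  # k ascending: last hit is the longest
    return best


class TestTrimAdapter:
    def test_full_internal_adapter_truncates_at_its_start(self):
        read = make_read("ACGTACGT" + ADAPTER + "TTTT")
        out = trim_adapter(read, ADAPTER)
        assert out.bases == "ACGTACGT"
        assert len(out.quals) == len(out.bases)

    def test_read_without_adapter_is_unchanged(self):
        read = make_read("ACGTACGTACGT")
        assert trim_adapter(read, ADAPTER) == read

    def test_partial_suffix_overlap_removes_longest_match(self):
        read = make_read("GGGCCATGG" + ADAPTER[:5])
        out = trim_adapter(read, ADAPTER, min_match=3)
        assert out.bases == "GGGCCATGG"

    @given(
        st.text(alphabet="ACGT", min_size=5, max_size=40),
        st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_suffix_oracle(self, core, k):
        bases = core + ADAPTER[:k]
        if ADAPTER in bases:
            return  # internal-occurrence rule takes precedence
        read = make_read(bases)
        out = trim_adapter(read, ADAPTER, min_match=3)
        assert len(out) == brute_force_suffix_trim(bases, ADAPTER, 3)

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(make_read("ACGT"), "")


class TestQualityFilter:
    def test_clean_read_is_unchanged(self):
        read = make_read("A" * 50, qual=30)
        assert quality_filter(read) == read

    def test_tail_trim_below_length_floor_discards(self):
        # 50 bp with the last 15 at Q10 -> 35 bp survivor -> discarded
        quals = tuple([30] * 35 + [10] * 15)
        read = ReadRecord("r", "A" * 50, quals)
        assert quality_filter(read) is None

    def test_tail_trim_just_above_floor_is_kept(self):
        # 50 bp with the last 9 at Q10 -> 41 bp survivor -> kept (41 > 40)
        quals = tuple([30] * 41 + [10] * 9)
        out = quality_filter(ReadRecord("r", "A" * 50, quals))
        assert out is not None and len(out) == 41

    def test_length_boundary_is_inclusive(self):
        assert quality_filter(make_read("A" * 40, qual=30)) is None
        assert quality_filter(make_read("A" * 41, qual=30)) is not None

    def test_five_prime_end_also_trimmed(self):
        quals = tuple([10] * 5 + [30] * 45)
        out = quality_filter(ReadRecord("r", "C" * 50, quals))
        assert len(out) == 45

    def test_all_low_quality_discards(self):
        assert quality_filter(make_read("A" * 50, qual=10)) is None

    @given(st.lists(st.integers(2, 40), min_size=1, max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_never_lengthens_and_keeps_quals_aligned(self, quals):
        read = ReadRecord("r", "A" * len(quals), tuple(quals))
        out = quality_filter(read, min_q=20, min_len=0)
        if out is not None:
            assert len(out) <= len(read)
            assert len(out.bases) == len(out.quals)
            assert all(q > 20 for q in (out.quals[0], out.quals[-1]))


def pair_from_fragment(frag, len1, len2, q1=35, q2=35):
    """Build (r1, r2) reading a fragment from both ends."""
    r1 = ReadRecord("p", frag[:len1], tuple([q1] * len1))
    r2_bases = reverse_complement(frag)[:len2]
    r2 = ReadRecord("p", r2_bases, tuple([q2] * len2))
    return r1, r2


class TestMergePair:
    def test_exact_reverse_complement_merges_full_length(self):
        frag = "ACGTACGTGGCCATATCGCGTTAA" * 4
        r1, r2 = pair_from_fragment(frag, len(frag), len(frag))
        m = merge_pair(r1, r2)
        assert m is not None
        assert m.bases == frag
        assert m.overlap_len == len(frag)
        assert m.mismatches_in_overlap == 0

    def test_partial_overlap_reconstructs_fragment(self):
        frag = (
            "TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAG"
            "TCTTTGCGCCCATAAATGTAGCCAGTGAGCTTAGTTGGAGCAAG"
        )
        r1, r2 = pair_from_fragment(frag, 60, 60)
        m = merge_pair(r1, r2)
        assert m is not None
        assert m.bases == frag
        assert m.overlap_len == 60 + 60 - len(frag)

    def test_higher_quality_base_wins_disagreements(self):
        frag = "ACGTACGTGGCCATATCGCGTTAA"
        r1, r2 = pair_from_fragment(frag, len(frag), len(frag), q1=40, q2=10)
        # plant a disagreement in r2 (position 5 of the fragment)
        b2 = list(r2.bases)
        pos_in_r2 = len(frag) - 1 - 5
        b2[pos_in_r2] = "A" if b2[pos_in_r2] != "A" else "C"
        r2 = ReadRecord("p", "".join(b2), r2.quals)
        m = merge_pair(r1, r2)
        assert m.bases == frag  # r1 (Q40) outvotes r2 (Q10)
        assert m.mismatches_in_overlap == 1
        assert m.quals[5] == 40

    def test_tie_goes_to_read_one(self):
        frag = "ACGTACGTGGCCATATCGCGTTAA"
        r1, r2 = pair_from_fragment(frag, len(frag), len(frag))
        b2 = list(r2.bases)
        assert b2[0] != "G"
        b2[0] = "G"  # disagrees with r1's last base at equal quality
        r2 = ReadRecord("p", "".join(b2), r2.quals)
        m = merge_pair(r1, r2)
        assert m.bases == frag

    def test_mismatch_fraction_threshold_brute_forced(self):
        # 30 bp true overlap with 4 planted mismatches: 4/30 > 0.1 (reject)
        # but <= 0.25 (accept).  Verify against scanning all overlaps.
        frag = "ATCCGGTTAACCGGATGCATGCAAGGTTCCATTGACCATGCAAGGTCGAT"
        r1, r2 = pair_from_fragment(frag, 40, 40)  # true overlap 30
        b1 = list(r1.bases)
        for p in (12, 18, 24, 30):  # inside the overlap [10, 40)
            b1[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b1[p]]
        r1 = ReadRecord("p", "".join(b1), r1.quals)
        assert merge_pair(r1, r2, max_mismatch_frac=0.1) is None
        m = merge_pair(r1, r2, max_mismatch_frac=0.25)
        assert m is not None
        assert m.overlap_len == 30
        assert m.mismatches_in_overlap == 4
        # brute-force: no longer admissible overlap exists at 0.25
        rc2 = reverse_complement(r2.bases)
        for ov in range(31, 41):
            tail, head = r1.bases[40 - ov:], rc2[:ov]
            mm = sum(a != b for a, b in zip(tail, head))
            assert mm / ov > 0.25

    def test_no_admissible_overlap_returns_unmerged(self):
        r1 = make_read("A" * 40)
        r2 = make_read("C" * 40)  # rc is G*40: no agreement anywhere
        assert merge_pair(r1, r2) is None

    def test_overlap_below_minimum_returns_unmerged(self):
        frag = "ACGTTGCAACGGTAGCATCCGGTTAACCGGAT"
        r1, r2 = pair_from_fragment(frag, 18, 18)  # true overlap 4
        assert merge_pair(r1, r2, min_overlap=10) is None
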