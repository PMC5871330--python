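"""Per-position tag deduplication: worked examples, invariants, oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from digitag.umi_dedup import (
    DedupSummary,
    EmptyGroupError,
    GroupedRead,
    TagLengthMismatchError,
    dedup_position_group,
    deduplicate_alignments,
    hamming_distance,
    rank_tags,
    select_representative,
)
from digitag.alignment_io import ReadRecord

from oracle import brute_force_dedup, random_group


def _group(*triples):
    return [GroupedRead(rid, tag, q) for rid, tag, q in triples]


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AAAAAAAA", "AAAAAAAA", 0),
            ("AAAAAAAA", "AAAAAAAT", 1),
            ("ACGTACGT", "TGCATGCA", 8),
            ("ANGT", "ANGT", 0),  # N matches N by character equality
            ("ANGT", "AAGT", 1),  # N differs from any other base
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(TagLengthMismatchError):
            hamming_distance("AAA", "AAAA")

    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=12),
        st.text(alphabet="ACGTN", min_size=1, max_size=12),
    )
    def test_symmetric(self, a, b):
        if len(a) != len(b):
            return
        assert hamming_distance(a, b) == hamming_distance(b, a)


class TestRankTags:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (
                {"AAAAAAAA": 3, "AAAAAAAT": 1, "CCCCCCCC": 1},
                ["AAAAAAAA", "AAAAAAAT", "CCCCCCCC"],
            ),
            ({"GGGGGGGG": 2, "AAAAAAAA": 2}, ["AAAAAAAA", "GGGGGGGG"]),
            ({}, []),
        ],
    )
    def test_count_desc_then_alphanumeric(self, counts, expected):
        assert rank_tags(counts) == expected

    def test_independent_of_insertion_order(self):
        counts = {"TTTT": 1, "AAAA": 1, "CCCC": 2}
        reordered = dict(sorted(counts.items(), reverse=True))
        assert rank_tags(counts) == rank_tags(reordered) == ["CCCC", "AAAA", "TTTT"]


class TestSelectRepresentative:
    @pytest.mark.parametrize(
        "reads, expected",
        [
            ([("r1", 30.0), ("r2", 35.0), ("r3", 35.0)], "r2"),
            ([("rX", 12.5)], "rX"),
            ([("b", 20.0), ("a", 20.0)], "a"),
        ],
    )
    def test_max_quality_then_id(self, reads, expected):
        assert select_representative(reads) == expected

    def test_empty_rejected(self):
        with pytest.raises(EmptyGroupError):
            select_representative([])


class TestDedupPositionGroup:
    def test_worked_five_read_example(self):
        """Tag AAAAAAAA keeps its best read, AAAAAAAT collapses into it,
        CCCCCCCC (distance 8) is accepted independently."""
        result = dedup_position_group(
            _group(
                ("r1", "AAAAAAAA", 30.0),
                ("r2", "AAAAAAAA", 35.0),
                ("r3", "AAAAAAAA", 35.0),
                ("r4", "AAAAAAAT", 40.0),
                ("r5", "CCCCCCCC", 20.0),
            )
        )
        assert result.kept == {"r2", "r5"}
        assert result.duplicates == {"r1", "r3", "r4"}
        assert result.valid_tags == ["AAAAAAAA", "CCCCCCCC"]
        assert result.per_tag_disposition["AAAAAAAT"] == ("collapsed", "AAAAAAAA")

    def test_single_read_kept(self):
        result = dedup_position_group(_group(("r1", "ACGTACGT", 10.0)))
        assert result.kept == {"r1"} and not result.duplicates

    def test_distance_two_tags_both_kept(self):
        result = dedup_position_group(
            _group(("r1", "AACC", 20.0), ("r2", "AAGG", 20.0))
        )
        assert result.kept == {"r1", "r2"}
        assert sorted(result.valid_tags) == ["AACC", "AAGG"]

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            dedup_position_group([])

    def test_mixed_tag_lengths_rejected(self):
        with pytest.raises(TagLengthMismatchError):
            dedup_position_group(_group(("r1", "AAAA", 10.0), ("r2", "AAA", 10.0)))


def groups(max_reads=30, tag_length=4, alphabet="AC"):
    """Strategy for small position groups with unique read ids."""
    tags = st.text(alphabet=alphabet, min_size=tag_length, max_size=tag_length)
    quals = st.sampled_from([10.0, 20.0, 30.0, 35.5])
    return st.lists(st.tuples(tags, quals), min_size=1, max_size=max_reads).map(
        lambda pairs: [
            GroupedRead(f"r{i:03d}", tag, q) for i, (tag, q) in enumerate(pairs)
        ]
    )


class TestAlgorithmInvariants:
    @settings(max_examples=300, derandomize=True)
    @given(groups())
    def test_partition_and_pool_separation(self, reads):
        """Kept and duplicates partition the input; accepted tags are
        pairwise at Hamming distance >= 2."""
        result = dedup_position_group(reads)
        ids = {r.read_id for r in reads}
        assert result.kept | result.duplicates == ids
        assert not (result.kept & result.duplicates)
        assert len(result.kept) == len(result.valid_tags)
        for i, a in enumerate(result.valid_tags):
            for b in result.valid_tags[i + 1 :]:
                assert hamming_distance(a, b) >= 2

    @settings(max_examples=300, derandomize=True)
    @given(groups())
    def test_idempotent_on_kept_reads(self, reads):
        """Re-deduplicating only the kept representatives marks nothing."""
        first = dedup_position_group(reads)
        survivors = [r for r in reads if r.read_id in first.kept]
        second = dedup_position_group(survivors)
        assert second.duplicates == set()
        assert second.kept == first.kept

    @settings(max_examples=300, derandomize=True)
    @given(groups(), st.randoms(use_true_random=False))
    def test_order_invariant(self, reads, rng):
        result = dedup_position_group(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        again = dedup_position_group(shuffled)
        assert again.kept == result.kept
        assert again.duplicates == result.duplicates
        assert again.valid_tags == result.valid_tags

    @settings(max_examples=500, derandomize=True)
    @given(groups())
    def test_matches_brute_force_oracle(self, reads):
        result = dedup_position_group(reads)
        kept, dups, pool = brute_force_dedup(
            [(r.read_id, r.tag, r.mean_quality) for r in reads]
        )
        assert result.kept == kept
        assert result.duplicates == dups
        assert result.valid_tags == pool


def test_oracle_agreement_randomized_sample():
    """Spot-check against the oracle on fully random groups (the large-scale
    sweep lives in the acceptance suite)."""
    rng = random.Random(7)
    for _ in range(500):
        triples = random_group(rng)
        reads = [GroupedRead(*t) for t in triples]
        result = dedup_position_group(reads)
        kept, dups, pool = brute_force_dedup(triples)
        assert (result.kept, result.duplicates, result.valid_tags) == (
            kept,
            dups,
            pool,
        )


def _record(rid, ref, pos, tag, qual, strand="+", cigar="4M"):
    flags = 0x10 if strand == "-" else 0
    return ReadRecord(
        read_id=f"{rid}_{tag}",
        reference=ref,
        position=pos,
        strand=strand,
        cigar=cigar,
        sequence="ACGT",
        base_qualities=[qual] * 4,
        flags=flags,
    )


class TestDeduplicateAlignments:
    def test_empty_stream(self):
        out, summary = deduplicate_alignments([], umi_length=8)
        assert out == [] and summary == DedupSummary()

    def test_five_read_single_position_summary(self):
        records = [
            _record("r1", "chr1", 100, "AAAAAAAA", 30),
            _record("r2", "chr1", 100, "AAAAAAAA", 35),
            _record("r3", "chr1", 100, "AAAAAAAA", 34),
            _record("r4", "chr1", 100, "AAAAAAAT", 40),
            _record("r5", "chr1", 100, "CCCCCCCC", 20),
        ]
        out, summary = deduplicate_alignments(records)
        assert summary.kept_reads == 2
        assert summary.duplicate_reads == 3
        assert summary.duplicate_rate == pytest.approx(0.6)
        assert len(out) == len(records)
        flagged = {r.read_id.split("_")[0] for r in out if r.is_duplicate}
        assert flagged == {"r1", "r3", "r4"}

    def test_positions_independent(self):
        records = [
            _record(f"p{p}c{c}", "chr1", 100 + 1000 * p, "AAAAAAAA", 30)
            for p in range(2)
            for c in range(3)
        ]
        _, summary = deduplicate_alignments(records)
        assert summary.kept_reads == 2
        assert summary.duplicate_reads == 4
        assert summary.positions_processed == 2

    def test_unmapped_passed_through_unflagged(self):
        mapped = _record("r1", "chr1", 100, "AAAAAAAA", 30)
        unmapped = ReadRecord(
            "u1_AAAAAAAA", "*", 0, "+", "*", "ACGT", [30] * 4, flags=0x4
        )
        out, summary = deduplicate_alignments([mapped, unmapped])
        assert summary.total_reads == 1
        assert not out[1].is_duplicate

    def test_input_order_does_not_change_flags(self):
        records = [
            _record("r1", "chr1", 100, "AACCAACC", 30),
            _record("r2", "chr1", 100, "AACCAACT", 35),
            _record("r3", "chr1", 100, "GGTTGGTT", 20),
            _record("r4", "chr2", 50, "AACCAACC", 10),
        ]
        out_fwd, s1 = deduplicate_alignments(records)
        out_rev, s2 = deduplicate_alignments(records[::-1])
        flags_fwd = {r.read_id: r.is_duplicate for r in out_fwd}
        flags_rev = {r.read_id: r.is_duplicate for r in out_rev}
        assert flags_fwd == flags_rev
        assert s1 == s2
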