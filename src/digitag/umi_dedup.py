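"""Molecular-tag (UMI) deduplication with 1-mismatch tag collapsing.

Each cDNA molecule in a tag-based library carries a random 8-mer tag, so
PCR copies of one molecule are reads that share a genomic position and a
tag.  Deduplication therefore works per position group:

1. count reads per tag;
2. sort tags by count descending, ties broken alphanumerically;
3. walk the tags in that order against an initially empty *valid pool*:
   a tag within Hamming distance 1 of any pool tag is treated as a
   sequencing-error copy of that pool tag and all of its reads become
   duplicates; otherwise the tag enters the pool, its highest-mean-PHRED
   read is kept as the molecule's representative and the remaining reads
   become duplicates.

Every step uses a total order (counts, tag strings, qualities, read ids),
so the result is deterministic and invariant under input permutation.
Accepted tags at one position are pairwise Hamming distance >= 2 by
construction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment_io import (
    PositionKey,
    ReadRecord,
    TagError,
    TagSource,
    extract_tag,
    mark_duplicate,
    position_key,
)

__all__ = [
    "GroupedRead",
    "PositionGroup",
    "DedupResult",
    "DedupSummary",
    "hamming_distance",
    "rank_tags",
    "select_representative",
    "dedup_position_group",
    "deduplicate_alignments",
]


class TagLengthMismatchError(ValueError):
    """Tags of unequal length compared or mixed within one group."""


class EmptyGroupError(ValueError):
    """An operation that requires at least one read received none."""


@dataclass(frozen=True)
class GroupedRead:
    """A read as seen by the per-position algorithm."""

    read_id: str
    tag: str
    mean_quality: float


@dataclass
class PositionGroup:
    """All reads sharing one position key."""

    key: PositionKey
    reads: list[GroupedRead]


@dataclass
class DedupResult:
    """Partition of one position group into kept reads and duplicates.

    ``valid_tags`` lists accepted tags in pool-insertion order; exactly one
    read is kept per valid tag.  ``per_tag_disposition`` maps every observed
    tag to ``"accepted"`` or ``("collapsed", target_tag)``.
    """

    kept: set[str]
    duplicates: set[str]
    valid_tags: list[str]
    per_tag_disposition: dict[str, object] = field(default_factory=dict)


@dataclass
class DedupSummary:
    total_reads: int = 0
    kept_reads: int = 0
    duplicate_reads: int = 0
    positions_processed: int = 0

    @property
    def duplicate_rate(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.duplicate_reads / self.total_reads


def hamming_distance(tag_a: str, tag_b: str) -> int:
    """Number of positions at which two equal-length tags differ.

    Plain character equality: ``N`` matches only ``N``.
    """
    if len(tag_a) != len(tag_b):
        raise TagLengthMismatchError(
            f"tag lengths differ: {len(tag_a)} vs {len(tag_b)}"
        )
    return sum(a != b for a, b in zip(tag_a, tag_b))


def rank_tags(tag_counts: Mapping[str, int]) -> list[str]:
    """Order tags by count descending, then tag string ascending.

    Deterministic regardless of mapping iteration order; an empty mapping
    yields an empty list.
    """
    return sorted(tag_counts, key=lambda t: (-tag_counts[t], t))


def select_representative(
    reads: Sequence[tuple[str, float]],
) -> str:
    """Pick the read with the highest mean PHRED quality.

    Quality ties are broken by read identifier ascending so the choice is
    stable under input permutation.
    """
    if not reads:
        raise EmptyGroupError("cannot select a representative from no reads")
    return min(reads, key=lambda r: (-r[1], r[0]))[0]


def dedup_position_group(
    reads: Sequence[GroupedRead] | PositionGroup,
) -> DedupResult:
    """Run the per-position algorithm on one group of reads."""
    if isinstance(reads, PositionGroup):
        reads = reads.reads
    if not reads:
        raise EmptyGroupError("empty position group")
    length = len(reads[0].tag)
    for r in reads:
        if len(r.tag) != length:
            raise TagLengthMismatchError(
                f"mixed tag lengths in group: {len(r.tag)} vs {length}"
            )

    by_tag: dict[str, list[GroupedRead]] = defaultdict(list)
    for r in reads:
        by_tag[r.tag].append(r)
    counts = {tag: len(rs) for tag, rs in by_tag.items()}

    kept: set[str] = set()
    duplicates: set[str] = set()
    valid_tags: list[str] = []
    disposition: dict[str, object] = {}

    for tag in rank_tags(counts):
        target = None
        for pool_tag in valid_tags:
            d = hamming_distance(tag, pool_tag)
            assert d >= 1, "distinct tags cannot coincide"
            if d == 1:
                target = pool_tag
                break
        if target is not None:
            disposition[tag] = ("collapsed", target)
            duplicates.update(r.read_id for r in by_tag[tag])
        else:
            valid_tags.append(tag)
            disposition[tag] = "accepted"
            rep = select_representative(
                [(r.read_id, r.mean_quality) for r in by_tag[tag]]
            )
            kept.add(rep)
            duplicates.update(
                r.read_id for r in by_tag[tag] if r.read_id != rep
            )

    return DedupResult(kept, duplicates, valid_tags, disposition)


def group_records(
    records: Iterable[ReadRecord],
    tag_source: TagSource = TagSource(),
    umi_length: int = 8,
    clip_adjust: bool = True,
    on_tag_error: str = "raise",
    aux_by_read: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> tuple[dict[PositionKey, PositionGroup], list[ReadRecord], list[ReadRecord]]:
    """Partition records into position groups.

    Returns (groups, passthrough, skipped): unmapped records go to
    ``passthrough`` unflagged; with ``on_tag_error="skip"`` records whose tag
    cannot be extracted go to ``skipped`` (also passed through unflagged).
    """
    if on_tag_error not in ("raise", "skip"):
        raise ValueError(f"on_tag_error must be 'raise' or 'skip': {on_tag_error!r}")
    groups: dict[PositionKey, PositionGroup] = {}
    passthrough: list[ReadRecord] = []
    skipped: list[ReadRecord] = []
    for rec in records:
        if not rec.is_mapped:
            passthrough.append(rec)
            continue
        try:
            aux = dict(aux_by_read[rec.read_id]) if aux_by_read else None
            tag = rec.tag or extract_tag(rec, tag_source, umi_length, aux=aux)
        except TagError:
            if on_tag_error == "raise":
                raise
            skipped.append(rec)
            continue
        rec.tag = tag
        key = position_key(rec, clip_adjust=clip_adjust)
        if key not in groups:
            groups[key] = PositionGroup(key, [])
        groups[key].reads.append(GroupedRead(rec.read_id, tag, rec.mean_quality))
    return groups, passthrough, skipped


def deduplicate_alignments(
    records: Iterable[ReadRecord],
    tag_source: TagSource = TagSource(),
    umi_length: int = 8,
    clip_adjust: bool = True,
    on_tag_error: str = "raise",
    aux_by_read: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> tuple[list[ReadRecord], DedupSummary]:
    """Mark duplicate reads across a whole alignment stream.

    Groups mapped records by position key, runs :func:`dedup_position_group`
    per group and sets the SAM duplicate bit on duplicates.  No record is
    dropped: unmapped (and, with ``on_tag_error="skip"``, untaggable) records
    are passed through unflagged and excluded from grouping and from the
    summary's read totals.  Output order follows input order.
    """
    records = list(records)
    groups, passthrough, skipped = group_records(
        records, tag_source, umi_length, clip_adjust, on_tag_error, aux_by_read
    )
    excluded_ids = {r.read_id for r in passthrough} | {r.read_id for r in skipped}

    duplicate_ids: set[str] = set()
    summary = DedupSummary()
    for key in sorted(groups):
        result = dedup_position_group(groups[key])
        _check_result(groups[key], result)
        duplicate_ids.update(result.duplicates)
        summary.total_reads += len(groups[key].reads)
        summary.kept_reads += len(result.kept)
        summary.duplicate_reads += len(result.duplicates)
        summary.positions_processed += 1

    out: list[ReadRecord] = []
    for rec in records:
        if rec.read_id in duplicate_ids and rec.read_id not in excluded_ids:
            out.append(mark_duplicate(rec))
        else:
            out.append(rec)
    return out, summary


def _check_result(group: PositionGroup, result: DedupResult) -> None:
    """Invariants asserted on every run."""
    ids = {r.read_id for r in group.reads}
    assert result.kept | result.duplicates == ids
    assert not (result.kept & result.duplicates)
    assert len(result.kept) == len(result.valid_tags)
    for i, a in enumerate(result.valid_tags):
        for b in result.valid_tags[i + 1 :]:
            assert hamming_distance(a, b) >= 2
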