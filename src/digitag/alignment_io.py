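"""Alignment records, molecular-tag extraction and position-grouping keys.

Single-end reads are modelled as lightweight :class:`ReadRecord` objects that
carry exactly the fields deduplication needs: coordinates, strand, CIGAR,
per-base PHRED qualities and the molecular tag.  SAM files are read and
written through pysam; the duplicate state is the standard SAM duplicate bit
(0x400), so any downstream tool that honours duplicate marking can consume
the output.

Reads are grouped by their inferred *unclipped 5' end* rather than the raw
leftmost mapping coordinate: PCR copies of one cDNA fragment can acquire
different soft-clips during alignment, and adjusting for the clip makes the
copies coincide on one key.  Grouping by raw leftmost coordinate is available
via ``position_key(record, clip_adjust=False)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pysam

#: SAM flag bit for "PCR or optical duplicate".
DUPLICATE_FLAG = 0x400

#: SAM flag bit for "segment unmapped".
UNMAPPED_FLAG = 0x4

#: SAM flag bit for "SEQ being reverse complemented".
REVERSE_FLAG = 0x10

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume the reference.
_REF_OPS = frozenset("MDN=X")


class TagError(ValueError):
    """Molecular tag missing from a record or of the wrong length."""


class CigarError(ValueError):
    """CIGAR string absent or unparseable."""


class UngroupableError(ValueError):
    """Record cannot be assigned a position key (e.g. unmapped)."""


@dataclass
class ReadRecord:
    """One aligned single-end read.

    ``position`` is the 1-based leftmost aligned reference coordinate, as in
    SAM.  ``base_qualities`` are PHRED integers, one per sequence base.
    ``tag`` is the molecular tag once extracted (``None`` until then).
    """

    read_id: str
    reference: str
    position: int
    strand: str
    cigar: str
    sequence: str
    base_qualities: list[int] = field(default_factory=list)
    tag: Optional[str] = None
    flags: int = 0

    @property
    def is_mapped(self) -> bool:
        return not (self.flags & UNMAPPED_FLAG)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & DUPLICATE_FLAG)

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean PHRED over all bases (soft-clipped included)."""
        if not self.base_qualities:
            return 0.0
        return sum(self.base_qualities) / len(self.base_qualities)


@dataclass(frozen=True, order=True)
class PositionKey:
    """Grouping key: (reference, strand, inferred unclipped 5' coordinate).

    Totally ordered so that grouping and iteration are deterministic.
    """

    reference: str
    strand: str
    five_prime: int


@dataclass(frozen=True)
class TagSource:
    """Where to find the molecular tag on a record.

    ``kind="readname"``: the tag is the last ``delimiter``-separated field of
    the read name (the convention used when the index read is appended to the
    name during demultiplexing).  ``kind="field"``: the tag sits in a
    two-character SAM auxiliary field named ``sam_tag`` (e.g. ``RX``).
    """

    kind: str = "readname"
    delimiter: str = "_"
    sam_tag: str = "RX"

    def __post_init__(self) -> None:
        if self.kind not in ("readname", "field"):
            raise ValueError(f"unknown tag source kind: {self.kind!r}")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; '*' is an error."""
    if not cigar or cigar == "*":
        raise CigarError(f"missing CIGAR: {cigar!r}")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise CigarError(f"unparseable CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def extract_tag(
    record: ReadRecord,
    source: TagSource = TagSource(),
    umi_length: int = 8,
    aux: Optional[dict[str, str]] = None,
) -> str:
    """Extract and validate the molecular tag of a record.

    Raises :class:`TagError` when the tag cannot be located or its length
    differs from ``umi_length``.  ``aux`` supplies SAM auxiliary fields when
    ``source.kind == "field"``.
    """
    if source.kind == "readname":
        name = record.read_id
        if source.delimiter not in name:
            raise TagError(
                f"read {name!r}: no {source.delimiter!r} delimiter in name"
            )
        tag = name.rsplit(source.delimiter, 1)[1]
    else:
        if aux is None or source.sam_tag not in aux:
            raise TagError(
                f"read {record.read_id!r}: missing {source.sam_tag} field"
            )
        tag = str(aux[source.sam_tag])
    tag = tag.upper()
    if len(tag) != umi_length:
        raise TagError(
            f"read {record.read_id!r}: tag {tag!r} has length {len(tag)}, "
            f"expected {umi_length}"
        )
    return tag


def _clip_lengths(ops: list[tuple[int, str]]) -> tuple[int, int]:
    """Leading and trailing soft-clip lengths (hard clips are skipped)."""
    leading = trailing = 0
    i = 0
    if i < len(ops) and ops[i][1] == "H":
        i += 1
    if i < len(ops) and ops[i][1] == "S":
        leading = ops[i][0]
    j = len(ops) - 1
    if j >= 0 and ops[j][1] == "H":
        j -= 1
    if j >= 0 and ops[j][1] == "S":
        trailing = ops[j][0]
    return leading, trailing


def reference_span(cigar: str) -> int:
    """Number of reference bases consumed by the alignment."""
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


def position_key(record: ReadRecord, clip_adjust: bool = True) -> PositionKey:
    """Compute the grouping key for a mapped record.

    Forward strand: 5' end = leftmost coordinate minus leading soft clip.
    Reverse strand: 5' end = rightmost reference coordinate consumed plus the
    trailing soft clip.  With ``clip_adjust=False`` the raw leftmost
    coordinate is used on both strands.
    """
    if not record.is_mapped:
        raise UngroupableError(f"read {record.read_id!r} is unmapped")
    if not clip_adjust:
        return PositionKey(record.reference, record.strand, record.position)
    ops = parse_cigar(record.cigar)
    leading, trailing = _clip_lengths(ops)
    if record.strand == "+":
        five_prime = record.position - leading
    else:
        rightmost = record.position + sum(
            n for n, op in ops if op in _REF_OPS
        ) - 1
        five_prime = rightmost + trailing
    return PositionKey(record.reference, record.strand, five_prime)


def mark_duplicate(record: ReadRecord) -> ReadRecord:
    """Return a copy with the duplicate bit set; idempotent."""
    return replace(record, flags=record.flags | DUPLICATE_FLAG)


def aligned_blocks(record: ReadRecord) -> list[tuple[int, int]]:
    """1-based inclusive reference intervals covered by aligned bases.

    Only M/=/X consume both read and reference; deletions and skipped
    introns (D/N) advance the reference without contributing aligned bases.
    """
    blocks: list[tuple[int, int]] = []
    ref = record.position
    for n, op in parse_cigar(record.cigar):
        if op in "M=X":
            blocks.append((ref, ref + n - 1))
            ref += n
        elif op in "DN":
            ref += n
    return blocks


# ---------------------------------------------------------------------------
# SAM I/O

def _from_pysam(seg: pysam.AlignedSegment) -> ReadRecord:
    quals = list(seg.query_qualities) if seg.query_qualities is not None else []
    return ReadRecord(
        read_id=seg.query_name,
        reference=seg.reference_name if not seg.is_unmapped else "*",
        position=(seg.reference_start + 1) if not seg.is_unmapped else 0,
        strand="-" if seg.is_reverse else "+",
        cigar=seg.cigarstring or "*",
        sequence=seg.query_sequence or "",
        base_qualities=quals,
        flags=seg.flag,
    )


def read_alignments(path: str) -> Iterator[tuple[ReadRecord, dict[str, str]]]:
    """Yield (ReadRecord, auxiliary-field dict) for every record in a SAM/BAM."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            aux = {k: str(v) for k, v in seg.get_tags()}
            yield _from_pysam(seg), aux


def write_alignments(
    path: str,
    records: Iterable[ReadRecord],
    references: dict[str, int],
    mode: str = "w",
) -> None:
    """Write ReadRecords as SAM (``mode="w"``) or BAM (``mode="wb"``)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = rec.flags
            if rec.is_mapped:
                seg.reference_name = rec.reference
                seg.reference_start = rec.position - 1
                seg.cigarstring = rec.cigar
                seg.mapping_quality = 60
            else:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            seg.query_sequence = rec.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.base_qualities)
            )
            out.write(seg)
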