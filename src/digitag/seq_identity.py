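"""Percent identity of gapped pairwise alignments.

The statistic is 100 * identical / (aligned + internal gap) columns, where
an *aligned* column has a residue in both sequences, an *identical* column
is an aligned column whose residues match (case-insensitive), and an
*internal gap* column contains a gap and lies strictly between the first
and last aligned column.  Terminal overhangs — gap runs before the first or
after the last aligned column — do not enter the denominator, so two
sequences that are identical over their overlap score 100 regardless of how
far one extends past the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO

__all__ = ["GappedPair", "percent_identity", "iter_fasta_pairs"]

GAP = "-"


class AlignmentShapeError(ValueError):
    """Sequences of unequal length or an all-gap column pair."""


class UndefinedIdentityError(ValueError):
    """No aligned columns: the statistic's denominator is zero."""


@dataclass(frozen=True)
class GappedPair:
    """Two rows of a pairwise alignment, equal length, '-' for gaps."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentShapeError(
                f"aligned sequences differ in length: "
                f"{len(self.seq_a)} vs {len(self.seq_b)}"
            )
        for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b)):
            if a == GAP and b == GAP:
                raise AlignmentShapeError(f"column {i} is gapped in both rows")


def percent_identity(pair: GappedPair | tuple[str, str]) -> float:
    """Percent identity of one gapped pair, in [0, 100].

    Raises :class:`UndefinedIdentityError` when the sequences share no
    aligned column.
    """
    if not isinstance(pair, GappedPair):
        pair = GappedPair(*pair)
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    aligned_cols = [i for i in range(len(a)) if a[i] != GAP and b[i] != GAP]
    if not aligned_cols:
        raise UndefinedIdentityError("no column with residues in both rows")
    first, last = aligned_cols[0], aligned_cols[-1]
    identical = sum(1 for i in aligned_cols if a[i] == b[i])
    internal_gaps = sum(
        1
        for i in range(first + 1, last)
        if a[i] == GAP or b[i] == GAP
    )
    return 100.0 * identical / (len(aligned_cols) + internal_gaps)


def iter_fasta_pairs(path: str) -> Iterator[tuple[str, str, float]]:
    """Yield (id_a, id_b, percent identity) for consecutive record pairs.

    The aligned FASTA must contain an even number of records; records
    2k and 2k+1 form pair k.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) % 2:
        raise AlignmentShapeError(
            f"{path}: odd number of records ({len(records)}); "
            "expected consecutive pairs"
        )
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        yield a.id, b.id, percent_identity((str(a.seq), str(b.seq)))
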