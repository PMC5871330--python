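"""Tumor/control whole-genome comparison utilities.

Covers three computations used when screening tumors for recurrent DNA
alterations: binned read coverage with median normalization and log2 fold
change between samples, threshold filtering of somatic variant candidates
(minimum tumor and control coverage, minimum allele frequency), and the
search for fixed-length genomic windows that contain small InDels in every
tumor sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinTrack",
    "VariantSite",
    "bin_coverage",
    "median_normalize",
    "coverage_fold_change",
    "filter_somatic_candidates",
    "recurrent_indel_windows",
    "read_variant_table",
]


class NormalizationError(ValueError):
    """Track cannot be median-normalized (median is zero)."""


@dataclass
class BinTrack:
    """Per-bin numeric values along one reference sequence.

    Bin i (0-based) covers [origin + i*bin_size, origin + (i+1)*bin_size - 1]
    in 1-based coordinates.
    """

    reference: str
    bin_size: int
    values: np.ndarray
    origin: int = 1

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1: {self.bin_size}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class VariantSite:
    """One somatic variant candidate with its supporting coverage."""

    reference: str
    position: int
    ref_allele: str
    alt_allele: str
    tumor_coverage: int
    control_coverage: int
    allele_frequency: float
    kind: str = "snv"

    def __post_init__(self) -> None:
        if self.tumor_coverage < 0 or self.control_coverage < 0:
            raise ValueError("coverages must be non-negative")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")


def bin_coverage(
    read_positions: Sequence[int],
    bin_size: int,
    reference_length: int,
    reference: str = "",
) -> BinTrack:
    """Count reads per genomic bin by their 5' coordinate.

    Every read falls in exactly one bin; the last partial bin is included,
    so the bin-count total equals the number of positions.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1: {bin_size}")
    positions = np.asarray(read_positions, dtype=int)
    if positions.size and (positions.min() < 1 or positions.max() > reference_length):
        raise ValueError("positions outside [1, reference_length]")
    n_bins = max(1, math.ceil(reference_length / bin_size))
    counts = np.bincount((positions - 1) // bin_size, minlength=n_bins)
    return BinTrack(reference, bin_size, counts.astype(float), origin=1)


def median_normalize(track: BinTrack) -> BinTrack:
    """Divide every bin by the track's median; output median is 1."""
    med = float(np.median(track.values))
    if med == 0.0:
        raise NormalizationError(
            "track median is 0; mask empty bins before normalizing"
        )
    return BinTrack(
        track.reference, track.bin_size, track.values / med, track.origin
    )


def coverage_fold_change(
    tumor: BinTrack,
    control: BinTrack,
    pseudocount: float = 0.0,
) -> BinTrack:
    """Per-bin log2((tumor + pseudocount) / (control + pseudocount)).

    Both tracks must share binning.  With pseudocount 0, bins where only
    one sample has signal become +/-inf and double-zero bins become NaN;
    they are flagged (not silently dropped) so the caller can mask them.
    """
    if (
        tumor.bin_size != control.bin_size
        or tumor.origin != control.origin
        or len(tumor.values) != len(control.values)
    ):
        raise ValueError("tumor and control tracks are binned differently")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(
            (tumor.values + pseudocount) / (control.values + pseudocount)
        )
    return BinTrack(tumor.reference, tumor.bin_size, ratio, tumor.origin)


def filter_somatic_candidates(
    sites: Iterable[VariantSite],
    min_tumor_cov: int = 14,
    min_control_cov: int = 8,
    min_af: float = 0.1,
) -> list[VariantSite]:
    """Keep candidates passing the coverage and allele-frequency gates.

    Coverage cuts are strict (tumor > 14, control > 8) while the allele
    frequency is inclusive (>= 0.1), matching the stated operators.
    """
    return [
        s
        for s in sites
        if s.tumor_coverage > min_tumor_cov
        and s.control_coverage > min_control_cov
        and s.allele_frequency >= min_af
    ]


def recurrent_indel_windows(
    indels: Mapping[str, Iterable[tuple[str, int]]],
    window_length: int = 10_000,
) -> list[tuple[str, int, int]]:
    """Windows containing at least one InDel from every sample.

    Each reference is tiled into non-overlapping windows of
    ``window_length`` starting at coordinate 1; a window is recurrent when
    all samples place an InDel inside it.  Returns (reference, start, end)
    tuples, 1-based inclusive, sorted.
    """
    if window_length < 1:
        raise ValueError(f"window_length must be >= 1: {window_length}")
    if not indels:
        raise ValueError("at least one sample is required")
    per_sample_windows: list[set[tuple[str, int]]] = []
    for sample, sites in indels.items():
        windows = {(ref, (pos - 1) // window_length) for ref, pos in sites}
        per_sample_windows.append(windows)
    common = set.intersection(*per_sample_windows)
    return sorted(
        (ref, idx * window_length + 1, (idx + 1) * window_length)
        for ref, idx in common
    )


def read_variant_table(path: str) -> list[VariantSite]:
    """Load variant candidates from a TSV.

    Columns: reference, position, ref, alt, tumor_cov, control_cov, af, kind.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        VariantSite(
            reference=str(r.reference),
            position=int(r.position),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            tumor_coverage=int(r.tumor_cov),
            control_coverage=int(r.control_cov),
            allele_frequency=float(r.af),
            kind=str(r.kind),
        )
        for r in df.itertuples()
    ]
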