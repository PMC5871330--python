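"""Synthetic tag-based library generator with ground truth.

Emulates the structure of a molecular-barcode RNA-seq library: at each
genomic position a number of cDNA molecules each receive a uniformly random
8-mer tag, PCR amplification turns every molecule into one or more reads
sharing its tag, and tag sequencing introduces independent per-base
substitution errors.  Each read carries a per-base PHRED quality string.
Reads are emitted pre-aligned (single synthetic reference, perfect CIGAR)
since alignment is outside the scope of this package.

The ground truth (:class:`SimTruth`) records which molecule every read came
from, so deduplication accuracy can be measured exactly.  The analytic
collision expectation for m uniform draws from a tag space of size K,
``K * (1 - (1 - 1/K)**m)``, is provided for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alignment_io import PositionKey, ReadRecord, REVERSE_FLAG
from .umi_dedup import DedupResult, hamming_distance

__all__ = [
    "SimConfig",
    "SimTruth",
    "RecoveryMetrics",
    "simulate_library",
    "expected_distinct_tags",
    "evaluate_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


class ConfigurationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library.

    ``pcr_copies`` is ``("fixed", k)`` for exactly k reads per molecule or
    ``("geometric", mu)`` for a geometric copy number on {1, 2, ...} with
    mean mu.  ``min_tag_distance`` optionally rejection-samples tags at one
    position to pairwise Hamming distance >= that value.
    """

    n_positions: int = 100
    molecules_per_position: int = 50
    umi_length: int = 8
    pcr_copies: tuple[str, float] = ("geometric", 4.0)
    umi_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 5.0
    read_length: int = 50
    reference: str = "sim_ref"
    position_spacing: int = 1000
    min_tag_distance: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 0 or self.molecules_per_position <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.umi_error_rate <= 1.0:
            raise ConfigurationError("umi_error_rate must lie in [0, 1]")
        kind, value = self.pcr_copies
        if kind not in ("fixed", "geometric") or value < 1:
            raise ConfigurationError(f"bad pcr_copies spec: {self.pcr_copies}")


@dataclass
class SimTruth:
    """Per-read molecule identity plus true molecule counts per position."""

    reads: pd.DataFrame  # read_id, molecule_id, true_tag, observed_tag, reference, five_prime, strand
    molecule_counts: dict[PositionKey, int] = field(default_factory=dict)


def _random_tag(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_position_tags(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_distance: Optional[int],
) -> list[str]:
    if min_distance is None or min_distance <= 1:
        return [_random_tag(rng, length) for _ in range(n)]
    tags: list[str] = []
    attempts = 0
    limit = 1000 * n
    while len(tags) < n:
        cand = _random_tag(rng, length)
        attempts += 1
        if attempts > limit:
            raise ConfigurationError(
                f"cannot place {n} tags of length {length} at pairwise "
                f"distance >= {min_distance}"
            )
        if all(hamming_distance(cand, t) >= min_distance for t in tags):
            tags.append(cand)
    return tags


def _mutate_tag(rng: np.random.Generator, tag: str, rate: float) -> str:
    if rate == 0.0:
        return tag
    chars = list(tag)
    for i, base in enumerate(chars):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != base]
            chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _n_copies(rng: np.random.Generator, spec: tuple[str, float]) -> int:
    kind, value = spec
    if kind == "fixed":
        return int(value)
    # geometric on {1, 2, ...} with mean mu -> success prob 1/mu
    return int(rng.geometric(1.0 / value))


def simulate_library(config: SimConfig) -> tuple[list[ReadRecord], SimTruth]:
    """Generate reads and ground truth; byte-identical for a fixed seed.

    All reads are forward-strand with CIGAR ``<read_length>M``; positions
    are spaced so groups never collide.  The observed tag is appended to the
    read name after an underscore, matching the default tag source.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ReadRecord] = []
    rows: list[tuple] = []
    counts: dict[PositionKey, int] = {}

    for p in range(config.n_positions):
        pos = 1 + p * config.position_spacing
        key = PositionKey(config.reference, "+", pos)
        true_tags = _draw_position_tags(
            rng,
            config.molecules_per_position,
            config.umi_length,
            config.min_tag_distance,
        )
        counts[key] = len(true_tags)
        for m, true_tag in enumerate(true_tags):
            molecule_id = f"p{p:05d}m{m:04d}"
            for c in range(_n_copies(rng, config.pcr_copies)):
                observed = _mutate_tag(rng, true_tag, config.umi_error_rate)
                read_id = f"{molecule_id}c{c:03d}_{observed}"
                seq = "".join(
                    _BASES[rng.integers(0, 4, size=config.read_length)]
                )
                quals = np.clip(
                    np.rint(
                        rng.normal(
                            config.quality_mean,
                            config.quality_sd,
                            size=config.read_length,
                        )
                    ),
                    2,
                    41,
                ).astype(int)
                records.append(
                    ReadRecord(
                        read_id=read_id,
                        reference=config.reference,
                        position=pos,
                        strand="+",
                        cigar=f"{config.read_length}M",
                        sequence=seq,
                        base_qualities=list(quals),
                        tag=None,
                    )
                )
                rows.append(
                    (
                        read_id,
                        molecule_id,
                        true_tag,
                        observed,
                        config.reference,
                        pos,
                        "+",
                    )
                )

    truth = SimTruth(
        reads=pd.DataFrame(
            rows,
            columns=[
                "read_id",
                "molecule_id",
                "true_tag",
                "observed_tag",
                "reference",
                "five_prime",
                "strand",
            ],
        ),
        molecule_counts=counts,
    )
    return records, truth


def expected_distinct_tags(m: int, K: int) -> float:
    """Expected number of distinct tags after m uniform draws from K tags.

    Each of the K tags is missed with probability (1 - 1/K)^m, so the
    expectation is K * (1 - (1 - 1/K)**m).
    """
    if m < 0 or K < 1:
        raise ValueError("require m >= 0 and K >= 1")
    return K * (1.0 - (1.0 - 1.0 / K) ** m)


@dataclass
class RecoveryMetrics:
    """Accuracy of deduplication against simulation truth."""

    per_position: pd.DataFrame  # estimated, truth, abs_error, rel_error
    mean_abs_error: float
    mean_rel_error: float
    duplicate_precision: float
    duplicate_recall: float


def evaluate_recovery(
    results: dict[PositionKey, DedupResult],
    truth: SimTruth,
) -> RecoveryMetrics:
    """Compare per-position dedup results with the simulation ground truth.

    A read is a *true duplicate* when another read of its molecule outranks
    it under the kept-read criterion (higher mean quality, ties broken by
    read id) — i.e. exactly one read per molecule is truly non-duplicate.
    Raises on empty truth or on read ids not present in the truth table.
    """
    if truth.reads.empty:
        raise ValueError("empty library: recovery metrics are undefined")

    known_ids = set(truth.reads["read_id"])
    predicted_dups: set[str] = set()
    rows = []
    for key, result in results.items():
        for rid in result.kept | result.duplicates:
            if rid not in known_ids:
                raise ValueError(f"read {rid!r} absent from truth")
        predicted_dups |= result.duplicates
        true_count = truth.molecule_counts.get(key)
        if true_count is None:
            raise ValueError(f"position {key} absent from truth")
        est = len(result.valid_tags)
        rows.append(
            {
                "reference": key.reference,
                "five_prime": key.five_prime,
                "estimated": est,
                "truth": true_count,
                "abs_error": abs(est - true_count),
                "rel_error": abs(est - true_count) / true_count,
            }
        )
    per_position = pd.DataFrame(rows)

    # ranking within a molecule needs mean qualities: see attach_qualities
    true_dups = _true_duplicates(truth)
    tp = len(predicted_dups & true_dups)
    precision = tp / len(predicted_dups) if predicted_dups else 1.0
    recall = tp / len(true_dups) if true_dups else 1.0
    return RecoveryMetrics(
        per_position=per_position,
        mean_abs_error=float(per_position["abs_error"].mean()),
        mean_rel_error=float(per_position["rel_error"].mean()),
        duplicate_precision=precision,
        duplicate_recall=recall,
    )


def _true_duplicates(truth: SimTruth) -> set[str]:
    dups: set[str] = set()
    if "mean_quality" in truth.reads.columns:
        ordered = truth.reads.sort_values(
            ["molecule_id", "mean_quality", "read_id"],
            ascending=[True, False, True],
        )
    else:
        ordered = truth.reads.sort_values(["molecule_id", "read_id"])
    seen: set[str] = set()
    for mol, rid in zip(ordered["molecule_id"], ordered["read_id"]):
        if mol in seen:
            dups.add(rid)
        else:
            seen.add(mol)
    return dups


def attach_qualities(truth: SimTruth, records: list[ReadRecord]) -> None:
    """Add a mean_quality column to the truth table from the read records.

    Makes the true-duplicate definition (best read per molecule by mean
    PHRED, ties by read id) computable during recovery evaluation.
    """
    quals = {r.read_id: r.mean_quality for r in records}
    truth.reads["mean_quality"] = truth.reads["read_id"].map(quals)
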