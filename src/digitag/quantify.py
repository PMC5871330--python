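"""Gene-level counting of deduplicated reads and fold-change classification.

Gene models come from GTF; biotypes known to dominate low-input libraries
without being informative (snRNA, rRNA, tRNA, snoRNA, pseudogenes) are
masked before counting.  Reads are assigned in union mode: a read counts for
a gene when any aligned base overlaps any of the gene's exons; reads hitting
more than one gene are ambiguous, reads hitting none are no-feature.
Differential-expression labels apply fixed thresholds (adjusted p < 0.01,
|log2 fold change| >= 2) to externally fitted (log2fc, padj) pairs; no
dispersion model is fitted here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignment_io import ReadRecord, aligned_blocks

__all__ = [
    "GeneModel",
    "GeneIndex",
    "DEFAULT_MASKED_BIOTYPES",
    "AMBIGUOUS",
    "NO_FEATURE",
    "mask_biotypes",
    "assign_read_to_gene",
    "build_count_matrix",
    "classify_de",
    "read_gene_models",
]

#: Biotypes removed before downstream analysis.
DEFAULT_MASKED_BIOTYPES = frozenset(
    {"snRNA", "rRNA", "tRNA", "snoRNA", "pseudogene"}
)

AMBIGUOUS = "__ambiguous__"
NO_FEATURE = "__no_feature__"


@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of exon intervals (1-based inclusive)."""

    gene_id: str
    biotype: str
    strand: str
    exons: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        for ref, start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid exon {ref}:{start}-{end}"
                )


def mask_biotypes(
    genes: Iterable[GeneModel],
    masked: frozenset[str] | set[str] = DEFAULT_MASKED_BIOTYPES,
) -> list[GeneModel]:
    """Drop genes whose biotype is in the masked set; order preserved."""
    return [g for g in genes if g.biotype not in masked]


class GeneIndex:
    """Interval index over exons for overlap queries.

    ``stranded=True`` restricts matches to genes on the read's strand;
    the default is strand-agnostic.
    """

    def __init__(self, genes: Iterable[GeneModel], stranded: bool = False):
        self.stranded = stranded
        self._trees: dict[object, IntervalTree] = {}
        for gene in genes:
            for ref, start, end in gene.exons:
                key = (ref, gene.strand) if stranded else ref
                tree = self._trees.setdefault(key, IntervalTree())
                # interval end is exclusive in intervaltree
                tree.addi(start, end + 1, gene.gene_id)

    def overlapping(self, record: ReadRecord) -> set[str]:
        key = (record.reference, record.strand) if self.stranded else record.reference
        tree = self._trees.get(key)
        if tree is None:
            return set()
        hits: set[str] = set()
        for start, end in aligned_blocks(record):
            for iv in tree.overlap(start, end + 1):
                hits.add(iv.data)
        return hits


def assign_read_to_gene(record: ReadRecord, index: GeneIndex) -> str:
    """Union-mode assignment of one kept read.

    Returns the gene id when exactly one gene's exons overlap an aligned
    base, :data:`AMBIGUOUS` for more than one, :data:`NO_FEATURE` for none.
    """
    hits = index.overlapping(record)
    if len(hits) == 1:
        return next(iter(hits))
    return AMBIGUOUS if hits else NO_FEATURE


def build_count_matrix(
    assignments: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally per-sample assignments into a genes x samples matrix.

    ``assignments`` maps sample id to the per-read assignment outcomes of
    its kept reads.  Returns (counts, qc) where ``qc`` holds the unique /
    ambiguous / no_feature tallies per sample; unique + ambiguous +
    no_feature equals the kept-read total of each sample.
    """
    samples = list(assignments)
    per_sample: dict[str, Counter] = {
        s: Counter(assignments[s]) for s in samples
    }
    genes = sorted(
        {
            g
            for c in per_sample.values()
            for g in c
            if g not in (AMBIGUOUS, NO_FEATURE)
        }
    )
    counts = pd.DataFrame(
        {s: [per_sample[s].get(g, 0) for g in genes] for s in samples},
        index=pd.Index(genes, name="gene_id"),
        dtype=int,
    )
    qc = pd.DataFrame(
        {
            s: {
                "unique": sum(
                    n
                    for g, n in per_sample[s].items()
                    if g not in (AMBIGUOUS, NO_FEATURE)
                ),
                "ambiguous": per_sample[s].get(AMBIGUOUS, 0),
                "no_feature": per_sample[s].get(NO_FEATURE, 0),
            }
            for s in samples
        },
        dtype=int,
    )
    return counts, qc


def classify_de(
    log2fc: float,
    padj: float,
    fdr: float = 0.01,
    lfc: float = 2.0,
) -> str:
    """Label a gene ``up``, ``down`` or ``unchanged``.

    ``up`` iff padj < fdr and log2fc >= lfc; ``down`` iff padj < fdr and
    log2fc <= -lfc.  Fold-change boundaries are inclusive, the significance
    cut is strict.  Positive log2fc means higher expression in the
    treatment/tumor sample.
    """
    if not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj must lie in [0, 1]: {padj}")
    if padj < fdr:
        if log2fc >= lfc:
            return "up"
        if log2fc <= -lfc:
            return "down"
    return "unchanged"


def read_gene_models(gtf_path: str) -> list[GeneModel]:
    """Load gene models from a GTF file (exon features only).

    Biotype is taken from the first of ``gene_biotype`` / ``gene_type`` /
    ``biotype`` attributes, defaulting to ``protein_coding``.
    """
    import gffutils.iterators

    exons: dict[str, list[tuple[str, int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in gffutils.iterators.DataIterator(gtf_path):
        if feat.featuretype != "exon":
            continue
        gene_id = feat.attributes["gene_id"][0]
        biotype = "protein_coding"
        for key in ("gene_biotype", "gene_type", "biotype"):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        exons.setdefault(gene_id, []).append((feat.seqid, feat.start, feat.end))
        meta.setdefault(gene_id, (biotype, feat.strand))
    return [
        GeneModel(gid, meta[gid][0], meta[gid][1], tuple(sorted(exs)))
        for gid, exs in exons.items()
    ]
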