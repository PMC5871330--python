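# Methods

## Deduplication model

A tag-based library attaches a uniformly random 8-mer tag (UMI) to each
cDNA molecule before PCR. After alignment, reads from one molecule share
(reference, strand, fragment 5′ end) and — up to sequencing errors — the
tag. Deduplication is a per-position procedure over the multiset of
observed tags:

1. **Grouping key.** Reads are grouped by (reference, strand, inferred
   unclipped 5′ end). On the forward strand the 5′ end is the leftmost
   aligned coordinate minus any leading soft clip; on the reverse strand
   it is the rightmost reference coordinate consumed by the alignment plus
   any trailing soft clip. Hard clips consume no sequence and are ignored.
   The clip adjustment makes PCR copies that acquired different clips
   coincide; grouping by raw leftmost coordinate is available
   (`clip_adjust=False` / `--no-clip-adjust`) for strict
   position-as-printed behaviour.
2. **Tag ranking.** Tags are ordered by read count descending, ties broken
   by tag string ascending (ASCII). The order is total, so results do not
   depend on hash or input order.
3. **Collapse rule.** Tags are consumed in rank order against a growing
   *valid pool*. A tag within Hamming distance 1 of any pool tag is
   interpreted as a sequencing error of that (more abundant, or
   equally-abundant-but-earlier) tag: all of its reads become duplicates
   and the collapse target recorded is the first pool tag at distance 1 in
   pool-insertion order. Otherwise the tag joins the pool. Distinct tags
   always differ, so a distance-0 hit against the pool is impossible; this
   is asserted rather than branched on.
4. **Representative.** For each accepted tag the read with the highest
   mean PHRED quality (arithmetic mean over all base qualities, soft-
   clipped bases included, no rounding) is kept; ties are broken by read
   identifier ascending. All other reads of the tag become duplicates.

Consequences, asserted on every run: kept and duplicate sets partition the
group; pool tags are pairwise Hamming distance ≥ 2; re-running on the kept
reads marks nothing; permuting the input changes nothing.

Tag comparison is plain character equality, so `N` matches only `N`.
Duplicates keep their records and receive the SAM duplicate flag (0x400);
no read is removed, and unmapped or untaggable reads pass through
unflagged.

One property that might be expected does **not** hold: adding one more
copy of a read can *increase* the number of kept molecules, because the
extra count can flip a ranking tie and change which of two distance-1 tags
anchors the pool (e.g. tags `AC`:2, `AA`:1, `CC`:1 — pool `{AC}`, one
molecule; after duplicating an `AA` read the order starts with `AA`, and
`CC` at distance 2 from `AA` is accepted, two molecules). This is inherent
to greedy rank-order collapsing, not an implementation artifact.

## Quantification

Gene models are read from GTF (exon features; biotype from
`gene_biotype`/`gene_type`/`biotype`, defaulting to `protein_coding`).
Biotypes whose fragments dominate low-input libraries without carrying
expression signal — snRNA, rRNA, tRNA, snoRNA, pseudogene — are masked
before counting. Assignment is union-mode: the genes whose exons overlap
any aligned base (CIGAR M/=/X; skipped introns and deletions excluded) of
a kept read; exactly one gene counts, several is `ambiguous`, none is
`no_feature`, and unique + ambiguous + no_feature equals the kept-read
total per sample. Matching is strand-agnostic by default (library
strandedness is often unknown); a stranded mode is available.

Differential-expression labels are threshold rules applied to externally
fitted (log2FC, adjusted p) pairs — no dispersion model is fitted here.
`up` iff padj < 0.01 and log2FC ≥ 2; `down` iff padj < 0.01 and
log2FC ≤ −2. Fold-change boundaries are inclusive, the significance cut is
strict. Positive log2FC means higher expression in the treatment/tumor
sample; output files state the convention in their header.

## Simulator

`simulate_library` emulates the structure that matters for deduplication:
per position, `molecules_per_position` molecules draw i.i.d. uniform tags
(optionally rejection-sampled to pairwise Hamming distance ≥
`min_tag_distance`, failing loudly if infeasible); each molecule is
amplified into a number of reads given by `pcr_copies`; each read's tag is
copied with independent per-base substitution errors at `umi_error_rate`;
base qualities are i.i.d. normal, rounded and clipped to [2, 41]. Reads
are emitted pre-aligned on one synthetic reference (forward strand,
perfect `<len>M` CIGAR, positions spaced so groups never collide), with
the observed tag as the last `_`-field of the read name. Everything is
drawn from one `numpy` generator, so a fixed seed gives byte-identical
output.

Defaults, chosen once as a realistic regime for a low-input library:
100 positions × 50 molecules; geometric PCR copy number with mean 4
(every molecule sequenced at least once, long right tail, duplicate rate
≈ 0.75); tag error rate 0.005 per base (≈ 4% of 8-mers carry an error,
typical of an index read); PHRED ~ N(35, 5) clipped to [2, 41]; 50 bp
single-end reads.

What the simulator does **not** model: real transcript sequence, fragment-
position jitter (each molecule's copies share one position exactly),
cycle-dependent error profiles, indel errors in the tag (fixed-length
index reads make substitutions the dominant mode), PCR jackpotting beyond
the geometric tail, and strand mixtures. Passing recovery tests therefore
demonstrates the algorithm's correctness under its own model of
amplification and tag error, not end-to-end accuracy on real libraries,
where alignment ambiguity and position jitter add further error modes.

`expected_distinct_tags(m, K) = K·(1 − (1 − 1/K)^m)` gives the expected
number of distinct tags among m uniform draws from a K-tag space (each tag
is missed with probability (1 − 1/K)^m); the simulator's Monte-Carlo mean
is checked against it within three standard errors. With m = 100 and
K = 4⁸ = 65,536 the expectation is ≈ 99.92, i.e. tag collisions cost less
than 0.1% of molecules at these depths.

`evaluate_recovery` scores a dedup result against the truth: per-position
absolute and relative molecule-count error, plus duplicate-marking
precision/recall, where a read is a *true* duplicate iff another read of
its molecule outranks it under the kept-read criterion (higher mean
quality, ties by read id).

## Tumor/control utilities

- **Bin coverage**: reads are counted by 5′ coordinate into non-overlapping
  bins from coordinate 1; the last partial bin is included, so bin totals
  conserve reads. Tracks are normalized by their median (error if the
  median is zero — mask empty bins first) and compared as per-bin
  log2((tumor + c)/(control + c)). The default pseudocount is 0 with ±inf
  and NaN left visible for the caller to mask, since silently shifting
  counts changes copy-number ratios.
- **Somatic candidate filter**: tumor coverage strictly > 14, control
  coverage strictly > 8, allele frequency ≥ 0.1 — the operators are
  deliberately asymmetric (strict vs inclusive) and configurable.
- **Recurrent InDel windows**: each reference is tiled into fixed,
  non-overlapping 10-kb windows from coordinate 1; a window is recurrent
  when every sample has ≥ 1 InDel inside it. Tiling (rather than sliding)
  windows are used: the test is for coarse co-occurrence, and tiling keeps
  the null distribution simple; a recurrent pair split by a tile boundary
  would be missed, which makes the check conservative.

## Percent identity

For one gapped pair (equal-length rows, no double-gap column):
`100 · identical / (aligned + internal gap)` columns, where *aligned*
columns have residues in both rows, *identical* aligned columns match
case-insensitively, and *internal gap* columns contain a gap strictly
between the first and last aligned column. Terminal overhangs are
excluded — they reflect block boundaries, not substitution history — so a
perfect overlap scores 100 regardless of overhang length. Gap runs count
per column, `N`–`N` counts as identical (plain character equality), and
the value is undefined (an error, not 0) when no column aligns.

## Numerical and testing choices

- All orderings in the dedup path are total; no randomization anywhere.
- Mean qualities are compared as floats without rounding.
- The test suite checks the dedup path against an independently written
  brute-force transcription of the procedure on randomized groups
  (4-letter tags over a 2-letter alphabet to force frequent distance-1
  collisions), and the position-key computation against a naive CIGAR
  walk over randomized alignments.
- Problem sizes in tests and in `scripts/acceptance.py` (10,000 oracle
  groups; 200 × 50 clean-recovery library; 1,000-position collision
  calibration) were chosen as the smallest scales at which the properties
  are meaningfully exercised; all complete in seconds.

## Known limitations

- Single-end only; paired-end duplicate marking (mate-aware flags,
  template-end keys) is out of scope.
- No network/directional UMI clustering; the collapse rule is the greedy
  rank-order procedure described above, by design.
- The kept read's sequence is not error-corrected by consensus.
- CRAM is not supported; SAM/BAM only.
- `classify_de` consumes externally computed statistics; it performs no
  count modelling, normalization or multiple-testing correction.
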