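"""Independent straight-line oracle for per-position tag deduplication.

Deliberately written without any imports from the package: plain lists,
stable sorts and an inline mismatch count, transcribing the procedure
step by step (count tags; sort by count descending then alphanumerically;
within a tag sort reads by mean quality then alphanumerically; keep the
top read of each accepted tag; collapse tags within one mismatch of the
accepted pool).
"""

import random


def brute_force_dedup(reads):
    """reads: list of (read_id, tag, mean_quality) -> (kept, dups, pool)."""
    counts = {}
    for _rid, tag, _q in reads:
        counts[tag] = counts.get(tag, 0) + 1

    ordered_tags = sorted(counts.keys())           # alphanumeric first
    ordered_tags.sort(key=lambda t: counts[t], reverse=True)  # stable

    kept = []
    duplicates = []
    pool = []
    for tag in ordered_tags:
        neighbour = None
        for accepted in pool:
            mismatches = 0
            for a, b in zip(tag, accepted):
                if a != b:
                    mismatches += 1
            if mismatches <= 1:
                neighbour = accepted
                break
        tag_reads = [r for r in reads if r[1] == tag]
        tag_reads.sort(key=lambda r: r[0])                      # alphanumeric
        tag_reads.sort(key=lambda r: r[2], reverse=True)        # stable, quality
        if neighbour is None:
            pool.append(tag)
            kept.append(tag_reads[0][0])
            for r in tag_reads[1:]:
                duplicates.append(r[0])
        else:
            for r in tag_reads:
                duplicates.append(r[0])
    return set(kept), set(duplicates), pool


def random_group(rng: random.Random, max_reads=30, tag_length=4, alphabet="AC"):
    """A random small position group as (read_id, tag, quality) triples."""
    n = rng.randint(1, max_reads)
    reads = []
    for i in range(n):
        tag = "".join(rng.choice(alphabet) for _ in range(tag_length))
        quality = rng.choice([10.0, 20.0, 30.0, rng.uniform(2, 41)])
        reads.append((f"r{i:03d}", tag, quality))
    return reads
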