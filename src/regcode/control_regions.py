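"""Mappability masking and size-preserving random control regions.

Short-read mappability is approximated at desk scale by exact k-mer
uniqueness: the genome is tiled into non-overlapping k-bp bins and a bin
is mappable iff its sequence occurs exactly once genome-wide considering
both strands and contains no N. Controls are then drawn uniformly over
all start positions that keep each shuffled interval entirely inside a
mappable run, preserving the count and the exact length multiset of the
input set (the semantics of shuffling peaks within an include-mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    IntervalSet,
    merge,
    reverse_complement,
)


@dataclass
class MappabilityMask:
    """Merged, disjoint mappable intervals produced from k-bp bins."""

    mappable: IntervalSet
    k: int
    genome_id: str = ""

    def runs(self) -> list[GenomicInterval]:
        return list(self.mappable)

    def max_run_length(self) -> int:
        return max((iv.length for iv in self.mappable), default=0)


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def mappability_mask(genome: GenomeSequence, k: int = 150) -> MappabilityMask:
    """Tile the genome into non-overlapping k-bp bins and keep unique ones.

    The final sub-k remainder of each chromosome is dropped. A bin is
    mappable iff it contains no N and its sequence, counted over every
    position of the genome on both strands, occurs exactly once (the bin
    itself). Adjacent mappable bins are merged into runs.
    """
    if k < 20:
        raise ValueError("k must be >= 20")
    if not genome.sequences:
        raise ValueError("genome is empty")
    if all(len(s) < k for s in genome.sequences.values()):
        raise ValueError(f"k={k} exceeds every chromosome length")
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            key = _canonical(seq[i : i + k])
            counts[key] = counts.get(key, 0) + 1
    bins = []
    for chrom in genome.chroms():
        seq = genome.sequences[chrom]
        for b in range(len(seq) // k):
            s = seq[b * k : (b + 1) * k]
            if "N" in s:
                continue
            if counts.get(_canonical(s), 0) == 1:
                bins.append(GenomicInterval(chrom, b * k, (b + 1) * k))
    if not bins:
        return MappabilityMask(IntervalSet([], genome.genome_id), k, genome.genome_id)
    # adjacent bins are book-ended; merge via a 1 bp-overlap trick on
    # half-open coordinates by extending ends, then trimming back
    extended = IntervalSet(
        [GenomicInterval(iv.chrom, iv.start, iv.end + 1) for iv in bins],
        genome.genome_id,
    )
    merged = merge(extended)
    trimmed = IntervalSet(
        [GenomicInterval(iv.chrom, iv.start, iv.end - 1) for iv in merged],
        genome.genome_id,
        "mappable",
    )
    return MappabilityMask(trimmed, k, genome.genome_id)


def shuffle_controls(
    intervals: IntervalSet,
    mask: MappabilityMask,
    seed: int,
    allow_overlap: bool = True,
    max_attempts: int = 1000,
) -> IntervalSet:
    """Random size-preserving controls entirely within the mappable mask.

    Each input interval is re-placed uniformly over every valid start
    position (any mask run long enough to contain it, any offset);
    strand, name and score are preserved. Deterministic given ``seed``.
    With ``allow_overlap=False``, placements colliding with an earlier
    control are rejected and redrawn up to ``max_attempts`` times.
    """
    rng = np.random.default_rng(seed)
    runs = sorted(mask.mappable, key=lambda iv: (iv.chrom, iv.start))
    run_len = np.array([iv.length for iv in runs], dtype=np.int64)
    placed: dict[str, list[tuple[int, int]]] = {}
    out = []
    for iv in intervals:
        L = iv.length
        slots = run_len - L + 1
        valid = slots > 0
        if not valid.any():
            raise ValueError(
                f"interval {iv.name or iv.chrom}:{iv.start}-{iv.end} of length {L} "
                "exceeds the longest mappable run"
            )
        weights = np.where(valid, slots, 0).astype(np.float64)
        probs = weights / weights.sum()
        for attempt in range(max_attempts):
            ri = int(rng.choice(len(runs), p=probs))
            off = int(rng.integers(0, slots[ri]))
            run = runs[ri]
            s = run.start + off
            e = s + L
            if not allow_overlap:
                clash = any(
                    s < pe and e > ps for ps, pe in placed.get(run.chrom, [])
                )
                if clash:
                    continue
                placed.setdefault(run.chrom, []).append((s, e))
            out.append(GenomicInterval(run.chrom, s, e, iv.strand, iv.name, iv.score))
            break
        else:
            raise ValueError(
                f"could not place interval {iv.name or iv.chrom}:{iv.start}-{iv.end} "
                f"after {max_attempts} attempts"
            )
    return IntervalSet(out, mask.genome_id, intervals.label + ":shuffled" if intervals.label else "shuffled")
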