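"""Peak reproducibility filtering, local/distal partitioning, feature
annotation and multi-sample intersection tables.

The reproducibility rule mirrors the standard pseudo-replicate scheme for
ChIP-seq: reads of the merged replicates are randomly split in two, peaks
are called on the merged sample and on each half, and only merged-sample
peaks recovered in *both* halves are kept. Read splitting and peak
calling happen upstream; this module implements the selection rule on the
three resulting peak sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, IntervalSet, intersect, merge, nearest_distance

DISTANCE_BINS = ("genic", "<2kb", "2-10kb", "10-100kb", ">100kb")

FEATURE_GENE = "gene"
FEATURE_INTERGENIC_NEAR = "intergenic<=2kb"
FEATURE_INTERGENIC_FAR = "intergenic>2kb"


def reproducible_peaks(
    merged: IntervalSet, pseudo1: IntervalSet, pseudo2: IntervalSet
) -> IntervalSet:
    """Merged-sample peaks overlapping (>=1 bp) a peak in both pseudo-replicates.

    Names and scores of the merged peaks are preserved; an empty merged
    set yields an empty result.
    """
    if len(merged) == 0:
        return IntervalSet([], merged.genome_id, merged.label)
    keep = np.ones(len(merged), dtype=bool)
    for pseudo in (pseudo1, pseudo2):
        if len(pseudo) == 0:
            keep[:] = False
            break
        flags, _ = intersect(merged, pseudo, min_bp=1)
        keep &= flags
    return IntervalSet(
        [iv for iv, k in zip(merged, keep) if k], merged.genome_id, merged.label
    )


def partition_local_distal(
    peaks: IntervalSet, genes: IntervalSet, threshold_bp: int = 2000
) -> tuple[IntervalSet, IntervalSet]:
    """Split peaks into (local, distal) by edge-gap distance to the nearest gene.

    A peak at least ``threshold_bp`` away from every gene (inclusive, so a
    peak exactly at the threshold is distal) goes to the distal set; peaks
    overlapping or closer than the threshold are local. The partition is
    exhaustive and disjoint.
    """
    if threshold_bp < 0:
        raise ValueError("threshold_bp must be >= 0")
    dist = nearest_distance(peaks, genes)
    local = [iv for iv, d in zip(peaks, dist) if d < threshold_bp]
    distal = [iv for iv, d in zip(peaks, dist) if d >= threshold_bp]
    return (
        IntervalSet(local, peaks.genome_id, peaks.label + ":local" if peaks.label else "local"),
        IntervalSet(distal, peaks.genome_id, peaks.label + ":distal" if peaks.label else "distal"),
    )


def annotate_features(
    intervals: IntervalSet,
    genes: IntervalSet,
    tes: IntervalSet,
    near_bp: int = 2000,
) -> list[str]:
    """One feature label per interval, by priority.

    gene overlap > TE family overlap (largest overlap wins, lexicographic
    family name on ties; the family is the TE interval's ``name``) >
    intergenic within ``near_bp`` of a gene > intergenic beyond. TE labels
    are rendered ``TE:<family>``.
    """
    labels = [""] * len(intervals)
    if len(genes):
        gflags, _ = intersect(intervals, genes, min_bp=1)
        gdist = nearest_distance(intervals, genes)
    else:
        gflags = np.zeros(len(intervals), dtype=bool)
        gdist = np.full(len(intervals), np.inf)
    te_best: dict[int, tuple[int, str]] = {}
    if len(tes):
        _, pairs = intersect(intervals, tes, min_bp=1)
        for ai, ti in pairs:
            iv, te = intervals[ai], tes[ti]
            ov = min(iv.end, te.end) - max(iv.start, te.start)
            fam = te.name or "TE"
            prev = te_best.get(ai)
            # largest overlap wins; lexicographically smaller family on ties
            if prev is None or (-ov, fam) < (-prev[0], prev[1]):
                te_best[ai] = (ov, fam)
    for i in range(len(intervals)):
        if gflags[i]:
            labels[i] = FEATURE_GENE
        elif i in te_best:
            labels[i] = f"TE:{te_best[i][1]}"
        elif gdist[i] <= near_bp:
            labels[i] = FEATURE_INTERGENIC_NEAR
        else:
            labels[i] = FEATURE_INTERGENIC_FAR
    return labels


def distance_bin(d: float) -> str:
    """Histogram bin for a peak-to-gene edge distance."""
    if d == 0:
        return "genic"
    if d < 2_000:
        return "<2kb"
    if d < 10_000:
        return "2-10kb"
    if d < 100_000:
        return "10-100kb"
    return ">100kb"


@dataclass
class PeakSample:
    """A labelled peak set (mark or assay, tissue, inbred)."""

    label: str
    peaks: IntervalSet


@dataclass
class IntersectionTable:
    """Upset-style summary over merged union regions.

    ``rows`` has one row per unique membership vector with the merged
    region count plus feature-composition and distance-bin counts;
    ``regions`` retains the per-region assignment.
    """

    rows: pd.DataFrame
    regions: pd.DataFrame
    sample_labels: list[str]

    @property
    def total_regions(self) -> int:
        return int(self.regions.shape[0])


def intersection_matrix(
    samples: list[PeakSample],
    genes: IntervalSet,
    tes: IntervalSet,
) -> IntersectionTable:
    """Membership of merged union regions across samples (upset semantics).

    All peaks are pooled and merged by single-linkage >=1 bp overlap; a
    sample is a member of a region iff one of its peaks overlaps it. Rows
    aggregate regions per unique membership vector, with feature labels
    from :func:`annotate_features` and distance bins to the nearest gene.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("sample labels must be unique")
    pooled = IntervalSet(
        [iv for s in samples for iv in s.peaks],
        genome_id=samples[0].peaks.genome_id,
    )
    if len(pooled) == 0:
        empty = pd.DataFrame(columns=["membership", "count"])
        return IntersectionTable(empty, empty, labels)
    regions = merge(pooled)
    member = np.zeros((len(regions), len(samples)), dtype=bool)
    for j, s in enumerate(samples):
        if len(s.peaks):
            flags, _ = intersect(regions, s.peaks, min_bp=1)
            member[:, j] = flags
    feats = annotate_features(regions, genes, tes)
    if len(genes):
        bins = [distance_bin(d) for d in nearest_distance(regions, genes)]
    else:
        bins = [">100kb"] * len(regions)
    regions_df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "membership": ["&".join(l for l, m in zip(labels, row) if m) for row in member],
            "feature": feats,
            "distance_bin": bins,
        }
    )
    rows = []
    for key, sub in regions_df.groupby("membership", sort=True):
        row = {"membership": key, "count": len(sub)}
        for f, n in sub["feature"].value_counts().items():
            row[f"feature:{f}"] = int(n)
        for b in DISTANCE_BINS:
            row[f"dist:{b}"] = int((sub["distance_bin"] == b).sum())
        rows.append(row)
    rows_df = pd.DataFrame(rows).fillna(0)
    count_cols = [c for c in rows_df.columns if c != "membership"]
    rows_df[count_cols] = rows_df[count_cols].astype(int)
    return IntersectionTable(rows_df, regions_df, labels)
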