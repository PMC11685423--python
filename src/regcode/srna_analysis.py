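"""Small-RNA size distributions, cluster strand bias / hairpin-like
flagging, and telomere repeat counting.

Hairpin flagging is a deliberate heuristic without RNA folding:
kilobase-scale loci producing strongly strand-biased, 22nt-dominant
siRNAs are the operational signature of long inverted-repeat
("proto-miRNA") precursors processed by DCL2; every threshold is a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeSequence, GenomicInterval, IntervalSet, reverse_complement

SRNA_COLUMNS = ("chrom", "start", "end", "strand", "length", "count")


@dataclass
class SRnaReadTable:
    """Collapsed small-RNA alignments plus the library size.

    ``reads`` columns: chrom, start, end, strand (+/-), length (nt,
    equal to end - start) and count (collapsed read multiplicity).
    """

    reads: pd.DataFrame
    library_size: int

    def __post_init__(self) -> None:
        df = self.reads
        if not (df["end"] - df["start"] == df["length"]).all():
            raise ValueError("length must equal end - start")
        if (df["count"] < 1).any():
            raise ValueError("counts must be >= 1")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")


def size_distribution(
    reads: SRnaReadTable, lengths: range = range(18, 29)
) -> pd.Series:
    """Counts per million mapped reads (CPM) for each read length."""
    if reads.library_size <= 0:
        raise ValueError("library_size must be positive")
    by_len = reads.reads.groupby("length")["count"].sum()
    cpm = pd.Series(
        {L: 1e6 * float(by_len.get(L, 0)) / reads.library_size for L in lengths},
        name="cpm",
    )
    cpm.index.name = "length"
    return cpm


@dataclass
class ClusterFlags:
    cluster: GenomicInterval
    strand_bias: float  # max(plus, minus) / total over 20-24nt reads; NaN if none
    dominant_length: int | None
    frac_22nt: float
    hairpin_like: bool | None  # None when no 20-24nt reads (undefined)


def hairpin_flags(
    clusters: IntervalSet,
    reads: SRnaReadTable,
    min_len_bp: int = 1000,
    min_bias: float = 0.8,
    min_22nt_frac: float = 0.5,
    sirna_lengths: tuple[int, int] = (20, 24),
) -> list[ClusterFlags]:
    """Per-cluster strand bias, dominant length and hairpin-like flag.

    A cluster is hairpin-like iff it spans at least ``min_len_bp``, its
    20-24nt reads are at least ``min_bias`` on one strand, and 22nt reads
    make up at least ``min_22nt_frac`` of its 20-24nt reads. Clusters
    with no 20-24nt reads get undefined (None/NaN) flags.
    """
    df = reads.reads
    out = []
    for cl in clusters:
        in_cl = df[
            (df["chrom"] == cl.chrom) & (df["start"] < cl.end) & (df["end"] > cl.start)
        ]
        sirna = in_cl[in_cl["length"].between(*sirna_lengths)]
        total = int(sirna["count"].sum())
        if total == 0:
            out.append(ClusterFlags(cl, float("nan"), None, float("nan"), None))
            continue
        plus = int(sirna.loc[sirna["strand"] == "+", "count"].sum())
        bias = max(plus, total - plus) / total
        per_len = in_cl.groupby("length")["count"].sum()
        dominant = int(per_len.idxmax())
        frac22 = float(sirna.loc[sirna["length"] == 22, "count"].sum()) / total
        hairpin = (
            cl.length >= min_len_bp and bias >= min_bias and frac22 >= min_22nt_frac
        )
        out.append(ClusterFlags(cl, bias, dominant, frac22, bool(hairpin)))
    return out


def _count_nonoverlapping(seq: str, motif: str) -> int:
    """Greedy left-to-right non-overlapping occurrence count."""
    return seq.count(motif)


def telomere_repeat_count(
    genome: GenomeSequence,
    motif: str = "CCCTAAA",
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Telomere-repeat copies in each chromosome-end window.

    Counts non-overlapping occurrences of ``motif`` in the first
    ``window_bp`` bases and of its reverse complement in the last
    ``window_bp`` bases of every chromosome (windows are truncated on
    chromosomes shorter than the window). Copy numbers counted this way
    bound the true telomere length from below — assemblies rarely carry
    complete telomere tracts — so the per-window counts are reported as
    such, never as a telomere-length estimate.
    """
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    if window_bp < len(motif):
        raise ValueError("window_bp must be at least the motif length")
    rc = reverse_complement(motif)
    rows = []
    for chrom in genome.chroms():
        seq = genome.sequences[chrom]
        w = min(window_bp, len(seq))
        five = _count_nonoverlapping(seq[:w], motif)
        three = _count_nonoverlapping(seq[-w:], rc)
        rows.append(
            {
                "chrom": chrom,
                "five_prime": five,
                "three_prime": three,
                "total": five + three,
                "window_bp": w,
                "truncated": w < window_bp,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
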