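"""Six-class enhancer classification and orthogonal evidence layers.

Distal H3K27ac peaks are classified on two axes: whether an H3K4me1 peak
(a gene-body mark in plants, hence a proxy for an unannotated gene) lies
within a window of the peak, and whether strand-resolved RNA coverage
supports transcription on both strands (bidirectional), one strand
(unidirectional) or neither. The cross gives six classes; peaks with
H3K4me1 are interpreted as misannotated genes, peaks without it and with
bidirectional non-coding RNA as the strongest enhancer candidates.

Evidence layers attached to each record: transcription-factor binding
sites, 5'-capped transcription (RAMPAGE-style signal, re-using the same
strand-call logic at its own threshold), reporter-assay activity
(STARR-seq-like track), chromatin-loop linkage to genes, and conserved
non-coding elements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    GenomicInterval,
    IntervalSet,
    LoopSet,
    StrandedSignal,
    intersect,
    nearest_distance,
)

EXPRESSION_CLASSES = ("bidirectional", "unidirectional", "none")

#: Canonical order of the six class labels.
CLASS_LABELS = tuple(
    f"{k4}:{expr}"
    for k4 in ("K4me1+", "K4me1-")
    for expr in EXPRESSION_CLASSES
)

#: Sentinel for a fraction over an empty class (distinguishable from 0).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ExpressionCall:
    """Per-strand transcription evidence within a peak.

    ``plus_reads``/``minus_reads`` are estimated read counts (coverage
    area divided by read length); ``call`` thresholds each strand.
    """

    call: str  # both_strands | plus_only | minus_only | none
    plus_reads: float
    minus_reads: float

    @property
    def collapsed(self) -> str:
        """Collapse plus_only/minus_only to "unidirectional" (the only
        lossy step; the raw per-strand evidence stays on the record)."""
        if self.call == "both_strands":
            return "bidirectional"
        if self.call in ("plus_only", "minus_only"):
            return "unidirectional"
        return "none"


def strand_expression_call(
    peak: GenomicInterval, signal: StrandedSignal, min_reads: float = 5.0
) -> ExpressionCall:
    """Call transcription from stranded coverage over a peak.

    Evidence per strand is the coverage area over the peak divided by the
    library read length — an estimated read count. A strand is expressed
    iff its evidence reaches ``min_reads``.
    """
    if signal.read_length <= 0:
        raise ValueError("read_length must be positive")
    plus = signal.sum_over(peak, "+") / signal.read_length
    minus = signal.sum_over(peak, "-") / signal.read_length
    p, m = plus >= min_reads, minus >= min_reads
    call = (
        "both_strands" if p and m else "plus_only" if p else "minus_only" if m else "none"
    )
    return ExpressionCall(call, plus, minus)


@dataclass
class EnhancerRecord:
    """A distal H3K27ac peak with its class label and evidence fields."""

    interval: GenomicInterval
    k4me1_within_window: bool
    expression: ExpressionCall
    tfbs_hit: bool | None = None
    capped_call: ExpressionCall | None = None
    activity_summary: tuple[float, float, float] | None = None  # (max, mean, median)
    in_loop: bool = False
    between_anchors: bool = False
    linked_genes: list[str] = field(default_factory=list)
    conserved_element_count: int | None = None

    @property
    def class_label(self) -> str:
        k4 = "K4me1+" if self.k4me1_within_window else "K4me1-"
        return f"{k4}:{self.expression.collapsed}"


def classify_enhancers(
    distal_peaks: IntervalSet,
    k4me1_peaks: IntervalSet,
    rna: StrandedSignal,
    window_bp: int = 1000,
    min_reads: float = 5.0,
) -> list[EnhancerRecord]:
    """Assign each distal peak to one of the six classes.

    H3K4me1 proximity is an edge-gap of at most ``window_bp`` (overlap
    counts), accommodating the offset between a TSS within the peak and
    the marked gene body. Every input peak yields exactly one record.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if len(k4me1_peaks):
        dist = nearest_distance(distal_peaks, k4me1_peaks)
    else:
        dist = np.full(len(distal_peaks), np.inf)
    records = []
    for iv, d in zip(distal_peaks, dist):
        expr = strand_expression_call(iv, rna, min_reads=min_reads)
        records.append(EnhancerRecord(iv, bool(d <= window_bp), expr))
    return records


def class_counts(records: list[EnhancerRecord]) -> dict[str, int]:
    out = {label: 0 for label in CLASS_LABELS}
    for r in records:
        out[r.class_label] += 1
    return out


def evidence_fractions(
    records: list[EnhancerRecord],
    tfbs_sets: list[IntervalSet],
    rampage: StrandedSignal,
    rampage_min_reads: float = 2.0,
) -> pd.DataFrame:
    """Per-class TFBS and capped-RNA evidence fractions.

    Sets ``tfbs_hit`` (>=1 bp overlap with the union of the TF binding
    site sets) and ``capped_call`` (strand call on the capped-RNA track at
    its own, shallower threshold) on every record, then aggregates per
    class: fraction with a TFBS and fractions whose capped call is
    bidirectional / one strand / none. Empty classes report NaN, not 0.
    """
    peaks = IntervalSet([r.interval for r in records])
    hit = np.zeros(len(records), dtype=bool)
    for tf in tfbs_sets:
        if len(tf):
            flags, _ = intersect(peaks, tf, min_bp=1)
            hit |= flags
    for r, h in zip(records, hit):
        r.tfbs_hit = bool(h)
        r.capped_call = strand_expression_call(r.interval, rampage, rampage_min_reads)
    rows = []
    for label in CLASS_LABELS:
        sub = [r for r in records if r.class_label == label]
        n = len(sub)
        if n == 0:
            rows.append(
                {
                    "class": label,
                    "n": 0,
                    "tfbs_fraction": UNDEFINED,
                    "capped_bidirectional": UNDEFINED,
                    "capped_one_strand": UNDEFINED,
                    "capped_none": UNDEFINED,
                }
            )
            continue
        calls = [r.capped_call.collapsed for r in sub]
        rows.append(
            {
                "class": label,
                "n": n,
                "tfbs_fraction": sum(r.tfbs_hit for r in sub) / n,
                "capped_bidirectional": calls.count("bidirectional") / n,
                "capped_one_strand": calls.count("unidirectional") / n,
                "capped_none": calls.count("none") / n,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def welch_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances). Returns (t, p)."""
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ActivityComparison:
    """Per-class activity distributions with pairwise Welch tests."""

    summary: str
    values: dict[str, np.ndarray]
    pairwise: pd.DataFrame  # class_a, class_b, t, p


def activity_compare(
    records: list[EnhancerRecord],
    activity: StrandedSignal,
    summary: str = "median",
) -> ActivityComparison:
    """Summarize activity signal within each record and compare classes.

    Each record gets its (max, mean, median) of per-bp activity over the
    interval; the chosen summary feeds two-sided Welch t-tests between
    every pair of non-empty classes. Full distributions are retained.
    """
    if summary not in ("max", "mean", "median"):
        raise ValueError("summary must be max, mean or median")
    per_class: dict[str, list[float]] = {}
    for r in records:
        vals = activity.values(r.interval.chrom, r.interval.start, r.interval.end)
        summ = (float(vals.max()), float(vals.mean()), float(np.median(vals)))
        r.activity_summary = summ
        chosen = {"max": summ[0], "mean": summ[1], "median": summ[2]}[summary]
        per_class.setdefault(r.class_label, []).append(chosen)
    values = {k: np.asarray(v) for k, v in per_class.items()}
    rows = []
    present = [c for c in CLASS_LABELS if c in values]
    for a, b in itertools.combinations(present, 2):
        xa, xb = values[a], values[b]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"class {a if len(xa) < 2 else b} has n < 2")
        if xa.std() == 0 and xb.std() == 0 and float(xa.mean()) == float(xb.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = welch_ttest(xa, xb)
        rows.append({"class_a": a, "class_b": b, "t": t, "p": p})
    return ActivityComparison(summary, values, pd.DataFrame(rows))


@dataclass
class LoopLinkResult:
    """Loop membership plus linked-gene expression comparison.

    ``linked_log2`` are log2(RPKM + 0.1) values of loop-linked genes;
    the two comparisons draw, with a fixed seed, (a) uniformly random
    genes and (b) random genes overlapping any loop anchor, each of the
    linked-set size, ``n_draws`` times; the Welch test uses the first
    draw and the medians over draws are reported.
    """

    n_in_loop: int
    n_between: int
    linked_genes: list[str]
    linked_log2: np.ndarray
    random_median: float | None = None
    random_in_loop_median: float | None = None
    welch_vs_random: tuple[float, float] | None = None
    welch_vs_random_in_loop: tuple[float, float] | None = None
    note: str = ""


def loop_link(
    records: list[EnhancerRecord],
    loops: LoopSet,
    genes: IntervalSet,
    expression: pd.Series,
    seed: int = 0,
    n_draws: int = 100,
    pseudocount: float = 0.1,
) -> LoopLinkResult:
    """Attach chromatin-loop evidence and compare linked-gene expression.

    A record is ``in_loop`` iff it overlaps either anchor of at least one
    loop; its linked genes are the genes (by ``name``) overlapping the
    opposite anchor of any such loop. ``between_anchors`` additionally
    reports records lying strictly between the two anchors of a loop,
    since "in a loop" is ambiguous between the two readings.
    ``expression`` maps gene name -> RPKM.
    """
    if len(loops) == 0:
        for r in records:
            r.in_loop = False
            r.linked_genes = []
        return LoopLinkResult(
            0, 0, [], np.array([]), note="empty loop set; comparison skipped"
        )
    peaks = IntervalSet([r.interval for r in records])
    left = IntervalSet([a for a, _ in loops])
    right = IntervalSet([b for _, b in loops])
    _, lp = intersect(peaks, left, min_bp=1)
    _, rp = intersect(peaks, right, min_bp=1)
    # genes overlapping each anchor, keyed by loop index
    genes_at: dict[tuple[int, str], list[str]] = {}
    for side, anchor_set in (("L", left), ("R", right)):
        _, pairs = intersect(genes, anchor_set, min_bp=1)
        for gi, li in pairs:
            genes_at.setdefault((li, side), []).append(genes[gi].name)
    hits: dict[int, set[str]] = {}
    for ri, li in lp:
        hits.setdefault(ri, set()).update(genes_at.get((li, "R"), []))
    for ri, li in rp:
        hits.setdefault(ri, set()).update(genes_at.get((li, "L"), []))
    n_between = 0
    spans = IntervalSet(
        [
            GenomicInterval(a.chrom, a.end, b.start)
            for a, b in loops
            if a.chrom == b.chrom and a.end < b.start
        ]
    )
    if len(spans):
        between_flags, _ = intersect(peaks, spans, min_bp=1)
    else:
        between_flags = np.zeros(len(records), dtype=bool)
    for i, r in enumerate(records):
        r.in_loop = i in hits
        r.linked_genes = sorted(hits.get(i, set()))
        r.between_anchors = bool(between_flags[i])
        if r.between_anchors:
            n_between += 1
    linked = sorted(set().union(*hits.values())) if hits else []

    def log2(gene_names):
        vals = expression.reindex(list(gene_names)).dropna().to_numpy(float)
        return np.log2(vals + pseudocount)

    linked_vals = log2(linked)
    result = LoopLinkResult(
        n_in_loop=sum(1 for r in records if r.in_loop),
        n_between=n_between,
        linked_genes=linked,
        linked_log2=linked_vals,
    )
    if not linked:
        result.note = "no linked genes; comparison skipped"
        return result
    rng = np.random.default_rng(seed)
    universe = expression.index.to_numpy()
    anchor_genes = np.array(
        sorted({g for lst in genes_at.values() for g in lst if g in expression.index})
    )
    for attr, pool in (("random", universe), ("random_in_loop", anchor_genes)):
        if len(pool) == 0:
            continue
        draws = [
            log2(list(rng.choice(pool, size=len(linked), replace=len(pool) < len(linked))))
            for _ in range(n_draws)
        ]
        medians = [float(np.median(d)) for d in draws]
        setattr(result, f"{attr}_median", float(np.median(medians)))
        t, p = welch_ttest(linked_vals, draws[0])
        setattr(result, f"welch_vs_{attr}", (t, p))
    return result


def conservation_profile(
    records: list[EnhancerRecord], conserved: IntervalSet
) -> pd.DataFrame:
    """Count conserved elements (>=1 bp overlap) per record; per-class
    fractions with >=1 and with >=10 elements plus the mean count."""
    peaks = IntervalSet([r.interval for r in records])
    counts = np.zeros(len(records), dtype=int)
    if len(conserved):
        _, pairs = intersect(peaks, conserved, min_bp=1)
        for ai, _ in pairs:
            counts[ai] += 1
    for r, c in zip(records, counts):
        r.conserved_element_count = int(c)
    rows = []
    for label in CLASS_LABELS:
        sub = [c for r, c in zip(records, counts) if r.class_label == label]
        n = len(sub)
        rows.append(
            {
                "class": label,
                "n": n,
                "frac_ge1": (sum(c >= 1 for c in sub) / n) if n else UNDEFINED,
                "frac_ge10": (sum(c >= 10 for c in sub) / n) if n else UNDEFINED,
                "mean_count": (float(np.mean(sub)) if n else UNDEFINED),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def records_to_dataframe(records: list[EnhancerRecord]) -> pd.DataFrame:
    """Flat one-row-per-record table (the TSV the CLI writes)."""
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "name": r.interval.name,
                "class": r.class_label,
                "k4me1_within_window": r.k4me1_within_window,
                "rna_call": r.expression.call,
                "rna_plus_reads": r.expression.plus_reads,
                "rna_minus_reads": r.expression.minus_reads,
                "tfbs_hit": r.tfbs_hit,
                "capped_call": r.capped_call.call if r.capped_call else None,
                "activity_max": r.activity_summary[0] if r.activity_summary else None,
                "activity_mean": r.activity_summary[1] if r.activity_summary else None,
                "activity_median": r.activity_summary[2] if r.activity_summary else None,
                "in_loop": r.in_loop,
                "between_anchors": r.between_anchors,
                "linked_genes": ",".join(r.linked_genes),
                "conserved_element_count": r.conserved_element_count,
            }
        )
    return pd.DataFrame(rows)
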