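"""Synthetic data bundle with planted truth for every pipeline stage.

The generator emulates the statistical structure of a plant regulatory
epigenomics study — distal H3K27ac peaks with a planted six-class
structure (H3K4me1 proximity x strand-resolved transcription), stranded
RNA and capped-RNA coverage realizing planted per-strand read counts,
24nt-siRNA coverage enriched at enhancer boundaries, a reporter-activity
track with class-dependent means, chromatin loops wiring enhancers to
genes with shifted expression, pairwise differential-expression tables
with planted tissue-specific genes, a reference-to-inbred orthology map
with a planted conservation rate, collapsed small-RNA reads with planted
size/strand mixtures, and telomeric repeat runs at chromosome ends.

The genome background is i.i.d. uniform A/C/G/T (scrubbed of the
telomere motif outside the planted runs), so long k-mer collisions are
negligible and the mappable space is controllable. Coverage tracks are
idealized read pileups — uniform coverage of ``count * read_length /
length`` across a locus — because the pipeline consumes coverage, not
reads. Planted marginals are exact wherever the configuration states a
count, and sampled wherever it states a probability.

Each chromosome is laid out in fixed-size slots; a slot carries (at
configurable zones) one gene, optionally one enhancer with its evidence,
one TE, one sRNA cluster and background sRNA reads, keeping every
enhancer at least 2 kb from every gene by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .control_regions import MappabilityMask
from .enhancer_classification import CLASS_LABELS
from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    IntervalSet,
    LoopSet,
    StrandedSignal,
    reverse_complement,
    write_intervals,
    write_loops,
)
from .srna_analysis import SRnaReadTable

# slot-internal zone offsets (bp from slot start)
_ENH_OFFSET = 5_000
_CLUSTER_OFFSET = 9_500
_TE_OFFSET = 13_000
_TE_LEN = 800
_BG_SRNA_ZONE = (14_200, 15_600)
_GENE_OFFSET = 16_000
_END_MARGIN = 6_000


def _default_class_counts() -> dict[str, int]:
    return {label: 100 for label in CLASS_LABELS}


def _default_boundary_factor() -> dict[str, float]:
    return {"bidirectional": 3.0, "unidirectional": 2.0, "none": 1.5}


def _default_tfbs_rate() -> dict[str, float]:
    return {
        "K4me1-:bidirectional": 0.6,
        "K4me1-:unidirectional": 0.4,
        "K4me1-:none": 0.2,
        "K4me1+:bidirectional": 0.35,
        "K4me1+:unidirectional": 0.3,
        "K4me1+:none": 0.25,
    }


def _default_capped_rate() -> dict[str, float]:
    return {
        "K4me1-:bidirectional": 0.5,
        "K4me1-:unidirectional": 0.2,
        "K4me1-:none": 0.05,
        "K4me1+:bidirectional": 0.5,
        "K4me1+:unidirectional": 0.2,
        "K4me1+:none": 0.05,
    }


def _default_activity_mean() -> dict[str, float]:
    return {"bidirectional": 3.0, "unidirectional": 2.0, "none": 1.0}


def _default_conserved_rate() -> dict[str, float]:
    return {
        "K4me1-:bidirectional": 0.45,
        "K4me1-:unidirectional": 0.3,
        "K4me1-:none": 0.15,
        "K4me1+:bidirectional": 0.5,
        "K4me1+:unidirectional": 0.45,
        "K4me1+:none": 0.4,
    }


def _default_deg_counts() -> dict[str, tuple[int, int]]:
    # (up, down) tissue-specific genes per tissue; pollen dominates and
    # the coleoptilar node has down-regulated genes only
    return {
        "pollen": (150, 100),
        "ear": (26, 19),
        "root": (40, 40),
        "endosperm": (60, 60),
        "CN": (0, 21),
    }


def _default_srna_totals() -> dict[int, int]:
    # genome-wide planted 21:22:24 = 1:3:6 mixture, exact totals
    return {21: 5_000, 22: 15_000, 24: 30_000}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    n_chroms: int = 2
    slot_bp: int = 20_000
    chrom_length: int | None = None  # auto-sized from content when None
    telomere_motif: str = "CCCTAAA"
    telomere_copies: int = 40
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    enhancer_length_range: tuple[int, int] = (1_200, 2_000)
    expressed_read_range: tuple[float, float] = (15.0, 25.0)
    rna_read_length: int = 150
    boundary_factor: dict[str, float] = field(default_factory=_default_boundary_factor)
    boundary_halfwidth: int = 500
    srna24_background: float = 1.0  # total over both strands
    tfbs_rate: dict[str, float] = field(default_factory=_default_tfbs_rate)
    capped_rate: dict[str, float] = field(default_factory=_default_capped_rate)
    capped_read_count: float = 10.0
    rampage_read_length: int = 50
    activity_mean: dict[str, float] = field(default_factory=_default_activity_mean)
    activity_sd: float = 0.5
    n_extra_gene_slots: int = 200
    gene_length: int = 2_000
    n_local_peaks: int = 150
    n_tes: int = 100
    te_families: tuple[str, ...] = ("LTR", "LINE", "SINE", "DNA")
    n_loops: int = 300
    loop_expression_shift: float = 1.5  # log2 units
    tissues: tuple[str, ...] = ("pollen", "ear", "root", "endosperm", "CN")
    deg_counts: dict[str, tuple[int, int]] = field(default_factory=_default_deg_counts)
    n_distractor_genes: int = 100
    expression_log2_mean: float = 3.0
    expression_log2_sd: float = 2.0
    deg_log2fc: float = 4.0
    n_ref_degs: int = 2_000
    conservation_probability: float = 0.6
    no_homolog_probability: float = 0.1
    target_inbreds: tuple[str, ...] = ("B73", "W22", "NC350")
    n_target_extra_degs: int = 500
    conserved_rate: dict[str, float] = field(default_factory=_default_conserved_rate)
    conserved_high_count_prob: float = 0.2  # K4me1+ classes: chance of >=10 elements
    conserved_element_len: int = 30
    n_srna_clusters: int = 50
    n_hairpin_clusters: int = 10
    hairpin_span: int = 3_000
    hairpin_bias: float = 0.95
    srna_totals: dict[int, int] = field(default_factory=_default_srna_totals)
    mask_bin: int = 150

    def validate(self) -> None:
        counts = [
            self.telomere_copies, self.n_extra_gene_slots, self.n_tes, self.n_loops,
            self.n_ref_degs, self.n_srna_clusters, self.n_hairpin_clusters,
            self.n_local_peaks, *self.class_counts.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        probs = [
            self.conservation_probability, self.no_homolog_probability,
            self.conserved_high_count_prob, self.hairpin_bias,
            *self.tfbs_rate.values(), *self.capped_rate.values(),
            *self.conserved_rate.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if set(self.class_counts) != set(CLASS_LABELS):
            raise ValueError("class_counts must cover exactly the six class labels")
        if self.n_hairpin_clusters > self.n_srna_clusters:
            raise ValueError("n_hairpin_clusters exceeds n_srna_clusters")


@dataclass
class TruthTable:
    """Planted labels for every generated entity (the test oracle)."""

    enhancers: pd.DataFrame
    genes: pd.DataFrame
    local_peaks: pd.DataFrame
    tissue_specific: dict[str, dict[str, set[str]]]  # tissue -> up/down -> genes
    conservation: pd.DataFrame  # gene, inbred, status
    clusters: pd.DataFrame
    telomere_copies: int
    srna_totals: dict[int, int]

    def write(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        self.enhancers.to_csv(outdir / "truth_enhancers.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.local_peaks.to_csv(outdir / "truth_local_peaks.tsv", sep="\t", index=False)
        self.conservation.to_csv(outdir / "truth_conservation.tsv", sep="\t", index=False)
        self.clusters.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
        meta = {
            "telomere_copies": self.telomere_copies,
            "srna_totals": {str(k): v for k, v in sorted(self.srna_totals.items())},
            "tissue_specific": {
                t: {d: sorted(g) for d, g in sorted(dd.items())}
                for t, dd in sorted(self.tissue_specific.items())
            },
        }
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


@dataclass
class SyntheticBundle:
    """In-memory view of a generated dataset plus its truth table."""

    config: SyntheticConfig
    genome: GenomeSequence
    genes: IntervalSet
    tes: IntervalSet
    k27ac: IntervalSet          # local + distal peaks
    k27ac_distal: IntervalSet
    k4me1: IntervalSet
    tfbs: list[IntervalSet]
    conserved: IntervalSet
    clusters: IntervalSet
    loops: LoopSet
    rna: StrandedSignal
    rampage: StrandedSignal
    srna24: StrandedSignal
    activity: StrandedSignal
    mask: MappabilityMask
    expression: pd.DataFrame    # gene x tissue RPKM
    de_table: pd.DataFrame
    orthology: dict[str, dict[str, list[str]]]
    target_degs: dict[str, set[str]]
    srna_reads: SRnaReadTable
    truth: TruthTable

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        _write_annotation_gff3(outdir / "annotation.gff3", self.genes, self.tes)
        write_intervals(self.tes, outdir / "tes.bed")
        write_intervals(self.k27ac, outdir / "k27ac.bed")
        write_intervals(self.k4me1, outdir / "k4me1.bed")
        for i, tf in enumerate(self.tfbs, start=1):
            write_intervals(tf, outdir / f"tfbs_{i}.bed")
        write_intervals(self.conserved, outdir / "conserved.bed")
        write_intervals(self.clusters, outdir / "srna_clusters.bed")
        write_intervals(self.mask.mappable, outdir / "mappable.bed")
        write_loops(self.loops, outdir / "loops.bedpe")
        self.rna.to_bedgraph(outdir / "rna.plus.bedgraph", outdir / "rna.minus.bedgraph")
        self.rampage.to_bedgraph(
            outdir / "rampage.plus.bedgraph", outdir / "rampage.minus.bedgraph"
        )
        self.srna24.to_bedgraph(
            outdir / "srna24.plus.bedgraph", outdir / "srna24.minus.bedgraph"
        )
        self.activity.to_bedgraph(outdir / "activity.bedgraph")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        _write_orthology(outdir / "orthology.tsv", self.orthology)
        with open(outdir / "target_degs.tsv", "w") as fh:
            fh.write("inbred\tgene\n")
            for inbred in sorted(self.target_degs):
                for g in sorted(self.target_degs[inbred]):
                    fh.write(f"{inbred}\t{g}\n")
        self.srna_reads.reads.to_csv(outdir / "srna_reads.tsv", sep="\t", index=False)
        (outdir / "srna_library_size.txt").write_text(str(self.srna_reads.library_size))
        self.truth.write(outdir / "truth")
        return outdir


def _write_annotation_gff3(path: Path, genes: IntervalSet, tes: IntervalSet) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in genes:
            fh.write(
                f"{iv.chrom}\tregcode\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={iv.name}\n"
            )
        for iv in tes:
            fh.write(
                f"{iv.chrom}\tregcode\ttransposable_element\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID=te_{iv.chrom}_{iv.start};family={iv.name}\n"
            )


def _write_orthology(path: Path, orthology: dict[str, dict[str, list[str]]]) -> None:
    with open(path, "w") as fh:
        fh.write("ref_gene\tinbred\thomolog\n")
        for gene in sorted(orthology):
            for inbred in sorted(orthology[gene]):
                for h in orthology[gene][inbred]:
                    fh.write(f"{gene}\t{inbred}\t{h}\n")


# ---------------------------------------------------------------------------
# genome sequence helpers
# ---------------------------------------------------------------------------

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def scrub_motif(seq: str, motifs: list[str]) -> str:
    """Destroy every occurrence of the given motifs by mutating one base.

    Iterates because a substitution can create a fresh occurrence.
    """
    buf = bytearray(seq, "ascii")
    sub = {ord("A"): ord("C"), ord("C"): ord("A"), ord("G"): ord("T"), ord("T"): ord("G")}
    dirty = True
    while dirty:
        dirty = False
        text = buf.decode()
        for motif in motifs:
            start = 0
            while True:
                i = text.find(motif, start)
                if i < 0:
                    break
                mid = i + len(motif) // 2
                buf[mid] = sub[buf[mid]]
                dirty = True
                start = i + 1
            if dirty:
                text = buf.decode()
    return buf.decode()


def generate_mappability_genome(
    seed: int,
    length: int = 50_000,
    n_chroms: int = 1,
    duplications: list[tuple[int, int, int]] | None = None,
    genome_id: str = "synthmap",
) -> tuple[GenomeSequence, list[tuple[int, int, int]]]:
    """Random genome with planted exact duplications (for mappability tests).

    ``duplications`` are (source_start, dest_start, length) triples on
    chromosome 1; when None, two duplications of 300 bp are planted at
    deterministic but seed-dependent positions.
    """
    rng = np.random.default_rng(seed)
    seqs = {}
    for c in range(n_chroms):
        seqs[f"chr{c + 1}"] = random_sequence(rng, length)
    if duplications is None:
        dl = 300
        a = int(rng.integers(0, length // 3))
        b = int(rng.integers(length // 2, length - dl))
        duplications = [(a, b, dl)]
    chrom1 = f"chr1"
    buf = bytearray(seqs[chrom1], "ascii")
    for src, dst, dl in duplications:
        buf[dst : dst + dl] = buf[src : src + dl]
    seqs[chrom1] = buf.decode()
    return GenomeSequence(seqs, genome_id), duplications


def generate_pseudo_replicate_design(
    n: int = 200,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    peak_len: int = 500,
    spacing: int = 2_000,
) -> tuple[IntervalSet, IntervalSet, IntervalSet, pd.DataFrame]:
    """Merged peaks with a planted both / one / neither pseudo-replicate design.

    Returns (merged, pseudo1, pseudo2, truth) where truth marks, per
    merged peak, whether it should survive the reproducibility rule.
    The planted fractions are realized exactly (counts, not sampling).
    """
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_both = int(round(n * fractions[0]))
    n_one = int(round(n * fractions[1]))
    kinds = ["both"] * n_both + ["one"] * n_one + ["neither"] * (n - n_both - n_one)
    kinds = [kinds[i] for i in rng.permutation(n)]
    merged, p1, p2, rows = [], [], [], []
    for i, kind in enumerate(kinds):
        s = _END_MARGIN + i * spacing
        iv = GenomicInterval("chr1", s, s + peak_len, name=f"m{i}", score=float(i))
        merged.append(iv)
        jitter = int(rng.integers(-100, 101))
        rep = GenomicInterval("chr1", s + jitter, s + jitter + peak_len)
        if kind == "both":
            p1.append(rep)
            p2.append(rep)
        elif kind == "one":
            (p1 if rng.random() < 0.5 else p2).append(rep)
        rows.append({"name": iv.name, "kind": kind, "reproducible": kind == "both"})
    gid = "synthrep"
    return (
        IntervalSet(merged, gid, "merged"),
        IntervalSet(p1, gid, "pseudo1"),
        IntervalSet(p2, gid, "pseudo2"),
        pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def _coverage_runs(
    entries: dict[tuple[str, str], list[tuple[int, int, float]]],
    chrom_lengths: dict[str, int],
    library_size: int,
    read_length: int,
    stranded: bool = True,
) -> StrandedSignal:
    runs: dict[str, dict[str, tuple]] = {c: {} for c in chrom_lengths}
    for (chrom, strand), lst in entries.items():
        lst = sorted(lst)
        s = np.array([x[0] for x in lst], dtype=np.int64)
        e = np.array([x[1] for x in lst], dtype=np.int64)
        v = np.array([x[2] for x in lst], dtype=np.float64)
        runs.setdefault(chrom, {})[strand] = (s, e, v)
    return StrandedSignal(
        runs,
        library_size=library_size,
        read_length=read_length,
        chrom_lengths=chrom_lengths,
        stranded=stranded,
    )


def generate_dataset(
    config: SyntheticConfig | None = None, outdir: str | Path | None = None
) -> SyntheticBundle:
    """Generate the full synthetic bundle; deterministic given the seed.

    When ``outdir`` is given the bundle is also written to disk. Raises
    before writing anything if the requested features cannot be placed on
    the configured genome.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gid = "synthgenome"

    n_enh = sum(cfg.class_counts.values())
    n_slots = n_enh + cfg.n_extra_gene_slots
    slots_per_chrom = math.ceil(n_slots / cfg.n_chroms) if n_slots else 0
    required = 2 * _END_MARGIN + slots_per_chrom * cfg.slot_bp
    if cfg.chrom_length is None:
        chrom_length = required
    else:
        chrom_length = cfg.chrom_length
        if chrom_length < required:
            raise ValueError(
                f"chrom_length {chrom_length} too small; need >= {required} "
                f"for {slots_per_chrom} slots per chromosome"
            )
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: chrom_length for c in chroms}

    # --- genome sequence with telomeric repeat runs ----------------------
    motif = cfg.telomere_motif
    telo5 = motif * cfg.telomere_copies
    telo3 = reverse_complement(motif) * cfg.telomere_copies
    if chrom_length < len(telo5) + len(telo3):
        raise ValueError("chromosomes too short for the telomere runs")
    sequences = {}
    for c in chroms:
        middle = scrub_motif(
            random_sequence(rng, chrom_length - len(telo5) - len(telo3)),
            [motif, reverse_complement(motif)],
        )
        sequences[c] = telo5 + middle + telo3
    genome = GenomeSequence(sequences, gid)

    # --- slot layout ------------------------------------------------------
    slot_coords = []  # (chrom, slot_start)
    for si in range(n_slots):
        chrom = chroms[si % cfg.n_chroms]
        within = si // cfg.n_chroms
        slot_coords.append((chrom, _END_MARGIN + within * cfg.slot_bp))

    # genes: one per slot, alternating strand
    gene_ivs, gene_rows = [], []
    for si, (chrom, s0) in enumerate(slot_coords):
        name = f"G{si:05d}"
        strand = "+" if si % 2 == 0 else "-"
        gene_ivs.append(
            GenomicInterval(
                chrom, s0 + _GENE_OFFSET, s0 + _GENE_OFFSET + cfg.gene_length, strand, name
            )
        )
        gene_rows.append({"name": name, "chrom": chrom, "start": s0 + _GENE_OFFSET})
    genes = IntervalSet(gene_ivs, gid, "genes")
    gene_names = [iv.name for iv in gene_ivs]

    # gene-body K4me1 peaks (plants mark gene bodies, not enhancers)
    k4_ivs = [
        GenomicInterval(iv.chrom, iv.start + 200, iv.end, name=f"k4_{iv.name}")
        for iv in gene_ivs
    ]

    # --- enhancers with planted six-class structure -----------------------
    class_sequence = [
        label for label in CLASS_LABELS for _ in range(cfg.class_counts[label])
    ]
    class_sequence = [class_sequence[i] for i in rng.permutation(len(class_sequence))]
    lo_len, hi_len = cfg.enhancer_length_range
    enh_rows = []
    enh_ivs = []
    rna_entries: dict[tuple[str, str], list] = {}
    rampage_entries: dict[tuple[str, str], list] = {}
    activity_entries: dict[tuple[str, str], list] = {}
    tf_ivs: list[list[GenomicInterval]] = [[], []]
    conserved_ivs = []
    for ei, label in enumerate(class_sequence):
        chrom, s0 = slot_coords[ei]
        L = int(rng.integers(lo_len, hi_len + 1))
        start = s0 + _ENH_OFFSET
        end = start + L
        name = f"enh{ei:05d}"
        iv = GenomicInterval(chrom, start, end, name=name)
        enh_ivs.append(iv)
        k4_flag = label.startswith("K4me1+")
        expr_class = label.split(":")[1]
        if k4_flag:
            gap = int(rng.integers(100, 901))
            k4_ivs.append(
                GenomicInterval(chrom, end + gap, end + gap + 800, name=f"k4_{name}")
            )
        # strand-resolved RNA pileup
        plus_reads = minus_reads = 0.0
        strands = []
        if expr_class == "bidirectional":
            strands = ["+", "-"]
        elif expr_class == "unidirectional":
            strands = ["+" if rng.random() < 0.5 else "-"]
        for st in strands:
            count = float(rng.uniform(*cfg.expressed_read_range))
            if st == "+":
                plus_reads = count
            else:
                minus_reads = count
            rna_entries.setdefault((chrom, st), []).append(
                (start, end, count * cfg.rna_read_length / L)
            )
        # capped transcription (RAMPAGE-like)
        capped = bool(rng.random() < cfg.capped_rate[label])
        if capped:
            capped_strands = strands if strands else ["+"]
            for st in capped_strands:
                rampage_entries.setdefault((chrom, st), []).append(
                    (start, end, cfg.capped_read_count * cfg.rampage_read_length / L)
                )
        # activity
        act = max(0.05, float(rng.normal(cfg.activity_mean[expr_class], cfg.activity_sd)))
        activity_entries.setdefault((chrom, "+"), []).append((start, end, act))
        # TFBS
        tfbs_hit = bool(rng.random() < cfg.tfbs_rate[label])
        if tfbs_hit:
            pos = start + int(rng.integers(0, L - 12))
            tf_ivs[ei % 2].append(
                GenomicInterval(chrom, pos, pos + 12, name=f"tf_{name}")
            )
        # conserved elements
        n_cons = 0
        if rng.random() < cfg.conserved_rate[label]:
            if k4_flag and rng.random() < cfg.conserved_high_count_prob:
                n_cons = int(rng.integers(10, 15))
            else:
                n_cons = int(rng.integers(1, 5))
            el = cfg.conserved_element_len
            gap_el = max(1, (L - n_cons * el) // (n_cons + 1))
            pos = start
            for _ in range(n_cons):
                pos += gap_el
                conserved_ivs.append(GenomicInterval(chrom, pos, pos + el))
                pos += el
        enh_rows.append(
            {
                "name": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "class": label,
                "k4me1": k4_flag,
                "expression_class": expr_class,
                "plus_reads": plus_reads,
                "minus_reads": minus_reads,
                "tfbs": tfbs_hit,
                "capped": capped,
                "activity": act,
                "conserved_count": n_cons,
            }
        )
    distal = IntervalSet(enh_ivs, gid, "k27ac:distal")

    # local K27ac peaks over gene TSS (partition truth)
    local_rows, local_ivs = [], []
    for li in range(min(cfg.n_local_peaks, n_slots)):
        g = gene_ivs[li]
        tss = g.start if g.strand == "+" else g.end
        iv = GenomicInterval(g.chrom, tss - 200, tss + 400, name=f"loc{li:04d}")
        local_ivs.append(iv)
        local_rows.append({"name": iv.name, "chrom": iv.chrom, "start": iv.start})
    k27ac = IntervalSet(local_ivs + enh_ivs, gid, "k27ac").sorted()

    # --- TEs --------------------------------------------------------------
    te_ivs = []
    for ti in range(min(cfg.n_tes, n_slots)):
        chrom, s0 = slot_coords[ti]
        fam = cfg.te_families[ti % len(cfg.te_families)]
        te_ivs.append(
            GenomicInterval(chrom, s0 + _TE_OFFSET, s0 + _TE_OFFSET + _TE_LEN, name=fam)
        )
    tes = IntervalSet(te_ivs, gid, "tes")

    # --- 24nt boundary-enriched signal ------------------------------------
    hw = cfg.boundary_halfwidth
    bg = cfg.srna24_background / 2.0  # per strand
    srna24_entries: dict[tuple[str, str], list] = {}
    zones: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for row in enh_rows:
        factor = cfg.boundary_factor[row["expression_class"]]
        zones[row["chrom"]].append((row["start"] - hw, row["start"] + hw, factor))
        zones[row["chrom"]].append((row["end"] - hw, row["end"] + hw, factor))
    for c in chroms:
        pos = 0
        for zs, ze, factor in sorted(zones[c]):
            if zs > pos:
                for st in "+-":
                    srna24_entries.setdefault((c, st), []).append((pos, zs, bg))
            for st in "+-":
                srna24_entries.setdefault((c, st), []).append((zs, ze, bg * factor))
            pos = ze
        if pos < chrom_length:
            for st in "+-":
                srna24_entries.setdefault((c, st), []).append((pos, chrom_length, bg))

    # --- loops and expression ---------------------------------------------
    n_loops = min(cfg.n_loops, n_enh)
    loop_enh = rng.choice(n_enh, size=n_loops, replace=False) if n_loops else np.array([], int)
    # loop target genes drawn from slots without enhancers when possible
    candidate_genes = np.arange(n_enh, n_slots) if n_slots > n_enh else np.arange(n_slots)
    if n_loops > len(candidate_genes):
        candidate_genes = np.arange(n_slots)
    loop_gene = (
        rng.choice(candidate_genes, size=n_loops, replace=n_loops > len(candidate_genes))
        if n_loops
        else np.array([], int)
    )
    pairs = []
    linked_gene_names = set()
    for ei, gi in zip(loop_enh, loop_gene):
        e = enh_ivs[int(ei)]
        g = gene_ivs[int(gi)]
        if e.chrom != g.chrom:
            # keep loops intra-chromosomal: re-target to the same-chrom gene slot
            gi = int(gi) - (int(gi) % cfg.n_chroms) + chroms.index(e.chrom)
            gi = min(gi, n_slots - 1)
            g = gene_ivs[gi]
        a = GenomicInterval(e.chrom, max(0, e.start - 200), e.end + 200)
        b = GenomicInterval(g.chrom, max(0, g.start - 200), g.end + 200)
        pairs.append((a, b))
        linked_gene_names.add(g.name)
        enh_rows[int(ei)]["in_loop"] = True
        enh_rows[int(ei)].setdefault("linked_genes", set()).add(g.name)
    for row in enh_rows:
        row.setdefault("in_loop", False)
        row["linked_genes"] = ",".join(sorted(row.get("linked_genes", set())))
    loops = LoopSet(pairs, gid, "loops")

    log2_expr = rng.normal(
        cfg.expression_log2_mean,
        cfg.expression_log2_sd,
        size=(len(gene_names), len(cfg.tissues)),
    )
    expression = pd.DataFrame(
        np.power(2.0, log2_expr), index=pd.Index(gene_names, name="gene"),
        columns=list(cfg.tissues),
    )

    # --- tissue-specific DEG structure ------------------------------------
    tissue_specific: dict[str, dict[str, set[str]]] = {}
    unassigned = [g for g in gene_names]
    rng.shuffle(unassigned)
    cursor = 0
    for tissue in cfg.tissues:
        up_n, down_n = cfg.deg_counts.get(tissue, (0, 0))
        if cursor + up_n + down_n > len(unassigned):
            raise ValueError("not enough genes for the requested DEG counts")
        ups = set(unassigned[cursor : cursor + up_n])
        cursor += up_n
        downs = set(unassigned[cursor : cursor + down_n])
        cursor += down_n
        tissue_specific[tissue] = {"up": ups, "down": downs}
        for g in ups:
            expression.loc[g, tissue] *= 2.0 ** cfg.deg_log2fc
        for g in downs:
            expression.loc[g, tissue] /= 2.0 ** cfg.deg_log2fc
    distractors = unassigned[cursor : cursor + cfg.n_distractor_genes]
    # loop-linked genes: planted expression shift, every tissue
    for g in linked_gene_names:
        expression.loc[g] *= 2.0 ** cfg.loop_expression_shift

    pairs_t = [
        (a, b) for i, a in enumerate(cfg.tissues) for b in cfg.tissues[i + 1 :]
    ]
    de_rows = []
    distractor_plan: dict[str, set[tuple[str, str]]] = {}
    for g in distractors:
        t = cfg.tissues[int(rng.integers(0, len(cfg.tissues)))]
        others = [x for x in cfg.tissues if x != t]
        k = int(rng.integers(1, len(others)))  # DE in 1..3 of the 4 pairings only
        chosen = rng.choice(len(others), size=k, replace=False)
        distractor_plan[g] = {(t, others[int(i)]) for i in chosen}
    for a, b in pairs_t:
        for g in gene_names:
            lfc = float(rng.normal(0.0, 0.2))
            q = float(rng.uniform(0.2, 1.0))
            for t, direction in ((a, 1.0), (b, -1.0)):
                if g in tissue_specific.get(t, {}).get("up", ()):  # up in t vs all
                    lfc, q = direction * cfg.deg_log2fc, 1e-4
                elif g in tissue_specific.get(t, {}).get("down", ()):
                    lfc, q = -direction * cfg.deg_log2fc, 1e-4
            plan = distractor_plan.get(g, ())
            if (a, b) in plan:
                lfc, q = cfg.deg_log2fc, 1e-4
            elif (b, a) in plan:
                lfc, q = -cfg.deg_log2fc, 1e-4
            de_rows.append(
                {"gene": g, "tissue_a": a, "tissue_b": b, "log2fc": lfc, "fdr": q}
            )
    de_table = pd.DataFrame(de_rows)

    # --- orthology / conservation flow -------------------------------------
    orthology: dict[str, dict[str, list[str]]] = {}
    target_degs: dict[str, set[str]] = {inb: set() for inb in cfg.target_inbreds}
    cons_rows = []
    ref_degs = [f"TIL11_G{i:05d}" for i in range(cfg.n_ref_degs)]
    for gi, gene in enumerate(ref_degs):
        orthology[gene] = {}
        for inbred in cfg.target_inbreds:
            if rng.random() < cfg.no_homolog_probability:
                status = "no_homolog"
            else:
                n_h = int(rng.integers(1, 3))
                homologs = [f"{inbred}_H{gi:05d}_{j}" for j in range(n_h)]
                orthology[gene][inbred] = homologs
                if rng.random() < cfg.conservation_probability:
                    status = "conserved_DEG"
                    target_degs[inbred].add(
                        homologs[int(rng.integers(0, n_h))]
                    )
                else:
                    status = "homolog_not_DEG"
            cons_rows.append({"gene": gene, "inbred": inbred, "status": status})
    for inbred in cfg.target_inbreds:
        for i in range(cfg.n_target_extra_degs):
            target_degs[inbred].add(f"{inbred}_X{i:05d}")
    conservation = pd.DataFrame(cons_rows, columns=["gene", "inbred", "status"])

    # --- small RNA clusters and reads ---------------------------------------
    cluster_ivs, cluster_rows, read_rows = [], [], []
    per_len_used = {L: 0 for L in cfg.srna_totals}

    def add_reads(chrom, pos, length, counts_by_strand):
        for st, cnt in counts_by_strand.items():
            if cnt > 0:
                read_rows.append(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + length,
                        "strand": st,
                        "length": length,
                        "count": int(cnt),
                    }
                )
                per_len_used[length] = per_len_used.get(length, 0) + int(cnt)

    hairpin_counts = {21: 140, 22: 700, 24: 160}
    short_counts = {21: 20, 22: 200, 24: 20}
    unbiased_counts = {21: 50, 22: 100, 24: 800}
    n_cl = min(cfg.n_srna_clusters, n_slots)
    for ci in range(n_cl):
        chrom, s0 = slot_coords[ci]
        if ci < cfg.n_hairpin_clusters:
            kind, span, counts, bias = "hairpin", cfg.hairpin_span, hairpin_counts, cfg.hairpin_bias
        elif ci < cfg.n_hairpin_clusters + (n_cl - cfg.n_hairpin_clusters) // 2:
            kind, span, counts, bias = "short_biased", 400, short_counts, cfg.hairpin_bias
        else:
            kind, span, counts, bias = "long_unbiased", 1_500, unbiased_counts, 0.5
        start = s0 + _CLUSTER_OFFSET
        iv = GenomicInterval(chrom, start, start + span, name=f"cl{ci:03d}")
        cluster_ivs.append(iv)
        dominant_strand = "+" if ci % 2 == 0 else "-"
        total = sum(counts.values())
        plus_total = 0
        for off, (L, cnt) in enumerate(sorted(counts.items())):
            n_dom = int(round(cnt * bias))
            dom, other = (n_dom, cnt - n_dom)
            by_strand = (
                {"+": dom, "-": other} if dominant_strand == "+" else {"+": other, "-": dom}
            )
            plus_total += by_strand["+"]
            add_reads(chrom, start + 10 + off * 40, L, by_strand)
        cluster_rows.append(
            {
                "name": iv.name,
                "chrom": chrom,
                "start": start,
                "end": start + span,
                "kind": kind,
                "bias": max(plus_total, total - plus_total) / total,
                "frac22": counts[22] / total,
                "hairpin_like": kind == "hairpin",
            }
        )
    # background reads topping the planted totals up to exact values
    for L in sorted(cfg.srna_totals):
        remaining = cfg.srna_totals[L] - per_len_used.get(L, 0)
        if remaining < 0:
            raise ValueError(
                f"cluster reads exceed the planted total for length {L}"
            )
        chunk = 50
        bi = 0
        while remaining > 0:
            c = min(chunk, remaining)
            chrom, s0 = slot_coords[bi % max(1, n_slots)] if n_slots else (chroms[0], _END_MARGIN)
            lo, hi = _BG_SRNA_ZONE
            pos = s0 + lo + int(rng.integers(0, hi - lo - L))
            st = "+" if bi % 2 == 0 else "-"
            add_reads(chrom, pos, L, {st: c})
            remaining -= c
            bi += 1
    reads_df = pd.DataFrame(
        read_rows, columns=["chrom", "start", "end", "strand", "length", "count"]
    )
    library_size = int(reads_df["count"].sum()) if len(reads_df) else 1
    srna_reads = SRnaReadTable(reads_df, library_size)
    clusters = IntervalSet(cluster_ivs, gid, "srna_clusters")

    # --- mappable mask (constructed from the layout truth) ------------------
    k = cfg.mask_bin
    telo_len = len(telo5)
    first_bin = math.ceil(telo_len / k)
    mask_ivs = []
    for c in chroms:
        last_bin = (chrom_length - telo_len) // k  # bins fully before the 3' run
        if last_bin > first_bin:
            mask_ivs.append(GenomicInterval(c, first_bin * k, last_bin * k))
    mask = MappabilityMask(IntervalSet(mask_ivs, gid, "mappable"), k, gid)

    # --- assemble signals ----------------------------------------------------
    rna_lib = int(
        sum(v * (e - s) for lst in rna_entries.values() for s, e, v in lst)
        / cfg.rna_read_length
    ) or 1
    rna = _coverage_runs(rna_entries, chrom_lengths, rna_lib, cfg.rna_read_length)
    ramp_lib = int(
        sum(v * (e - s) for lst in rampage_entries.values() for s, e, v in lst)
        / cfg.rampage_read_length
    ) or 1
    rampage = _coverage_runs(
        rampage_entries, chrom_lengths, ramp_lib, cfg.rampage_read_length
    )
    srna24 = _coverage_runs(srna24_entries, chrom_lengths, 1, 24)
    activity = _coverage_runs(
        activity_entries, chrom_lengths, 1, 1, stranded=False
    )

    truth = TruthTable(
        enhancers=pd.DataFrame(
            enh_rows,
            columns=[
                "name", "chrom", "start", "end", "class", "k4me1",
                "expression_class", "plus_reads", "minus_reads", "tfbs",
                "capped", "activity", "conserved_count", "in_loop", "linked_genes",
            ],
        ),
        genes=pd.DataFrame(gene_rows, columns=["name", "chrom", "start"]),
        local_peaks=pd.DataFrame(local_rows, columns=["name", "chrom", "start"]),
        tissue_specific=tissue_specific,
        conservation=conservation,
        clusters=pd.DataFrame(
            cluster_rows,
            columns=["name", "chrom", "start", "end", "kind", "bias", "frac22", "hairpin_like"],
        ),
        telomere_copies=cfg.telomere_copies,
        srna_totals=dict(cfg.srna_totals),
    )

    bundle = SyntheticBundle(
        config=cfg,
        genome=genome,
        genes=genes,
        tes=tes,
        k27ac=k27ac,
        k27ac_distal=distal,
        k4me1=IntervalSet(k4_ivs, gid, "k4me1").sorted(),
        tfbs=[IntervalSet(t, gid, f"tf{i+1}") for i, t in enumerate(tf_ivs)],
        conserved=IntervalSet(conserved_ivs, gid, "conserved"),
        clusters=clusters,
        loops=loops,
        rna=rna,
        rampage=rampage,
        srna24=srna24,
        activity=activity,
        mask=mask,
        expression=expression,
        de_table=de_table,
        orthology=orthology,
        target_degs=target_degs,
        srna_reads=srna_reads,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
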