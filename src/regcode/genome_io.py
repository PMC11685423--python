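"""Genomic interval, signal and sequence containers plus readers/writers.

All coordinates are 0-based half-open (BED convention). GFF3, which is
1-based closed, is converted at the parsing boundary so that no other
module ever sees a 1-based coordinate.

Distances between intervals are edge-to-edge gaps: two intervals that
share at least one base are at distance 0; a query on a chromosome with
no reference interval is at distance ``+inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed interval-format lines; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded region on a named chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.score is None or (isinstance(self.score, float) and math.isnan(self.score)):
            raise ValueError("score must not be NaN")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def gap_to(self, other: "GenomicInterval") -> float:
        """Edge-to-edge gap in bp; 0 on overlap, +inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        return float(max(0, max(self.start, other.start) - min(self.end, other.end)))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` on one genome."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome_id: str = "",
        label: str = "",
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome_id = genome_id
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalSet)
            and self.intervals == other.intervals
            and self.genome_id == other.genome_id
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, genome={self.genome_id!r}, label={self.label!r})"

    def sorted(self) -> "IntervalSet":
        """Canonical order: chrom lexicographic, then start, then end."""
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, self.genome_id, self.label)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, genome_id: str = "", label: str = ""
    ) -> "IntervalSet":
        ivs = [
            GenomicInterval(
                str(r.chrom),
                int(r.start),
                int(r.end),
                str(getattr(r, "strand", ".")) or ".",
                str(getattr(r, "name", "") or ""),
                float(getattr(r, "score", 0.0) or 0.0),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(ivs, genome_id, label)


class LoopSet:
    """Pairs of anchor intervals (chromatin contacts) on one genome.

    Anchor order within a pair is normalized so the left anchor sorts
    before the right one.
    """

    def __init__(
        self,
        pairs: Iterable[tuple[GenomicInterval, GenomicInterval]] = (),
        genome_id: str = "",
        label: str = "",
    ) -> None:
        norm = []
        for a, b in pairs:
            if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
                a, b = b, a
            norm.append((a, b))
        self.pairs: list[tuple[GenomicInterval, GenomicInterval]] = norm
        self.genome_id = genome_id
        self.label = label

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LoopSet)
            and self.pairs == other.pairs
            and self.genome_id == other.genome_id
        )

    def anchors(self) -> IntervalSet:
        """All anchors as one flat set (left then right, per pair order)."""
        out = []
        for a, b in self.pairs:
            out.append(a)
            out.append(b)
        return IntervalSet(out, self.genome_id, self.label + ":anchors")


@dataclass
class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name."""

    sequences: dict[str, str]
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence(
            {c: reverse_complement(s) for c, s in self.sequences.items()},
            genome_id=self.genome_id + "_rc" if self.genome_id else "",
        )

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str = "") -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in FASTA {path}")
        return cls(seqs, genome_id or Path(path).stem)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=c, description="") for c, s in self.sequences.items()]
        SeqIO.write(recs, str(path), "fasta")


class StrandedSignal:
    """Per-base non-negative coverage on + and - strands, run-length encoded.

    Runs are stored per chromosome and strand as parallel numpy arrays
    ``(starts, ends, values)`` sorted and non-overlapping; positions not
    covered by a run have value 0. An unstranded track is represented
    with all mass on the ``+`` strand and ``stranded=False``.
    """

    def __init__(
        self,
        runs: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]],
        library_size: int = 0,
        read_length: int = 1,
        chrom_lengths: dict[str, int] | None = None,
        stranded: bool = True,
    ) -> None:
        if read_length <= 0:
            raise ValueError("read_length must be positive")
        self.runs = runs
        self.library_size = int(library_size)
        self.read_length = int(read_length)
        self.chrom_lengths = dict(chrom_lengths or {})
        self.stranded = stranded
        self._cum: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for chrom, strands in runs.items():
            for strand, (s, e, v) in strands.items():
                s = np.asarray(s, dtype=np.int64)
                e = np.asarray(e, dtype=np.int64)
                v = np.asarray(v, dtype=np.float64)
                if np.any(v < 0):
                    raise ValueError("coverage values must be >= 0")
                if np.any(e <= s) or np.any(s[1:] < e[:-1]):
                    raise ValueError("runs must be sorted and non-overlapping")
                strands[strand] = (s, e, v)
            if chrom_lengths is None:
                hi = max(
                    (int(e[-1]) for (s, e, v) in strands.values() if len(e)), default=0
                )
                self.chrom_lengths[chrom] = max(self.chrom_lengths.get(chrom, 0), hi)

    # -- construction -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        per_bp: dict[str, dict[str, np.ndarray]],
        **kw,
    ) -> "StrandedSignal":
        """Build from dense per-bp arrays (test/synthesis convenience)."""
        runs: dict[str, dict[str, tuple]] = {}
        if "chrom_lengths" not in kw:
            kw["chrom_lengths"] = {
                c: max(len(a) for a in strands.values()) for c, strands in per_bp.items()
            }
        for chrom, strands in per_bp.items():
            runs[chrom] = {}
            for strand, arr in strands.items():
                arr = np.asarray(arr, dtype=np.float64)
                change = np.flatnonzero(np.diff(arr) != 0) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                vals = arr[starts]
                keep = vals != 0
                runs[chrom][strand] = (starts[keep], ends[keep], vals[keep])
        return cls(runs, **kw)

    @classmethod
    def from_bedgraph(
        cls,
        plus_path: str | Path,
        minus_path: str | Path | None = None,
        library_size: int = 0,
        read_length: int = 1,
        chrom_lengths: dict[str, int] | None = None,
    ) -> "StrandedSignal":
        runs: dict[str, dict[str, tuple]] = {}

        def load(path, strand):
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "value"],
                comment="#",
                dtype={"chrom": str},
            )
            for chrom, sub in df.groupby("chrom", sort=True):
                sub = sub.sort_values("start")
                runs.setdefault(chrom, {})[strand] = (
                    sub["start"].to_numpy(np.int64),
                    sub["end"].to_numpy(np.int64),
                    sub["value"].to_numpy(np.float64),
                )

        load(plus_path, "+")
        stranded = minus_path is not None
        if stranded:
            load(minus_path, "-")
        return cls(
            runs,
            library_size=library_size,
            read_length=read_length,
            chrom_lengths=chrom_lengths,
            stranded=stranded,
        )

    def to_bedgraph(self, plus_path: str | Path, minus_path: str | Path | None = None) -> None:
        def dump(path, strand):
            with open(path, "w") as fh:
                for chrom in sorted(self.runs):
                    s, e, v = self.runs[chrom].get(
                        strand, (np.array([], int), np.array([], int), np.array([], float))
                    )
                    for i in range(len(s)):
                        fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")

        dump(plus_path, "+")
        if minus_path is not None:
            dump(minus_path, "-")

    # -- queries ------------------------------------------------------

    def _knots(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear cumulative-area knots for one chrom/strand."""
        key = (chrom, strand)
        if key not in self._cum:
            s, e, v = self.runs.get(chrom, {}).get(
                strand, (np.array([], int), np.array([], int), np.array([], float))
            )
            if len(s) == 0:
                self._cum[key] = (np.array([0.0]), np.array([0.0]))
            else:
                areas = v * (e - s)
                cum = np.concatenate(([0.0], np.cumsum(areas)))
                # knot positions: s0,e0,s1,e1,... with flat segments in gaps
                pos = np.empty(2 * len(s), dtype=np.float64)
                val = np.empty(2 * len(s), dtype=np.float64)
                pos[0::2] = s
                pos[1::2] = e
                val[0::2] = cum[:-1]
                val[1::2] = cum[1:]
                self._cum[key] = (pos, val)
        return self._cum[key]

    def integral(self, chrom: str, x, y, strand: str = "both") -> np.ndarray:
        """Area under the coverage curve over [x, y); x, y may be arrays.

        Positions outside any run contribute 0. Fractional (float)
        endpoints are supported via linear interpolation within runs.
        """
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        y = np.atleast_1d(np.asarray(y, dtype=np.float64))
        strands = ["+", "-"] if strand == "both" else [strand]
        total = np.zeros_like(x)
        for st in strands:
            pos, val = self._knots(chrom, st)
            total += np.interp(y, pos, val) - np.interp(x, pos, val)
        return total

    def sum_over(self, interval: GenomicInterval, strand: str = "both") -> float:
        return float(self.integral(interval.chrom, interval.start, interval.end, strand)[0])

    def values(self, chrom: str, start: int, end: int, strand: str = "both") -> np.ndarray:
        """Dense per-bp values over [start, end) (clipped to >=0 positions)."""
        n = end - start
        out = np.zeros(n, dtype=np.float64)
        strands = ["+", "-"] if strand == "both" else [strand]
        for st in strands:
            s, e, v = self.runs.get(chrom, {}).get(
                st, (np.array([], int), np.array([], int), np.array([], float))
            )
            for i in range(len(s)):
                lo = max(int(s[i]), start)
                hi = min(int(e[i]), end)
                if lo < hi:
                    out[lo - start : hi - start] += v[i]
        return out

    def scaled(self, factor: float) -> "StrandedSignal":
        runs = {
            c: {st: (s.copy(), e.copy(), v * factor) for st, (s, e, v) in strands.items()}
            for c, strands in self.runs.items()
        }
        return StrandedSignal(
            runs,
            library_size=self.library_size,
            read_length=self.read_length,
            chrom_lengths=self.chrom_lengths,
            stranded=self.stranded,
        )


# ---------------------------------------------------------------------------
# Parsing / writing of interval formats
# ---------------------------------------------------------------------------

_BED_FORMATS = {"BED", "narrowPeak"}


def parse_intervals(
    path: str | Path,
    format: str,
    genome_id: str = "",
    label: str = "",
    feature_types: Sequence[str] | None = None,
):
    """Parse BED/narrowPeak/GFF3 into an :class:`IntervalSet`, BEDPE into a
    :class:`LoopSet`.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    For GFF3 the interval ``name`` is the ``ID`` attribute when present,
    else the feature type; ``feature_types`` optionally restricts which
    feature rows are kept. Malformed lines raise :class:`FormatError`
    naming the line number.
    """
    path = Path(path)
    if format in _BED_FORMATS:
        return _parse_bed(path, format, genome_id, label)
    if format == "GFF3":
        return _parse_gff3(path, genome_id, label, feature_types)
    if format == "BEDPE":
        return _parse_bedpe(path, genome_id, label)
    raise ValueError(f"unknown format {format!r}")


def _fail(path: Path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


def _parse_bed(path: Path, format: str, genome_id: str, label: str) -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, f"expected >=3 tab-separated fields, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start >= end:
                _fail(path, lineno, f"start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else ""
            score = 0.0
            if len(f) > 4 and f[4] not in (".", ""):
                try:
                    score = float(f[4])
                except ValueError:
                    _fail(path, lineno, f"non-numeric score {f[4]!r}")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            if format == "narrowPeak" and len(f) >= 10:
                # summit offset retained as metadata in the name (unused downstream)
                name = f"{name};summit={f[9]}"
            ivs.append(GenomicInterval(f[0], start, end, strand, name, score))
    return IntervalSet(ivs, genome_id, label or path.stem)


def _parse_gff3(
    path: Path, genome_id: str, label: str, feature_types: Sequence[str] | None
) -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                _fail(path, lineno, f"expected 9 GFF3 fields, got {len(f)}")
            ftype = f[2]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if start >= end:
                _fail(path, lineno, f"start >= end after conversion ({start} >= {end})")
            score = 0.0 if f[5] == "." else float(f[5])
            strand = f[6] if f[6] in ("+", "-") else "."
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID", ftype)
            ivs.append(GenomicInterval(f[0], start, end, strand, name, score))
    return IntervalSet(ivs, genome_id, label or path.stem)


def _parse_bedpe(path: Path, genome_id: str, label: str) -> LoopSet:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                _fail(path, lineno, f"expected >=6 BEDPE fields, got {len(f)}")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[6] if len(f) > 6 else "")
                b = GenomicInterval(f[3], int(f[4]), int(f[5]), name=f[6] if len(f) > 6 else "")
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            pairs.append((a, b))
    return LoopSet(pairs, genome_id, label or path.stem)


def write_intervals(ivs: IntervalSet, path: str | Path, format: str = "BED") -> None:
    """Write BED6 (or GFF3, converting back to 1-based closed)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "BED":
            for iv in ivs:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{iv.score:g}\t{iv.strand}\n"
                )
        elif format == "GFF3":
            fh.write("##gff-version 3\n")
            for iv in ivs:
                name = iv.name or "feature"
                fh.write(
                    f"{iv.chrom}\tregcode\t{name.split(':')[0] or 'feature'}\t{iv.start + 1}\t{iv.end}\t"
                    f"{iv.score:g}\t{iv.strand}\t.\tID={name}\n"
                )
        else:
            raise ValueError(f"unsupported write format {format!r}")


def write_loops(loops: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(loops):
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\tloop{i}\n"
            )


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------


def _check_same_genome(a, b) -> None:
    if a.genome_id and b.genome_id and a.genome_id != b.genome_id:
        raise ValueError(
            f"genome mismatch: {a.genome_id!r} vs {b.genome_id!r}"
        )


def _chrom_arrays(ivs: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chrom (starts, ends, order) sorted by start; order maps back to input index."""
    grouped: dict[str, list[int]] = {}
    for i, iv in enumerate(ivs):
        grouped.setdefault(iv.chrom, []).append(i)
    out = {}
    for chrom, idx_list in grouped.items():
        idx = np.asarray(idx_list, dtype=np.int64)
        starts = np.array([ivs[int(i)].start for i in idx], dtype=np.int64)
        ends = np.array([ivs[int(i)].end for i in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        out[chrom] = (starts[order], ends[order], idx[order])
    return out


def nearest_distance(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Edge-gap distance (bp) from each query interval to its closest
    reference interval; 0 on any >=1 bp overlap, +inf when the query's
    chromosome carries no reference interval.
    """
    _check_same_genome(query, reference)
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    ref = {
        c: (s, e, np.maximum.accumulate(e)) for c, (s, e, _) in _chrom_arrays(reference).items()
    }
    out = np.full(len(query), np.inf)
    for qi, iv in enumerate(query):
        if iv.chrom not in ref:
            continue
        starts, ends, cummax_ends = ref[iv.chrom]
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        best = math.inf
        if idx > 0:
            left_end = int(cummax_ends[idx - 1])
            if left_end > iv.start:
                out[qi] = 0.0
                continue
            best = iv.start - left_end
        if idx < len(starts):
            best = min(best, int(starts[idx]) - iv.end)
        out[qi] = float(best)
    return out


def intersect(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flag each a-interval sharing >= min_bp with any b-interval.

    Returns ``(flags, pairs)`` where ``pairs`` lists every qualifying
    (a_index, b_index) in input order of ``a``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    _check_same_genome(a, b)
    barr = _chrom_arrays(b)
    maxlen = {c: int((e - s).max()) if len(s) else 0 for c, (s, e, _) in barr.items()}
    flags = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ai, iv in enumerate(a):
        if iv.chrom not in barr:
            continue
        starts, ends, orig = barr[iv.chrom]
        # candidates: b.start <= a.end - min_bp and b.end >= a.start + min_bp
        hi = int(np.searchsorted(starts, iv.end - min_bp, side="right"))
        lo = int(np.searchsorted(starts, iv.start + min_bp - maxlen[iv.chrom], side="left"))
        for j in range(lo, hi):
            ov = min(iv.end, int(ends[j])) - max(iv.start, int(starts[j]))
            if ov >= min_bp:
                flags[ai] = True
                pairs.append((ai, int(orig[j])))
    return flags, pairs


def merge(ivs: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    """Single-linkage merge of intervals sharing >= min_overlap_bp bases.

    With the default 1 bp, book-ended (touching) intervals stay separate
    under half-open coordinates.
    """
    merged = []
    for chrom, lst in sorted(ivs.by_chrom().items()):
        lst = sorted(lst, key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = lst[0].start, lst[0].end
        for iv in lst[1:]:
            if iv.start <= cur_e - min_overlap_bp:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(merged, ivs.genome_id, ivs.label + ":merged" if ivs.label else "")
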