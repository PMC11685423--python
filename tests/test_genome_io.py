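"""Interval/sequence/signal containers, format round-trips and the
nearest/intersect primitives against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regcode.genome_io import (
    FormatError,
    GenomeSequence,
    GenomicInterval,
    IntervalSet,
    LoopSet,
    StrandedSignal,
    intersect,
    merge,
    nearest_distance,
    parse_intervals,
    write_intervals,
    write_loops,
)


def _random_set(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500, genome_id="g"):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(
            GenomicInterval(
                chroms[int(rng.integers(0, len(chroms)))],
                start,
                start + length,
                name=f"iv{i}",
                score=float(rng.integers(0, 1000)),
            )
        )
    return IntervalSet(ivs, genome_id)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, strand="x")

    def test_gap_and_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.gap_to(GenomicInterval("chr1", 150, 300)) == 0
        assert a.gap_to(GenomicInterval("chr1", 2200, 2400)) == 2000
        assert a.gap_to(GenomicInterval("chr2", 100, 200)) == math.inf
        assert a.overlaps(GenomicInterval("chr1", 199, 250))
        assert not a.overlaps(GenomicInterval("chr1", 200, 250))  # half-open


class TestParsing:
    def test_bed_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\tp1\t5\t+\n")
        ivs = parse_intervals(p, "BED")
        assert ivs[0] == GenomicInterval("chr1", 100, 200, "+", "p1", 5.0)

    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\nchr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        )
        ivs = parse_intervals(p, "GFF3")
        assert (ivs[0].start, ivs[0].end) == (100, 200)
        assert ivs[0].name == "g1"

    def test_gff3_feature_filter(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "chr1\ts\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\ts\texon\t1\t50\t.\t+\t.\tID=e1\n"
        )
        assert len(parse_intervals(p, "GFF3", feature_types=["gene"])) == 1

    def test_bedpe_gives_loops_with_normalized_order(self, tmp_path):
        p = tmp_path / "x.bedpe"
        p.write_text("chr1\t5000\t6000\tchr1\t100\t200\n")
        loops = parse_intervals(p, "BEDPE")
        assert isinstance(loops, LoopSet)
        a, b = loops.pairs[0]
        assert a.start == 100 and b.start == 5000

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t250\n")
        with pytest.raises(FormatError, match="bad.bed:2"):
            parse_intervals(p, "BED")

    def test_narrowpeak_summit_kept_as_metadata(self, tmp_path):
        p = tmp_path / "x.narrowPeak"
        p.write_text("chr1\t0\t100\tpk\t60\t.\t5.0\t4.0\t3.0\t42\n")
        ivs = parse_intervals(p, "narrowPeak")
        assert "summit=42" in ivs[0].name

    def test_bed_roundtrip_large_set(self, tmp_path):
        rng = np.random.default_rng(0)
        ivs = _random_set(rng, 1000).sorted()
        write_intervals(ivs, tmp_path / "r.bed")
        back = parse_intervals(tmp_path / "r.bed", "BED", genome_id="g")
        assert back.intervals == ivs.intervals

    def test_bedpe_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(50):
            s1 = int(rng.integers(0, 10_000))
            s2 = int(rng.integers(0, 10_000))
            pairs.append(
                (GenomicInterval("chr1", s1, s1 + 100), GenomicInterval("chr1", s2, s2 + 100))
            )
        loops = LoopSet(pairs, "g")
        write_loops(loops, tmp_path / "l.bedpe")
        back = parse_intervals(tmp_path / "l.bedpe", "BEDPE", genome_id="g")
        assert [(a.start, b.start) for a, b in back] == [
            (a.start, b.start) for a, b in loops
        ]


class TestNearestDistance:
    def test_overlap_is_zero(self):
        q = IntervalSet([GenomicInterval("chr1", 100, 200)])
        r = IntervalSet([GenomicInterval("chr1", 150, 300)])
        assert nearest_distance(q, r)[0] == 0

    def test_edge_gap(self):
        q = IntervalSet([GenomicInterval("chr1", 100, 200)])
        r = IntervalSet([GenomicInterval("chr1", 2200, 2400)])
        assert nearest_distance(q, r)[0] == 2000

    def test_missing_chromosome_gives_inf(self):
        q = IntervalSet([GenomicInterval("chr9", 0, 10)])
        r = IntervalSet([GenomicInterval("chr1", 0, 10)])
        assert nearest_distance(q, r)[0] == math.inf

    def test_empty_reference_errors(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            nearest_distance(q, IntervalSet([]))

    def test_genome_mismatch_errors(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10)], genome_id="a")
        r = IntervalSet([GenomicInterval("chr1", 0, 10)], genome_id="b")
        with pytest.raises(ValueError, match="genome mismatch"):
            nearest_distance(q, r)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = _random_set(rng, 500)
        r = _random_set(rng, 50)
        got = nearest_distance(q, r)
        expected = np.array(
            [min((iv.gap_to(rv) for rv in r), default=math.inf) for iv in q]
        )
        assert np.array_equal(got, expected)

    def test_zero_distance_iff_intersecting(self):
        rng = np.random.default_rng(3)
        q = _random_set(rng, 300)
        r = _random_set(rng, 40)
        flags, _ = intersect(q, r)
        assert np.array_equal(nearest_distance(q, r) == 0, flags)


class TestIntersect:
    def test_one_bp_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 9, 20)])
        assert intersect(a, b)[0][0]

    def test_half_open_boundary(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 10, 20)])
        assert not intersect(a, b)[0][0]

    def test_min_bp_below_one_errors(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            intersect(a, a, min_bp=0)

    @pytest.mark.parametrize("min_bp", [1, 25])
    def test_matches_quadratic_oracle(self, min_bp):
        rng = np.random.default_rng(4)
        a = _random_set(rng, 300)
        b = _random_set(rng, 200)
        flags, pairs = intersect(a, b, min_bp=min_bp)
        expected_pairs = {
            (i, j)
            for i, ai in enumerate(a)
            for j, bj in enumerate(b)
            if ai.chrom == bj.chrom
            and min(ai.end, bj.end) - max(ai.start, bj.start) >= min_bp
        }
        assert set(pairs) == expected_pairs
        assert np.array_equal(flags, np.array([any(p[0] == i for p in expected_pairs) for i in range(len(a))]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_count_invariant_under_shuffling_and_renaming(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_set(rng, 60)
        b = _random_set(rng, 40)
        n = len(intersect(a, b)[1])
        perm = rng.permutation(len(a))
        a_shuf = IntervalSet([a[int(i)] for i in perm], a.genome_id)
        rename = lambda ivs: IntervalSet(
            [
                GenomicInterval("X" + iv.chrom, iv.start, iv.end, iv.strand, iv.name, iv.score)
                for iv in ivs
            ],
            ivs.genome_id,
        )
        assert len(intersect(a_shuf, b)[1]) == n
        assert len(intersect(rename(a), rename(b))[1]) == n


class TestMerge:
    def test_single_linkage_chain(self):
        ivs = IntervalSet(
            [
                GenomicInterval("chr1", 0, 10),
                GenomicInterval("chr1", 5, 15),
                GenomicInterval("chr1", 14, 30),
                GenomicInterval("chr1", 30, 40),  # book-ended: not merged
            ]
        )
        out = merge(ivs)
        assert [(iv.start, iv.end) for iv in out] == [(0, 30), (30, 40)]


class TestStrandedSignal:
    def test_from_arrays_and_integral(self):
        arr = np.zeros(100)
        arr[10:20] = 2.0
        sig = StrandedSignal.from_arrays({"chr1": {"+": arr, "-": np.zeros(100)}})
        assert sig.integral("chr1", 0, 100, "+")[0] == 20.0
        assert sig.integral("chr1", 15, 25, "+")[0] == 10.0
        assert sig.integral("chr1", 0, 100, "-")[0] == 0.0

    def test_fractional_endpoints(self):
        arr = np.zeros(10)
        arr[2:4] = 3.0
        sig = StrandedSignal.from_arrays({"chr1": {"+": arr}})
        assert sig.integral("chr1", 2.5, 3.5, "+")[0] == pytest.approx(3.0)

    def test_values_dense(self):
        arr = np.arange(20, dtype=float)
        sig = StrandedSignal.from_arrays({"chr1": {"+": arr}})
        assert np.array_equal(sig.values("chr1", 5, 12, "+"), arr[5:12])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            StrandedSignal({"chr1": {"+": (np.array([0]), np.array([5]), np.array([-1.0]))}})

    def test_bedgraph_roundtrip(self, tmp_path, small_bundle):
        sig = small_bundle.rna
        sig.to_bedgraph(tmp_path / "p.bg", tmp_path / "m.bg")
        back = StrandedSignal.from_bedgraph(
            tmp_path / "p.bg", tmp_path / "m.bg",
            library_size=sig.library_size, read_length=sig.read_length,
        )
        for chrom in sig.runs:
            for strand in "+-":
                a = sig.runs[chrom].get(strand)
                b = back.runs.get(chrom, {}).get(strand)
                if a is None or len(a[0]) == 0:
                    assert b is None or len(b[0]) == 0
                else:
                    assert np.array_equal(a[0], b[0])
                    assert np.array_equal(a[1], b[1])
                    assert np.allclose(a[2], b[2])


class TestGenomeSequence:
    def test_fasta_roundtrip(self, tmp_path):
        g = GenomeSequence({"chr1": "ACGTACGTAC", "chr2": "GGGTTTAAAC"}, "g")
        g.to_fasta(tmp_path / "g.fa")
        back = GenomeSequence.from_fasta(tmp_path / "g.fa")
        assert back.sequences == g.sequences

    def test_reverse_complement(self):
        g = GenomeSequence({"chr1": "AACGT"})
        assert g.reverse_complemented().sequences["chr1"] == "ACGTT"
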