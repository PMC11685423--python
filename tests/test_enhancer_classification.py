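"""Strand calls, six-class assignment, evidence layers, Welch activity
comparison, loop linkage and conservation profiling."""

import numpy as np
import pytest
from scipy import stats

from regcode.enhancer_classification import (
    CLASS_LABELS,
    activity_compare,
    class_counts,
    classify_enhancers,
    conservation_profile,
    evidence_fractions,
    loop_link,
    records_to_dataframe,
    strand_expression_call,
    welch_ttest,
)
from regcode.genome_io import (
    GenomicInterval,
    IntervalSet,
    LoopSet,
    StrandedSignal,
)

import pandas as pd


def _signal(plus, minus, read_length=10):
    return StrandedSignal.from_arrays(
        {"chr1": {"+": np.asarray(plus, float), "-": np.asarray(minus, float)}},
        read_length=read_length,
    )


class TestStrandExpressionCall:
    def test_zero_coverage_is_none(self):
        sig = _signal(np.zeros(100), np.zeros(100))
        call = strand_expression_call(GenomicInterval("chr1", 0, 100), sig)
        assert call.call == "none"

    def test_plus_only_threshold(self):
        plus = np.full(100, 1.2)  # area 120 / read_length 10 = 12 reads
        minus = np.full(100, 0.03)  # 0.3 reads
        sig = _signal(plus, minus)
        call = strand_expression_call(GenomicInterval("chr1", 0, 100), sig, min_reads=5)
        assert call.call == "plus_only"
        assert call.plus_reads == pytest.approx(12.0)
        assert call.minus_reads == pytest.approx(0.3)

    def test_both_strands(self):
        sig = _signal(np.full(100, 1.0), np.full(100, 1.0))
        call = strand_expression_call(GenomicInterval("chr1", 0, 100), sig, min_reads=5)
        assert call.call == "both_strands" and call.collapsed == "bidirectional"

    def test_planted_counts_thresholded_away_from_boundary(self):
        rng = np.random.default_rng(0)
        read_length = 10
        peaks, planted = [], []
        plus = np.zeros(50_000)
        minus = np.zeros(50_000)
        for i in range(100):
            s = i * 500
            c_p = float(rng.uniform(0, 12))
            c_m = float(rng.uniform(0, 12))
            plus[s : s + 400] = c_p * read_length / 400
            minus[s : s + 400] = c_m * read_length / 400
            peaks.append(GenomicInterval("chr1", s, s + 400))
            planted.append((c_p, c_m))
        sig = _signal(plus, minus, read_length)
        for peak, (c_p, c_m) in zip(peaks, planted):
            if 4 <= c_p <= 6 or 4 <= c_m <= 6:
                continue  # boundary zone excluded by design
            call = strand_expression_call(peak, sig, min_reads=5)
            expected = (
                "both_strands" if c_p >= 5 and c_m >= 5
                else "plus_only" if c_p >= 5
                else "minus_only" if c_m >= 5
                else "none"
            )
            assert call.call == expected


class TestClassify:
    def test_k4me1_within_window_bidirectional(self):
        peaks = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        k4 = IntervalSet([GenomicInterval("chr1", 2500, 3000)])  # 500 bp away
        sig = _signal(np.full(5000, 1.0), np.full(5000, 1.0))
        rec = classify_enhancers(peaks, k4, sig)[0]
        assert rec.class_label == "K4me1+:bidirectional"

    def test_no_k4me1_no_rna(self):
        peaks = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        k4 = IntervalSet([GenomicInterval("chr1", 4000, 5000)])  # 2 kb away
        sig = _signal(np.zeros(6000), np.zeros(6000))
        rec = classify_enhancers(peaks, k4, sig)[0]
        assert rec.class_label == "K4me1-:none"

    def test_negative_window_errors(self):
        peaks = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            classify_enhancers(peaks, peaks, _signal(np.zeros(10), np.zeros(10)), window_bp=-1)

    def test_full_six_class_recovery_on_bundle(self, bundle, records):
        truth = bundle.truth.enhancers
        assert len(records) == len(truth) == 600
        agree = sum(r.class_label == t for r, t in zip(records, truth["class"]))
        assert agree == 600
        counts = class_counts(records)
        assert all(counts[label] == 100 for label in CLASS_LABELS)

    def test_min_reads_monotonicity(self, bundle):
        """Raising the threshold never shrinks "none" and never grows
        "both_strands"."""
        thresholds = [1, 5, 30]
        prev_none, prev_both = -1, float("inf")
        for t in thresholds:
            recs = classify_enhancers(
                bundle.k27ac_distal, bundle.k4me1, bundle.rna, min_reads=t
            )
            counts = class_counts(recs)
            none = counts["K4me1+:none"] + counts["K4me1-:none"]
            both = counts["K4me1+:bidirectional"] + counts["K4me1-:bidirectional"]
            assert none >= prev_none
            assert both <= prev_both
            prev_none, prev_both = none, both

    def test_per_strand_evidence_retained(self, bundle, records):
        truth = bundle.truth.enhancers
        for r, (_, row) in zip(records, truth.iterrows()):
            assert r.expression.plus_reads == pytest.approx(row["plus_reads"], abs=1e-6)
            assert r.expression.minus_reads == pytest.approx(row["minus_reads"], abs=1e-6)


class TestEvidenceFractions:
    def test_simple_counting(self):
        peaks = IntervalSet([GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
        sig0 = _signal(np.zeros(10_000), np.zeros(10_000))
        recs = classify_enhancers(peaks, IntervalSet([]), sig0)
        tfbs = IntervalSet(
            [GenomicInterval("chr1", i * 1000 + 50, i * 1000 + 60) for i in range(4)]
        )
        df = evidence_fractions(recs, [tfbs], sig0)
        assert df.loc["K4me1-:none", "tfbs_fraction"] == pytest.approx(0.40)

    def test_empty_class_is_nan_not_zero(self):
        peaks = IntervalSet([GenomicInterval("chr1", 0, 100)])
        sig0 = _signal(np.zeros(200), np.zeros(200))
        recs = classify_enhancers(peaks, IntervalSet([]), sig0)
        df = evidence_fractions(recs, [], sig0)
        assert np.isnan(df.loc["K4me1+:bidirectional", "tfbs_fraction"])

    def test_planted_tfbs_and_capped_recovery(self, bundle, records):
        truth = bundle.truth.enhancers
        df = evidence_fractions(records, bundle.tfbs, bundle.rampage)
        for r, (_, row) in zip(records, truth.iterrows()):
            assert r.tfbs_hit == bool(row["tfbs"])
        # planted capped fraction for bidirectional classes is 0.5; the
        # realized rate must lie within a binomial 95% CI (n=100 per class)
        for label in ("K4me1-:bidirectional", "K4me1+:bidirectional"):
            frac = df.loc[label, "capped_bidirectional"]
            assert abs(frac - 0.5) <= 1.96 * np.sqrt(0.25 / 100)


class TestActivityCompare:
    def test_identical_classes_give_p_one(self):
        rows = []
        peaks = []
        for i in range(4):
            peaks.append(GenomicInterval("chr1", i * 1000, i * 1000 + 100))
        arr = np.ones(10_000)
        sig = StrandedSignal.from_arrays({"chr1": {"+": arr}}, stranded=False)
        rna0 = _signal(np.zeros(10_000), np.zeros(10_000))
        recs = classify_enhancers(IntervalSet(peaks[:2]), IntervalSet([]), rna0)
        k4 = IntervalSet([GenomicInterval("chr1", p.start, p.end) for p in peaks[2:]])
        recs += classify_enhancers(IntervalSet(peaks[2:]), k4, rna0)
        cmp_ = activity_compare(recs, sig)
        assert cmp_.pairwise["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        rng = np.random.default_rng(42)
        x = rng.normal(3, 1, 200)
        y = rng.normal(1, 1, 200)
        t, p = welch_ttest(x, y)
        # independent closed-form computation
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        se2 = vx / nx + vy / ny
        t_ref = (x.mean() - y.mean()) / np.sqrt(se2)
        df_ref = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert abs(t - t_ref) / abs(t_ref) < 1e-10
        assert p == pytest.approx(p_ref, rel=1e-9)
        assert p < 1e-5  # the planted Normal(3,1) vs Normal(1,1) shift

    def test_planted_class_ordering_on_bundle(self, bundle, records):
        cmp_ = activity_compare(records, bundle.activity, summary="median")
        means = {k: float(v.mean()) for k, v in cmp_.values.items()}
        for k4 in ("K4me1+", "K4me1-"):
            assert (
                means[f"{k4}:bidirectional"]
                > means[f"{k4}:unidirectional"]
                > means[f"{k4}:none"]
            )
        lookup = cmp_.pairwise.set_index(["class_a", "class_b"])["p"]
        p = lookup.get(("K4me1-:bidirectional", "K4me1-:none"))
        assert p < 1e-5


class TestLoopLink:
    def _mini(self):
        peaks = IntervalSet([GenomicInterval("chr1", 1000, 1500, name="e0"),
                             GenomicInterval("chr1", 50_000, 50_500, name="e1")])
        rna0 = _signal(np.zeros(60_000), np.zeros(60_000))
        recs = classify_enhancers(peaks, IntervalSet([]), rna0)
        genes = IntervalSet([GenomicInterval("chr1", 20_000, 22_000, name="gA"),
                             GenomicInterval("chr1", 30_000, 32_000, name="gB")])
        loops = LoopSet([(GenomicInterval("chr1", 900, 1600), GenomicInterval("chr1", 19_900, 22_100))])
        expr = pd.Series({"gA": 10.0, "gB": 1.0})
        return recs, loops, genes, expr

    def test_anchor_overlap_links_opposite_anchor_gene(self):
        recs, loops, genes, expr = self._mini()
        result = loop_link(recs, loops, genes, expr, seed=0, n_draws=5)
        assert recs[0].in_loop and recs[0].linked_genes == ["gA"]
        assert not recs[1].in_loop and recs[1].linked_genes == []
        assert result.n_in_loop == 1

    def test_empty_loopset_skips_comparison(self):
        recs, _, genes, expr = self._mini()
        result = loop_link(recs, LoopSet([]), genes, expr, seed=0)
        assert result.note.startswith("empty loop set")
        assert all(not r.in_loop for r in recs)

    def test_planted_expression_shift_recovered(self, bundle, records):
        result = loop_link(
            records, bundle.loops, bundle.genes, bundle.expression["ear"], seed=3
        )
        assert result.n_in_loop == len(bundle.loops)
        linked_median = float(np.median(result.linked_log2))
        # linked genes carry a planted +1.5 log2 shift over background
        assert linked_median > result.random_median + 0.5
        t, p = result.welch_vs_random
        assert p < 1e-3 and t > 0
        # vs genes already in loops the shift is much smaller
        shift_rand = linked_median - result.random_median
        shift_loop = linked_median - result.random_in_loop_median
        assert abs(shift_loop) < shift_rand


class TestConservationProfile:
    def test_counts(self):
        peaks = IntervalSet([GenomicInterval("chr1", 0, 1000, name="a"),
                             GenomicInterval("chr1", 5000, 6000, name="b")])
        rna0 = _signal(np.zeros(10_000), np.zeros(10_000))
        recs = classify_enhancers(peaks, IntervalSet([]), rna0)
        elements = IntervalSet(
            [GenomicInterval("chr1", 10 + 60 * i, 40 + 60 * i) for i in range(12)]
        )
        conservation_profile(recs, elements)
        assert recs[0].conserved_element_count == 12
        assert recs[1].conserved_element_count == 0

    def test_planted_counts_and_tiers_on_bundle(self, bundle, records):
        truth = bundle.truth.enhancers
        df = conservation_profile(records, bundle.conserved)
        got = np.array([r.conserved_element_count for r in records])
        assert np.array_equal(got, truth["conserved_count"].to_numpy())
        # planted per-class >=1 rates within binomial 95% CI (n=100)
        rates = bundle.config.conserved_rate
        for label in CLASS_LABELS:
            p0 = rates[label]
            assert abs(df.loc[label, "frac_ge1"] - p0) <= 1.96 * np.sqrt(
                p0 * (1 - p0) / 100
            ) + 1e-9


def test_records_dataframe_roundtrip_columns(records):
    df = records_to_dataframe(records)
    assert len(df) == len(records)
    assert {"chrom", "start", "end", "class", "rna_call"} <= set(df.columns)
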