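"""Promoter windows, peak overlap enrichment, and TE content."""

import math

import numpy as np
import pytest

from stemlinc.errors import DataError
from stemlinc.intervals import GenomicInterval
from stemlinc.regulome import (
    PeakSet,
    PromoterConfig,
    RepeatAnnotation,
    genebody_coverage,
    genebody_mark_test,
    promoter_enrichment,
    promoter_region,
    region_has_peak,
    te_content,
    te_family_enrichment,
)

from util import gene, tx


def peakset(spans, name="mark"):
    return PeakSet(name, [GenomicInterval("chr1", s, e) for s, e in spans])


class TestPromoterRegion:
    def test_plus_strand_window(self):
        t = tx("t", [(10000, 10500)], strand="+")
        r = promoter_region(t)
        assert (r.start, r.end) == (7000, 11000)

    def test_minus_strand_window(self):
        t = tx("t", [(9000, 10000)], strand="-")
        r = promoter_region(t)
        assert (r.start, r.end) == (9000, 13000)

    def test_clipped_at_chromosome_start(self):
        t = tx("t", [(500, 900)], strand="+")
        r = promoter_region(t)
        assert (r.start, r.end) == (0, 1500)

    def test_unstranded_rejected(self):
        with pytest.raises(DataError):
            promoter_region(tx("t", [(100, 200)], strand="."))

    def test_minus_is_mirror_of_plus_about_tss(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            tss = int(rng.integers(5000, 50000))
            span = int(rng.integers(100, 2000))
            plus = promoter_region(tx("p", [(tss, tss + span)], strand="+"))
            minus = promoter_region(tx("m", [(tss - span, tss)], strand="-"))
            # reflect the + window about the TSS
            assert (tss - (plus.end - tss), tss + (tss - plus.start)) == (
                minus.start, minus.end
            )


class TestPeakOverlap:
    REGION = GenomicInterval("chr1", 7000, 11000)

    def test_one_bp_overlap_counts(self):
        assert region_has_peak(self.REGION, peakset([(10999, 11500)]))

    def test_abutting_half_open_does_not(self):
        assert not region_has_peak(self.REGION, peakset([(11000, 11500)]))

    def test_empty_peak_set(self):
        assert not region_has_peak(self.REGION, peakset([]))


def simple_gene(gid, start, *, strand="+", span=1000):
    return gene(gid, [tx(f"{gid}_t", [(start, start + span)], strand=strand)])


class TestPromoterEnrichment:
    def test_extreme_separation_reference_p(self):
        group = [simple_gene(f"g{i}", 100_000 * (i + 1)) for i in range(5)]
        bg = [simple_gene(f"b{i}", 100_000 * (i + 20)) for i in range(5)]
        peaks = peakset([(g.span.start - 500, g.span.start - 300) for g in group])
        res = promoter_enrichment(group, bg, peaks)
        assert math.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_identical_rates_odds_ratio_one(self):
        group = [simple_gene(f"g{i}", 100_000 * (i + 1)) for i in range(4)]
        bg = [simple_gene(f"b{i}", 100_000 * (i + 20)) for i in range(4)]
        peaks = peakset(
            [(g.span.start - 500, g.span.start - 300) for g in group[:2] + bg[:2]]
        )
        assert promoter_enrichment(group, bg, peaks).odds_ratio == 1.0

    def test_group_subtracted_from_background(self):
        group = [simple_gene("g0", 100_000)]
        bg = group + [simple_gene("b0", 500_000)]
        res = promoter_enrichment(group, bg, peakset([]))
        assert res.a + res.b == 1 and res.c + res.d == 1

    def test_empty_background_errors(self):
        g = [simple_gene("g0", 100_000)]
        with pytest.raises(DataError):
            promoter_enrichment(g, g, peakset([]))

    def test_odds_ratio_converges_to_planted_rates(self):
        rng = np.random.default_rng(42)
        f_g, f_b = 0.7, 0.2
        group, bg, spans = [], [], []
        for i in range(400):
            g = simple_gene(f"g{i}", 50_000 * (i + 1))
            group.append(g)
            if rng.random() < f_g:
                spans.append((g.span.start - 500, g.span.start - 300))
        for i in range(400):
            b = simple_gene(f"b{i}", 50_000 * (i + 500))
            bg.append(b)
            if rng.random() < f_b:
                spans.append((b.span.start - 500, b.span.start - 300))
        res = promoter_enrichment(group, bg, peakset(spans))
        expected = (f_g / (1 - f_g)) / (f_b / (1 - f_b))
        assert res.odds_ratio == pytest.approx(expected, rel=0.35)


class TestGeneBody:
    def test_coverage_fractions(self):
        g = simple_gene("g", 10_000)
        assert genebody_coverage(g, peakset([(10_000, 11_000)])) == 1.0
        assert genebody_coverage(g, peakset([])) == 0.0
        assert genebody_coverage(g, peakset([(10_000, 10_500)])) == 0.5

    def test_rank_test_reference_p(self):
        group = [simple_gene(f"g{i}", 100_000 * (i + 1)) for i in range(3)]
        bg = [simple_gene(f"b{i}", 100_000 * (i + 20)) for i in range(3)]
        peaks = peakset([(g.span.start, g.span.end) for g in group])
        assert genebody_mark_test(group, bg, peaks).p_value == pytest.approx(1 / 20)


def repeat(s, e, name, cls, fam):
    return RepeatAnnotation(GenomicInterval("chr1", s, e), cls, fam, name)


class TestTE:
    G = gene("g", [tx("t", [(1000, 1600), (2600, 3400)])])

    def test_excluded_class_ignored(self):
        reps = [repeat(1100, 1200, "ALR/Alpha", "Satellite", "centr")]
        assert te_content(self.G, reps) == set()

    def test_name_and_family_labels_returned(self):
        reps = [repeat(1100, 1300, "HERVH-int", "LTR", "ERV1")]
        assert te_content(self.G, reps) == {"HERVH-int", "ERV1"}

    def test_intron_only_repeat_ignored(self):
        reps = [repeat(1700, 1900, "AluY", "SINE", "Alu")]
        assert te_content(self.G, reps) == set()

    def test_family_enrichment_reference_p(self):
        te = {f"a{i}": {"HERVH-int"} for i in range(3)}
        te |= {f"b{i}": {"AluY"} for i in range(3)}
        res = te_family_enrichment({"a0", "a1", "a2"}, {"b0", "b1", "b2"}, te)
        assert math.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(0.05)

    def test_pattern_matching_nothing_skipped(self):
        res = te_family_enrichment({"a"}, {"b"}, {}, family_pattern="NOPE")
        assert res.reason is not None

    def test_overlapping_groups_rejected(self):
        with pytest.raises(DataError):
            te_family_enrichment({"a"}, {"a", "b"}, {})
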