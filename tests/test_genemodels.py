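"""Gene-model parsing, filtering, merging, and the ORF surrogate."""

import numpy as np
import pytest

from stemlinc.errors import DataError, ParseError
from stemlinc.genemodels import (
    FilterConfig,
    filter_assembled_transcripts,
    filter_linc_candidates,
    merge_into_genes,
    read_gene_models,
    surrogate_coding_label,
    write_gene_models,
)
from stemlinc.intervals import GenomicInterval

from util import brute_force_components, gene, tx


class TestReadWrite:
    def test_gtf_coordinates_convert_to_half_open(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text(
            'chr1\tensembl\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'chr1\tensembl\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        )
        (t,) = read_gene_models(p, "gtf")
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        assert t.length == 200

    def test_bed12_block_count(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text(
            "chr1\t100\t1000\tt1\t0\t+\t100\t1000\t0\t3\t100,100,100\t0,300,800\n"
        )
        (t,) = read_gene_models(p, "bed12")
        assert len(t.exons) == 3
        assert t.exons[2].end == 1000

    def test_mixed_chromosomes_error_names_transcript(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text(
            'chr1\t.\texon\t1\t100\t.\t+\t.\ttranscript_id "tX";\n'
            'chr2\t.\texon\t1\t100\t.\t+\t.\ttranscript_id "tX";\n'
        )
        with pytest.raises(DataError, match="tX"):
            read_gene_models(p, "gtf")

    def test_unparseable_line_names_line_number(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ParseError, match="line 1"):
            read_gene_models(p, "gtf")

    @pytest.mark.parametrize("fmt", ["gtf", "bed12"])
    def test_round_trip_is_exact(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        ts = []
        for i in range(20):
            pos = int(rng.integers(0, 10000))
            exons, cur = [], pos
            for _ in range(int(rng.integers(1, 5))):
                s = cur + int(rng.integers(1, 50))
                e = s + int(rng.integers(1, 200))
                exons.append((s, e))
                cur = e
            ts.append(tx(f"t{i}", exons, strand="+-"[i % 2]))
        p = tmp_path / f"rt.{fmt}"
        write_gene_models(ts, p, fmt)
        back = read_gene_models(p, fmt)
        assert [t.exon_chain for t in back] == [t.exon_chain for t in ts]


class TestFilter:
    KNOWN = [gene("kg", [tx("kt", [(1000, 2000)], coding_label="coding")])]

    def reasons(self, report):
        return dict(zip(report["transcript_id"], report["reason"]))

    def test_rejection_reasons(self):
        ts = [
            tx("short", [(0, 100), (200, 250)], coding_label="noncoding"),
            tx("mono", [(5000, 5500)], coding_label="noncoding"),
            tx("coding", [(7000, 7300), (7500, 7800)], coding_label="coding"),
            # exon overlapping the known exon by exactly 1 bp
            tx("ovl", [(800, 1001), (1200, 1400)], coding_label="noncoding"),
            tx("good", [(3000, 3300), (3500, 3800)], coding_label="noncoding"),
        ]
        kept, report = filter_linc_candidates(ts, self.KNOWN)
        assert [t.transcript_id for t in kept] == ["good"]
        assert self.reasons(report) == {
            "short": "length",
            "mono": "exon_count",
            "coding": "coding_label",
            "ovl": "overlap",
            "good": "",
        }

    def test_length_threshold_is_strict(self):
        t200 = tx("t200", [(0, 100), (200, 300)], coding_label="noncoding")
        t201 = tx("t201", [(0, 100), (200, 301)], coding_label="noncoding")
        kept, _ = filter_linc_candidates([t200, t201], [])
        assert [t.transcript_id for t in kept] == ["t201"]

    def test_known_overlap_is_strand_ignorant_by_default(self):
        anti = tx("anti", [(900, 1200), (1500, 1800)], strand="-",
                  coding_label="noncoding")
        kept, _ = filter_linc_candidates([anti], self.KNOWN)
        assert kept == []
        kept, _ = filter_linc_candidates([anti], self.KNOWN, strand_aware=True)
        assert [t.transcript_id for t in kept] == ["anti"]

    def test_empty_input(self):
        kept, report = filter_linc_candidates([], self.KNOWN)
        assert kept == [] and len(report) == 0


class TestMerge:
    def test_identical_chains_collapse_by_source_priority(self):
        a = tx("ENST1", [(0, 100), (200, 300)], source="ensembl")
        b = tx("uc001", [(0, 100), (200, 300)], source="ucsc")
        (g,) = merge_into_genes([a, b])
        assert [t.transcript_id for t in g.transcripts] == ["ENST1"]

    def test_transitive_overlap_chains_one_gene(self):
        a = tx("A", [(0, 100)])
        b = tx("B", [(50, 150)])
        c = tx("C", [(140, 200)])
        genes = merge_into_genes([a, b, c])
        assert len(genes) == 1
        assert {t.transcript_id for t in genes[0].transcripts} == {"A", "B", "C"}

    def test_opposite_strands_stay_separate(self):
        a = tx("A", [(0, 100)], strand="+")
        b = tx("B", [(0, 100)], strand="-")
        assert len(merge_into_genes([a, b])) == 2

    def test_abutting_exons_do_not_merge(self):
        a = tx("A", [(0, 100)])
        b = tx("B", [(100, 200)])
        assert len(merge_into_genes([a, b])) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        ts = []
        for i in range(200):
            start = int(rng.integers(0, 5000))
            exons, cur = [], start
            for _ in range(int(rng.integers(1, 4))):
                s = cur + int(rng.integers(0, 100)) + 1
                e = s + int(rng.integers(1, 150))
                exons.append((s, e))
                cur = e
            ts.append(
                tx(f"t{i}", exons, chrom=f"chr{rng.integers(1, 3)}",
                   strand="+-"[int(rng.integers(2))])
            )
        genes = merge_into_genes(ts)
        got = {
            frozenset(t.transcript_id for t in g.transcripts) for g in genes
        }
        # brute-force components, then collapse identical chains the same way
        comps = brute_force_components(ts)
        by_id = {t.transcript_id: t for t in ts}
        expected = []
        for comp in comps:
            chains = {}
            for tid in comp:
                chains.setdefault(by_id[tid].exon_chain, []).append(tid)
            expected.append(
                frozenset(min(v) for v in chains.values())
            )
        assert got == set(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        ts = [
            tx(f"t{i}", [(int(s), int(s) + 50)])
            for i, s in enumerate(rng.integers(0, 500, size=40))
        ]
        ref = {
            g.gene_id: {t.transcript_id for t in g.transcripts}
            for g in merge_into_genes(ts)
        }
        perm = list(ts)
        rng.shuffle(perm)
        got = {
            g.gene_id: {t.transcript_id for t in g.transcripts}
            for g in merge_into_genes(perm)
        }
        assert got == ref


class TestAssembledFilter:
    T = tx("nov", [(0, 200), (300, 600)], coding_label="noncoding",
           source="assembled")

    def test_kept_when_all_thresholds_met(self):
        out = filter_assembled_transcripts(
            [self.T], {"nov": 5.0}, {"nov": [10]}, FilterConfig()
        )
        assert [t.transcript_id for t in out] == ["nov"]

    @pytest.mark.parametrize(
        "fpkm,support", [(0.2, [10]), (5.0, [0])]
    )
    def test_low_expression_or_weak_junction_rejected(self, fpkm, support):
        out = filter_assembled_transcripts(
            [self.T], {"nov": fpkm}, {"nov": support}, FilterConfig()
        )
        assert out == []

    def test_missing_entries_name_the_transcript(self):
        with pytest.raises(DataError, match="nov"):
            filter_assembled_transcripts([self.T], {}, {"nov": [10]})
        with pytest.raises(DataError, match="nov"):
            filter_assembled_transcripts([self.T], {"nov": 5.0}, {})


class TestOrfSurrogate:
    def test_no_orf_is_noncoding(self):
        assert surrogate_coding_label("A" * 300) == "noncoding"

    def test_long_orf_is_coding(self):
        seq = "ATG" + "GCT" * 150 + "TAA"
        assert surrogate_coding_label(seq) == "coding"

    def test_short_orf_below_threshold(self):
        seq = "ATG" + "GCT" * 50 + "TAA"
        assert surrogate_coding_label(seq) == "noncoding"
        assert surrogate_coding_label(seq, max_orf_aa=10) == "coding"

    def test_orf_requires_stop(self):
        assert surrogate_coding_label("ATG" + "GCT" * 200) == "noncoding"

    @pytest.mark.parametrize("bad", ["", "ACGU", "ACGTX"])
    def test_invalid_sequences_error(self, bad):
        with pytest.raises(DataError):
            surrogate_coding_label(bad)
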