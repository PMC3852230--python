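"""Chromatin-mark / TF-binding enrichment and transposable-element content.

Promoters are strand-aware windows 3 kb upstream to 1 kb downstream of
the transcription start site. Promoter-biased marks and transcription
factor binding are scored as any >= 1 bp peak overlap with the promoter
window (Fisher's exact test, group vs background); gene-body marks are
compared by the fraction of the gene span covered by peaks (rank-sum
test). Transposable-element content intersects repeat annotation with
exons, after excluding the Satellite / Low_complexity / Simple_repeat
classes, and tests whether one gene set preferentially holds a repeat
family (substring match on repeat name and family, e.g. "HERVH").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .genemodels import Gene, Transcript
from .intervals import GenomicInterval, merge_intervals
from .stats import (
    ContingencyTable2x2,
    EnrichmentResult,
    TestResult,
    fisher_exact,
    odds_ratio,
    ranksum_test,
)

DEFAULT_EXCLUDED_CLASSES = frozenset({"Satellite", "Low_complexity", "Simple_repeat"})


@dataclass
class PromoterConfig:
    upstream: int = 3000
    downstream: int = 1000

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise DataError("promoter extents must be >= 0")
        if self.upstream == 0 and self.downstream == 0:
            raise DataError("promoter window cannot be empty")


@dataclass
class PeakSet:
    """Called peaks for one mark or factor; scores optional."""

    name: str
    peaks: list[GenomicInterval]
    scores: list[float] | None = None

    def __post_init__(self):
        if self.scores is not None:
            if len(self.scores) != len(self.peaks):
                raise DataError(f"peak set {self.name}: score/peak mismatch")
            if any(s < 0 for s in self.scores):
                raise DataError(f"peak set {self.name}: negative score")
        self._trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "PeakSet":
        peaks, scores = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                peaks.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
                scores.append(float(f[4]) if len(f) > 4 else 0.0)
        return cls(name or Path(path).stem, peaks, scores)

    def overlaps(self, region: GenomicInterval) -> bool:
        tree = self._trees.get(region.chrom)
        return bool(tree and tree.overlap(region.start, region.end))

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(region.chrom)
        if not tree:
            return []
        return [
            GenomicInterval(region.chrom, iv.begin, iv.end)
            for iv in tree.overlap(region.start, region.end)
        ]


@dataclass
class RepeatAnnotation:
    interval: GenomicInterval
    repeat_class: str
    repeat_family: str
    repeat_name: str


def read_repeats_tsv(path: str | Path) -> list[RepeatAnnotation]:
    """Read an rmsk-style repeat table (genoName/genoStart/genoEnd/repName/repClass/repFamily)."""
    df = pd.read_csv(path, sep="\t")
    required = {"genoName", "genoStart", "genoEnd", "repName", "repClass", "repFamily"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"repeat table missing columns: {sorted(missing)}")
    return [
        RepeatAnnotation(
            GenomicInterval(r.genoName, int(r.genoStart), int(r.genoEnd)),
            r.repClass,
            r.repFamily,
            r.repName,
        )
        for r in df.itertuples()
    ]


def promoter_region(t: Transcript, cfg: PromoterConfig | None = None) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at position 0."""
    cfg = cfg or PromoterConfig()
    if t.strand == "+":
        tss = t.span.start
        start, end = max(0, tss - cfg.upstream), tss + cfg.downstream
    elif t.strand == "-":
        tss = t.span.end
        start, end = max(0, tss - cfg.downstream), tss + cfg.upstream
    else:
        raise DataError(f"transcript {t.transcript_id}: unstranded, no TSS")
    return GenomicInterval(t.chrom, start, end, t.strand)


def gene_promoters(gene: Gene, cfg: PromoterConfig | None = None) -> list[GenomicInterval]:
    """Union of the promoter windows of a gene's transcripts."""
    return merge_intervals(promoter_region(t, cfg) for t in gene.transcripts)


def region_has_peak(region: GenomicInterval, peaks: PeakSet) -> bool:
    """True iff any peak overlaps the region by >= 1 bp (half-open)."""
    return peaks.overlaps(region)


def _dedupe(genes: Iterable[Gene]) -> dict[str, Gene]:
    return {g.gene_id: g for g in genes}


def promoter_enrichment(
    group: Sequence[Gene],
    background: Sequence[Gene],
    peaks: PeakSet,
    cfg: PromoterConfig | None = None,
) -> EnrichmentResult:
    """Fisher test (one-sided greater) of promoter peak presence.

    A gene counts as peaked when any of its transcript promoters overlaps
    a peak. Genes appearing in both sets are removed from the background
    first.
    """
    grp = _dedupe(group)
    bg = {k: v for k, v in _dedupe(background).items() if k not in grp}
    if not bg:
        raise DataError("empty background after removing the group")

    def peaked(g: Gene) -> bool:
        return any(region_has_peak(r, peaks) for r in gene_promoters(g, cfg))

    a = sum(1 for g in grp.values() if peaked(g))
    b = len(grp) - a
    c = sum(1 for g in bg.values() if peaked(g))
    d = len(bg) - c
    tr = fisher_exact(ContingencyTable2x2(a, b, c, d), "greater")
    return EnrichmentResult(peaks.name, a, b, c, d, tr.statistic, tr.p_value)


def genebody_coverage(gene: Gene, peaks: PeakSet) -> float:
    """Fraction of the gene span covered by the union of overlapping peaks."""
    span = gene.span
    hits = peaks.overlapping(span)
    if not hits:
        return 0.0
    from .evolution import coverage_fraction

    return coverage_fraction(span, hits)


def genebody_mark_test(
    group: Sequence[Gene],
    background: Sequence[Gene],
    peaks: PeakSet,
    sidedness: str = "greater",
) -> TestResult:
    """Rank-sum test on gene-body peak coverage, group vs background."""
    grp = _dedupe(group)
    bg = {k: v for k, v in _dedupe(background).items() if k not in grp}
    if not grp or not bg:
        raise DataError("both gene sets must be non-empty")
    cov_g = [genebody_coverage(g, peaks) for g in grp.values()]
    cov_b = [genebody_coverage(g, peaks) for g in bg.values()]
    return ranksum_test(cov_g, cov_b, sidedness=sidedness)


def te_content(
    gene: Gene,
    repeats: Sequence[RepeatAnnotation],
    excluded_classes: frozenset = DEFAULT_EXCLUDED_CLASSES,
) -> set[str]:
    """Repeat name and family labels overlapping the gene's exons.

    Repeats in the excluded classes (satellite, low-complexity, simple
    repeats by default) are ignored; intron-only repeats do not count.
    """
    labels: set[str] = set()
    for rep in repeats:
        if rep.repeat_class in excluded_classes:
            continue
        if any(rep.interval.overlaps(e) for e in gene.exons):
            labels.add(rep.repeat_name)
            labels.add(rep.repeat_family)
    return labels


def te_family_enrichment(
    group_a: set[str],
    group_b: set[str],
    te_by_gene: Mapping[str, set[str]],
    family_pattern: str = "HERVH",
) -> EnrichmentResult:
    """Fisher test (one-sided greater for group a) of family-holding genes.

    A gene holds the family iff any of its overlapping repeat labels
    contains ``family_pattern`` as a case-sensitive substring. When no
    gene in either group holds the family the test is skipped with a
    reason.
    """
    if group_a & group_b:
        raise DataError("gene groups must be disjoint")

    def holds(g: str) -> bool:
        return any(family_pattern in lab for lab in te_by_gene.get(g, ()))

    a = sum(1 for g in group_a if holds(g))
    c = sum(1 for g in group_b if holds(g))
    b, d = len(group_a) - a, len(group_b) - c
    res = EnrichmentResult(family_pattern, a, b, c, d, float("nan"), float("nan"))
    if a + c == 0:
        res.reason = "family held by no gene"
        return res
    tr = fisher_exact(ContingencyTable2x2(a, b, c, d), "greater")
    res.odds_ratio, res.p_value = tr.statistic, tr.p_value
    return res
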