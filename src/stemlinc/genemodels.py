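"""Gene-model I/O, lincRNA candidate filtering, and redundancy merging.

A lincRNA (long intergenic non-coding RNA) catalog is built conservatively:
only multi-exon transcripts longer than 200 bp that do not overlap any exon
of a known gene and that carry a non-coding label are kept, and redundant
models from the different source annotations are merged by genomic
coordinate into standalone genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError, ParseError
from .intervals import GenomicInterval

SOURCES = ("ensembl", "ucsc", "refseq", "assembled", "other")
_SOURCE_PRIORITY = {s: i for i, s in enumerate(SOURCES)}
CODING_LABELS = ("coding", "noncoding", "unknown")

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class Transcript:
    """An exon chain on one chromosome and strand.

    Exons are stored sorted by start in the internal 0-based half-open
    convention and must be non-overlapping.
    """

    transcript_id: str
    exons: list[GenomicInterval]
    gene_id: str = ""
    source: str = "other"
    coding_label: str = "unknown"

    def __post_init__(self):
        if not self.exons:
            raise DataError(f"transcript {self.transcript_id}: no exons")
        if self.source not in _SOURCE_PRIORITY:
            raise DataError(
                f"transcript {self.transcript_id}: unknown source {self.source!r}"
            )
        if self.coding_label not in CODING_LABELS:
            raise DataError(
                f"transcript {self.transcript_id}: bad coding label "
                f"{self.coding_label!r}"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise DataError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise DataError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in bp."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exon_chain(self) -> tuple:
        """Hashable identity of the exon structure."""
        return (self.chrom, self.strand, tuple((e.start, e.end) for e in self.exons))

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron junctions as (donor exon end, acceptor exon start) pairs."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class Gene:
    """A merged locus: one or more transcripts on the same chrom/strand."""

    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self):
        if not self.transcripts:
            raise DataError(f"gene {self.gene_id}: no transcripts")
        if len({t.chrom for t in self.transcripts}) > 1 or len(
            {t.strand for t in self.transcripts}
        ) > 1:
            raise DataError(
                f"gene {self.gene_id}: transcripts on different chrom/strand"
            )
        self.transcripts = sorted(self.transcripts, key=lambda t: t.transcript_id)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


@dataclass
class FilterConfig:
    """Thresholds of the lincRNA candidate filter.

    min_length is exclusive (spliced length must be > 200 bp by default);
    min_exons is the minimum exon count (multi-exon = 2); the novel-transcript
    thresholds apply only to de novo assembled models.
    """

    min_length: int = 200
    min_exons: int = 2
    min_fpkm_novel: float = 1.0
    min_junction_reads: int = 2

    def __post_init__(self):
        if min(self.min_length, self.min_exons, self.min_fpkm_novel,
               self.min_junction_reads) < 0:
            raise DataError("filter thresholds must be >= 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_models(
    path: str | Path,
    format: str = "gtf",
    default_source: str = "other",
    default_coding_label: str = "unknown",
) -> list[Transcript]:
    """Read transcripts from a GTF (Ensembl dialect) or BED12 file.

    GTF coordinates (1-based inclusive) and BED (0-based half-open) are both
    converted to the internal 0-based half-open convention. Only ``exon``
    features of a GTF are consumed; other feature types are ignored.
    """
    path = Path(path)
    if format == "gtf":
        return _read_gtf(path, default_source, default_coding_label)
    if format == "bed12":
        return _read_bed12(path, default_source, default_coding_label)
    raise DataError(f"unknown gene-model format {format!r}")


def _read_gtf(path: Path, default_source: str, default_label: str) -> list[Transcript]:
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, source)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GTF fields")
            chrom, src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise ParseError(f"{path} line {lineno}: missing transcript_id")
            if tid not in exons:
                order.append(tid)
                source = src.lower() if src.lower() in _SOURCE_PRIORITY else default_source
                meta[tid] = (attr.get("gene_id", ""), source)
                exons[tid] = []
            exons[tid].append(iv)
    out = []
    for tid in order:
        gene_id, source = meta[tid]
        out.append(
            Transcript(tid, exons[tid], gene_id=gene_id, source=source,
                       coding_label=default_label)
        )
    return out


def _read_bed12(path: Path, default_source: str, default_label: str) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path} line {lineno}: expected 12 BED fields")
            try:
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(
                    f"{path} line {lineno}: blockCount does not match block lists"
                )
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            out.append(
                Transcript(name, exons, source=default_source,
                           coding_label=default_label)
            )
    return out


def write_gene_models(
    transcripts: Sequence[Transcript], path: str | Path, format: str = "gtf"
) -> None:
    """Write transcripts as GTF (1-based inclusive) or BED12 (0-based)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gtf":
            for t in transcripts:
                for e in t.exons:
                    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(
                        f"{t.chrom}\t{t.source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{t.strand}\t.\t{attrs}\n"
                    )
        elif format == "bed12":
            for t in transcripts:
                span = t.span
                sizes = ",".join(str(e.length) for e in t.exons)
                starts = ",".join(str(e.start - span.start) for e in t.exons)
                fh.write(
                    f"{t.chrom}\t{span.start}\t{span.end}\t{t.transcript_id}\t0\t"
                    f"{t.strand}\t{span.start}\t{span.end}\t0\t{len(t.exons)}\t"
                    f"{sizes}\t{starts}\n"
                )
        else:
            raise DataError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _exon_tree(genes: Iterable[Gene], by_strand: bool) -> dict:
    trees: dict = {}
    for g in genes:
        for e in g.exons:
            key = (e.chrom, e.strand) if by_strand else e.chrom
            trees.setdefault(key, IntervalTree()).addi(e.start, e.end)
    return trees


REJECT_REASONS = ("length", "exon_count", "coding_label", "overlap")


def filter_linc_candidates(
    transcripts: Sequence[Transcript],
    known: Sequence[Gene],
    cfg: FilterConfig | None = None,
    strand_aware: bool = False,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Apply the conservative lincRNA candidate filter.

    Keeps multi-exon transcripts with spliced length strictly above
    ``cfg.min_length``, a ``noncoding`` label, and no exonic overlap with
    any exon of a known gene. Overlap is strand-ignorant by default
    (intergenicity is a genomic property); set ``strand_aware=True`` for the
    same-strand-only variant.

    Returns the kept transcripts and a per-transcript report with the
    primary rejection reason (first failure in the fixed order
    length, exon_count, coding_label, overlap) and the full reason list.
    """
    cfg = cfg or FilterConfig()
    trees = _exon_tree(known, strand_aware)
    kept: list[Transcript] = []
    rows = []
    for t in transcripts:
        reasons = []
        if t.length <= cfg.min_length:
            reasons.append("length")
        if len(t.exons) < cfg.min_exons:
            reasons.append("exon_count")
        if t.coding_label != "noncoding":
            reasons.append("coding_label")
        key = (t.chrom, t.strand) if strand_aware else t.chrom
        tree = trees.get(key)
        if tree is not None and any(tree.overlap(e.start, e.end) for e in t.exons):
            reasons.append("overlap")
        if not reasons:
            kept.append(t)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "kept": not reasons,
                "reason": reasons[0] if reasons else "",
                "reasons": ";".join(reasons),
            }
        )
    return kept, pd.DataFrame(rows, columns=["transcript_id", "kept", "reason", "reasons"])


def merge_into_genes(transcripts: Sequence[Transcript]) -> list[Gene]:
    """Merge transcripts into genes by transitive same-strand exonic overlap.

    Two transcripts belong to the same gene iff they are connected
    (transitively) through exon pairs sharing >= 1 bp on the same strand.
    Transcripts with identical exon chains are collapsed to a single
    representative chosen by source priority (ensembl > ucsc > refseq >
    assembled > other) then lexicographic transcript id. The result is
    invariant to input order: genes are sorted by coordinate and gene ids
    are taken from member transcripts when present, else generated.
    """
    ts = list(transcripts)
    n = len(ts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # sweep exons per (chrom, strand): overlapping-interval clusters are
    # exactly the connected components of the pairwise exon-overlap graph
    by_cs: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, t in enumerate(ts):
        for e in t.exons:
            by_cs.setdefault((t.chrom, t.strand), []).append((e.start, e.end, i))
    for exons in by_cs.values():
        exons.sort()
        cluster_rep, cluster_end = None, -1
        for start, end, i in exons:
            if cluster_rep is not None and start < cluster_end:
                union(i, cluster_rep)
                cluster_end = max(cluster_end, end)
            else:
                cluster_rep, cluster_end = i, end

    groups: dict[int, list[Transcript]] = {}
    for i, t in enumerate(ts):
        groups.setdefault(find(i), []).append(t)

    genes: list[Gene] = []
    for members in groups.values():
        # collapse identical exon chains
        by_chain: dict[tuple, list[Transcript]] = {}
        for t in members:
            by_chain.setdefault(t.exon_chain, []).append(t)
        reps = [
            min(v, key=lambda t: (_SOURCE_PRIORITY[t.source], t.transcript_id))
            for v in by_chain.values()
        ]
        genes.append(Gene("", reps))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.span.end, g.strand))
    for i, g in enumerate(genes):
        member_ids = sorted(t.gene_id for t in g.transcripts if t.gene_id)
        g.gene_id = member_ids[0] if member_ids else f"LINCG{i + 1:05d}"
    return genes


def filter_assembled_transcripts(
    transcripts: Sequence[Transcript],
    fpkm: Mapping[str, float],
    junction_support: Mapping[str, Sequence[int]],
    cfg: FilterConfig | None = None,
    known: Sequence[Gene] = (),
) -> list[Transcript]:
    """Filter de novo assembled transcripts.

    On top of the structural lincRNA filter, suspicious models with low
    expression (FPKM below ``min_fpkm_novel``) or weak junction support
    (any junction with fewer than ``min_junction_reads`` reads) are removed.
    """
    cfg = cfg or FilterConfig()
    structural, _ = filter_linc_candidates(transcripts, known, cfg)
    out = []
    for t in structural:
        if t.transcript_id not in fpkm:
            raise DataError(f"no FPKM value for transcript {t.transcript_id}")
        if t.transcript_id not in junction_support:
            raise DataError(f"no junction support for transcript {t.transcript_id}")
        support = list(junction_support[t.transcript_id])
        if len(support) != len(t.junctions):
            raise DataError(
                f"transcript {t.transcript_id}: {len(support)} junction support "
                f"values for {len(t.junctions)} junctions"
            )
        if fpkm[t.transcript_id] < cfg.min_fpkm_novel:
            continue
        if any(s < cfg.min_junction_reads for s in support):
            continue
        out.append(t)
    return out


_STOPS = {"TAA", "TAG", "TGA"}


def surrogate_coding_label(sequence: str, max_orf_aa: int = 100) -> str:
    """Rule-of-thumb coding-potential label from ORF length.

    Scans the three forward frames of the mature transcript for ATG→stop
    open reading frames and labels the transcript ``coding`` iff the
    longest ORF spans at least ``max_orf_aa`` codons (ATG included, stop
    excluded). This is deliberately simple plumbing for workflows where no
    external coding-potential classification is available as input.
    """
    if not sequence:
        raise DataError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise DataError("sequence contains non-ACGTN characters")
    longest = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    longest = max(longest, (i - start) // 3)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return "coding" if longest >= max_orf_aa else "noncoding"
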