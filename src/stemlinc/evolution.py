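"""Homolog calling and strict-parsimony evolutionary dating of lincRNAs.

A lincRNA has a homolog in another species when cross-species genome
alignment blocks (in focal-genome coordinates) cover strictly more than
80% of the locus. Dating follows a strict parsimony rule on a rooted
species tree: a gene is assigned to the branch subtending the unique
nested clade (on the path from the focal leaf to the root) whose members
are exactly the species with a homolog plus the focal species; any patchy
presence pattern is left undated.

The default tree is the seven-taxon mammalian tree
(((((( human, chimp), gorilla), orangutan), rhesus), marmoset), mouse).
Ordinal ages count nested clades outward: 0 = focal-specific, up to
(number of leaves − 1) = root.

A derived-allele-frequency (DAF) summary over the exons flags genes under
putative intra-population purifying selection (mean DAF strictly below
0.1).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Phylo

from .errors import DataError
from .genemodels import Gene
from .intervals import GenomicInterval, intersect_length, total_length
from .stats import TestResult, ranksum_test

logger = logging.getLogger(__name__)

DEFAULT_NEWICK = "((((((human,chimp),gorilla),orangutan),rhesus),marmoset),mouse);"


class SpeciesTree:
    """A rooted species tree with a designated focal leaf."""

    def __init__(self, tree, focal: str = "human"):
        self.tree = tree
        names = [leaf.name for leaf in tree.get_terminals()]
        if len(set(names)) != len(names):
            raise DataError("species tree has duplicate leaf names")
        if focal not in names:
            raise DataError(f"focal leaf {focal!r} not in tree")
        self.focal = focal
        self.leaves = frozenset(names)

    @classmethod
    def from_newick(cls, source: str | Path, focal: str = "human") -> "SpeciesTree":
        """Load from a newick file path or a newick string."""
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
            tree = Phylo.read(str(source), "newick")
        else:
            tree = Phylo.read(io.StringIO(str(source)), "newick")
        return cls(tree, focal=focal)

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls.from_newick(DEFAULT_NEWICK)

    def nested_clades(self) -> list[frozenset]:
        """Leaf sets of the clades on the focal→root path, smallest first.

        Element 0 is {focal}; the last element is the full leaf set.
        """
        target = next(
            leaf for leaf in self.tree.get_terminals() if leaf.name == self.focal
        )
        path = [self.tree.root] + self.tree.get_path(target)
        clades = [
            frozenset(leaf.name for leaf in node.get_terminals())
            for node in reversed(path)
        ]
        return clades


@dataclass
class DatingResult:
    """Branch assignment of one gene; ``branch`` is the clade's leaf set."""

    gene_id: str
    branch: tuple[str, ...] | None
    age: int | None  # ordinal: 0 = focal-specific, max = root

    @property
    def dated(self) -> bool:
        return self.branch is not None


def coverage_fraction(
    locus: Sequence[GenomicInterval] | GenomicInterval,
    blocks: Sequence[GenomicInterval],
) -> float:
    """Fraction of the locus covered by the union of the blocks.

    Interval arithmetic on the union makes double counting impossible; the
    result is invariant to block order and to splitting blocks.
    """
    loci = [locus] if isinstance(locus, GenomicInterval) else list(locus)
    if not loci:
        raise DataError("empty locus")
    denom = total_length(loci)
    if not blocks:
        return 0.0
    return intersect_length(loci, blocks) / denom


def call_homologs(
    gene: Gene,
    blocks_by_species: Mapping[str, Sequence[GenomicInterval]],
    cutoff: float = 0.8,
    use_exons: bool = False,
    species: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Per-species homolog presence from alignment coverage.

    A species is called present iff the union of its blocks covers
    strictly more than ``cutoff`` of the gene locus (the gene span by
    default; the exon union with ``use_exons=True``). Species listed in
    ``species`` but missing from the input are treated as absent and
    logged.
    """
    locus = gene.exons if use_exons else [gene.span]
    wanted = list(species) if species is not None else sorted(blocks_by_species)
    pv: dict[str, bool] = {}
    for sp in wanted:
        if sp not in blocks_by_species:
            logger.warning("species %s missing from alignments; treated as absent", sp)
            pv[sp] = False
            continue
        blocks = [
            b for b in blocks_by_species[sp] if b.chrom == gene.chrom
        ]
        pv[sp] = coverage_fraction(locus, blocks) > cutoff
    return pv


def date_gene(
    pv: Mapping[str, bool], tree: SpeciesTree, gene_id: str = ""
) -> DatingResult:
    """Strict-parsimony dating of one presence/absence vector.

    The present set (plus the focal species) must exactly equal one of the
    nested clades on the focal→root path; otherwise the gene is undated.
    """
    extra = set(pv) - (tree.leaves - {tree.focal})
    if extra:
        raise DataError(f"presence vector names unknown species: {sorted(extra)}")
    present = frozenset({tree.focal} | {s for s, v in pv.items() if v})
    for age, clade in enumerate(tree.nested_clades()):
        if clade == present:
            return DatingResult(gene_id, tuple(sorted(clade)), age)
    return DatingResult(gene_id, None, None)


def compare_age_distributions(
    ages_a: Sequence[int], ages_b: Sequence[int], sidedness: str = "less"
) -> TestResult:
    """Rank-sum comparison of two sets of ordinal branch ages.

    ``less`` tests whether group a is younger (smaller ordinal age) than
    group b.
    """
    if not len(ages_a) or not len(ages_b):
        raise DataError("age comparison needs two non-empty groups")
    return ranksum_test(ages_a, ages_b, sidedness=sidedness)


@dataclass
class DafResult:
    gene_id: str
    mean_daf: float | None
    purifying: bool | None


def mean_daf(
    gene: Gene,
    variants: Sequence[tuple[int, float]] | Sequence[tuple[str, int, float]],
    cutoff: float = 0.1,
) -> DafResult:
    """Mean derived allele frequency over variants inside the gene's exons.

    Variants are (position, DAF) pairs or (chrom, position, DAF) triples;
    positions are 0-based. Returns mean None when no variant overlaps an
    exon; the purifying flag is mean < cutoff (strict).
    """
    values = []
    for var in variants:
        if len(var) == 3:
            chrom, pos, daf = var
            if chrom != gene.chrom:
                continue
        else:
            pos, daf = var
        if not 0 <= daf <= 1:
            raise DataError(f"DAF {daf} outside [0, 1]")
        if any(e.start <= pos < e.end for e in gene.exons):
            values.append(daf)
    if not values:
        return DafResult(gene.gene_id, None, None)
    m = sum(values) / len(values)
    return DafResult(gene.gene_id, m, m < cutoff)
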