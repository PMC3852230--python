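"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated at desk scale on a toy
genome (two 10 Mb chromosomes by default): gene models for coding genes
and lincRNA candidates (including contaminants that each violate exactly
one catalog filter), a group-structured FPKM matrix with planted
ES-exclusive genes and planted co-expression modules, a small GO-like DAG
with a designated slim subset, per-species alignment blocks realizing
chosen gene ages on the default mammalian tree, ChIP peaks enriched at
chosen promoters and gene bodies, repeats including a HERVH-like family,
and variants with chosen derived-allele-frequency distributions.

All generators are pure functions of the configuration (seed included):
rerunning with the same config writes byte-identical files. Each bundle
ships a machine-readable ``truth.json`` recording what was planted, for
end-to-end verification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .evolution import SpeciesTree

TISSUES = (
    "adipose", "adrenal", "brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "lymph_node", "muscle", "ovary", "prostate", "skin",
    "testis", "thyroid",
)

HES = "hES"


@dataclass
class SynthConfig:
    """Study conditions of the synthetic bundle.

    Defaults emulate the real study at desk scale: a few hundred coding
    genes and lincRNAs, an over-represented ES sample group summarized by
    its median, 16 adult tissues with one sample each, five planted
    co-expression modules each tied to one ontology leaf term, twenty
    planted ES-exclusive lincRNAs, and planted gene ages spanning every
    branch of the seven-taxon tree.
    """

    seed: int = 0
    n_coding: int = 500
    n_linc: int = 200
    n_tissues: int = 16
    n_hes_samples: int = 5
    n_modules: int = 5
    module_lincs: int = 4
    module_coding: int = 10
    n_hes_specific: int = 20
    n_contaminants: int = 10  # per violation class
    n_patchy: int = 10
    n_purifying: int = 15
    n_decoy_terms: int = 10
    peak_enrichment: tuple[float, float] = (0.9, 0.1)
    hervh_rates: tuple[float, float] = (0.8, 0.05)
    noise_sd: float = 0.0
    chrom_length: int = 10_000_000
    n_chroms: int = 2
    slot: int = 20_000
    age_assignments: dict | None = None

    def __post_init__(self):
        if min(self.n_coding, self.n_linc, self.n_hes_specific,
               self.n_modules) < 0:
            raise ConfigError("counts must be >= 0")
        for r in (*self.peak_enrichment, *self.hervh_rates):
            if not 0 <= r <= 1:
                raise ConfigError("rates must be in [0, 1]")
        planted = (self.n_hes_specific + self.n_modules * self.module_lincs
                   + self.n_patchy)
        if planted > self.n_linc:
            raise ConfigError("planted lincRNAs exceed n_linc")
        if self.n_modules * self.module_coding > self.n_coding:
            raise ConfigError("planted module coding genes exceed n_coding")
        if self.n_tissues > len(TISSUES):
            raise ConfigError(f"at most {len(TISSUES)} tissues supported")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, stream])


def _slots(cfg: SynthConfig, n_needed: int) -> list[tuple[str, int]]:
    per_chrom = cfg.chrom_length // cfg.slot
    if n_needed > per_chrom * cfg.n_chroms:
        raise DataError(
            f"cannot pack {n_needed} loci into {cfg.n_chroms} chromosomes "
            f"of {cfg.chrom_length} bp at slot width {cfg.slot}"
        )
    out = []
    for i in range(n_needed):
        chrom = f"chr{i // per_chrom + 1}"
        out.append((chrom, (i % per_chrom) * cfg.slot))
    return out


def _conditions(cfg: SynthConfig) -> list[str]:
    return [HES] + sorted(TISSUES[: cfg.n_tissues])


def _linc_roles(cfg: SynthConfig) -> dict:
    """Partition linc indices into planted roles (deterministic layout)."""
    ids = [f"LINC{i:04d}" for i in range(cfg.n_linc)]
    hes = ids[: cfg.n_hes_specific]
    modules = []
    p = cfg.n_hes_specific
    for m in range(cfg.n_modules):
        modules.append(ids[p : p + cfg.module_lincs])
        p += cfg.module_lincs
    patchy = ids[cfg.n_linc - cfg.n_patchy :] if cfg.n_patchy else []
    purifying = ids[p : p + cfg.n_purifying]
    return {"ids": ids, "hes": hes, "modules": modules, "patchy": patchy,
            "purifying": purifying}


# ---------------------------------------------------------------------------
# Gene models, repeats
# ---------------------------------------------------------------------------

def gen_annotation(cfg: SynthConfig, outdir: Path) -> dict:
    """Write known coding GTF, linc candidate GTF, CPC-like labels, repeats.

    Contaminant candidates violate exactly one filter each (too short,
    single exon, or exon-overlapping a coding gene) so the downstream
    rejection report can be checked against planted counts.
    """
    roles = _linc_roles(cfg)
    n_slots = cfg.n_coding + cfg.n_linc + 2 * cfg.n_contaminants
    slots = _slots(cfg, n_slots)
    coding_slots = slots[: cfg.n_coding]
    linc_slots = slots[cfg.n_coding : cfg.n_coding + cfg.n_linc]
    extra = slots[cfg.n_coding + cfg.n_linc :]
    short_slots = extra[: cfg.n_contaminants]
    single_slots = extra[cfg.n_contaminants :]

    def strand(i: int) -> str:
        return "+" if i % 2 == 0 else "-"

    coding_lines = []
    for i, (chrom, o) in enumerate(coding_slots):
        gid, tid, st = f"CG{i:04d}", f"CGT{i:04d}", strand(i)
        for s, e in ((o + 500, o + 2000), (o + 3000, o + 4500)):
            coding_lines.append(
                f'{chrom}\tensembl\texon\t{s + 1}\t{e}\t.\t{st}\t.\t'
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )
    linc_lines = []
    linc_loci = {}
    for i, (chrom, o) in enumerate(linc_slots):
        gid, tid, st = f"LINC{i:04d}", f"LNCT{i:04d}", strand(i + 1)
        exons = ((o + 1000, o + 1600), (o + 2600, o + 3400))
        linc_loci[gid] = (chrom, exons, st)
        for s, e in exons:
            linc_lines.append(
                f'{chrom}\tensembl\texon\t{s + 1}\t{e}\t.\t{st}\t.\t'
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )
    contaminants = {"length": [], "exon_count": [], "overlap": []}
    for i, (chrom, o) in enumerate(short_slots):
        tid = f"BADLEN_T{i:02d}"
        contaminants["length"].append(tid)
        for s, e in ((o + 1000, o + 1080), (o + 2000, o + 2120)):  # 200 bp total
            linc_lines.append(
                f'{chrom}\tassembled\texon\t{s + 1}\t{e}\t.\t+\t.\t'
                f'gene_id "BADLEN{i:02d}"; transcript_id "{tid}";'
            )
    for i, (chrom, o) in enumerate(single_slots):
        tid = f"BADEXON_T{i:02d}"
        contaminants["exon_count"].append(tid)
        linc_lines.append(
            f'{chrom}\tassembled\texon\t{o + 1001}\t{o + 1500}\t.\t+\t.\t'
            f'gene_id "BADEXON{i:02d}"; transcript_id "{tid}";'
        )
    for i in range(cfg.n_contaminants):
        if i >= len(coding_slots):
            break
        chrom, co = coding_slots[i]
        tid = f"BADOVL_T{i:02d}"
        contaminants["overlap"].append(tid)
        for s, e in ((co + 600, co + 900), (co + 2100, co + 2400)):
            linc_lines.append(
                f'{chrom}\tassembled\texon\t{s + 1}\t{e}\t.\t+\t.\t'
                f'gene_id "BADOVL{i:02d}"; transcript_id "{tid}";'
            )
    (outdir / "known_coding.gtf").write_text("\n".join(coding_lines) + "\n")
    (outdir / "linc_candidates.gtf").write_text("\n".join(linc_lines) + "\n")
    label_rows = ["transcript_id\tlabel"]
    all_tids = sorted(
        {line.split('transcript_id "')[1].split('"')[0] for line in linc_lines}
    )
    label_rows += [f"{tid}\tnoncoding" for tid in all_tids]
    (outdir / "cpc_labels.tsv").write_text("\n".join(label_rows) + "\n")

    truth_ann = {
        "contaminants": contaminants,
        "linc_ids": roles["ids"],
        "coding_ids": [f"CG{i:04d}" for i in range(cfg.n_coding)],
        "linc_loci": {
            g: {"chrom": c, "exons": [list(e) for e in ex], "strand": s}
            for g, (c, ex, s) in linc_loci.items()
        },
    }
    return truth_ann


def gen_repeats(cfg: SynthConfig, truth_ann: dict, ages: dict, outdir: Path) -> dict:
    """Write an rmsk-style repeat table with a planted HERVH-like family.

    HERVH-int elements are planted in exon 1 of human-specific lincRNAs at
    rate_a and of root-dated lincRNAs at rate_b; satellite and simple
    repeats (which the TE analysis must exclude) plus neutral Alu elements
    are planted as distractors.
    """
    rng = _rng(cfg, 5)
    rate_a, rate_b = cfg.hervh_rates
    max_rank = len(SpeciesTree.default().leaves) - 1
    group_a = sorted(g for g, a in ages.items() if a["rank"] == 0)
    group_b = sorted(g for g, a in ages.items() if a["rank"] == max_rank)
    rows = ["genoName\tgenoStart\tgenoEnd\trepName\trepClass\trepFamily"]
    hervh_genes = []
    for gid, rate in [(g, rate_a) for g in group_a] + [(g, rate_b) for g in group_b]:
        locus = truth_ann["linc_loci"][gid]
        e0 = locus["exons"][0]
        if rng.random() < rate:
            hervh_genes.append(gid)
            rows.append(
                f"{locus['chrom']}\t{e0[0] + 50}\t{e0[0] + 250}\tHERVH-int\tLTR\tERV1"
            )
    for i, gid in enumerate(truth_ann["linc_ids"][:40]):
        locus = truth_ann["linc_loci"][gid]
        e0 = locus["exons"][0]
        if i % 2 == 0:  # excluded class overlapping an exon: must be ignored
            rows.append(
                f"{locus['chrom']}\t{e0[0] + 300}\t{e0[0] + 400}\tALR/Alpha\tSatellite\tcentr"
            )
        else:  # intron-only neutral repeat: must not count
            rows.append(
                f"{locus['chrom']}\t{e0[1] + 100}\t{e0[1] + 300}\tAluY\tSINE\tAlu"
            )
    (outdir / "repeats.tsv").write_text("\n".join(rows) + "\n")
    return {
        "hervh_genes": sorted(hervh_genes),
        "human_specific": group_a,
        "root_dated": group_b,
        "rates": [rate_a, rate_b],
    }


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(cfg: SynthConfig, outdir: Path) -> dict:
    """Write the FPKM matrix and sample→group map.

    ES-exclusive lincRNAs draw LogNormal(mu=2, sigma=0.25) in the ES
    samples and 0 elsewhere (tau = 1 by construction). Module members
    share a per-module latent profile Uniform(2, 6) per condition times
    multiplicative lognormal noise of sd ``noise_sd`` (pairwise
    correlation 1 at zero noise; the Uniform(2, 6) range keeps module
    profiles above the low-expression floor and far from tissue-biased).
    Background genes are i.i.d. Uniform(0.5, 4) per sample.
    """
    rng = _rng(cfg, 1)
    roles = _linc_roles(cfg)
    conditions = _conditions(cfg)
    samples, groups = [], {}
    for i in range(cfg.n_hes_samples):
        s = f"hES_{i + 1:02d}"
        samples.append(s)
        groups[s] = HES
    for t in conditions[1:]:
        s = f"{t}_1"
        samples.append(s)
        groups[s] = t
    cond_of = [groups[s] for s in samples]
    cond_index = {c: i for i, c in enumerate(conditions)}

    coding_ids = [f"CG{i:04d}" for i in range(cfg.n_coding)]
    module_coding = []
    p = 0
    for m in range(cfg.n_modules):
        module_coding.append(coding_ids[p : p + cfg.module_coding])
        p += cfg.module_coding

    gene_ids = roles["ids"] + coding_ids
    values = rng.uniform(0.5, 4.0, size=(len(gene_ids), len(samples)))
    row = {g: i for i, g in enumerate(gene_ids)}

    for g in roles["hes"]:
        values[row[g], :] = 0.0
        hes_cols = [j for j, c in enumerate(cond_of) if c == HES]
        values[row[g], hes_cols] = np.exp(rng.normal(2.0, 0.25, size=len(hes_cols)))

    latents = rng.uniform(2.0, 6.0, size=(cfg.n_modules, len(conditions)))
    for m in range(cfg.n_modules):
        members = roles["modules"][m] + module_coding[m]
        for g in members:
            base = np.array([latents[m, cond_index[c]] for c in cond_of])
            if cfg.noise_sd > 0:
                base = base * np.exp(rng.normal(0.0, cfg.noise_sd, size=len(base)))
            values[row[g], :] = base

    lines = ["gene_id\t" + "\t".join(samples)]
    for g in gene_ids:
        lines.append(g + "\t" + "\t".join(f"{v:.6g}" for v in values[row[g]]))
    (outdir / "fpkm.tsv").write_text("\n".join(lines) + "\n")
    (outdir / "sample_groups.tsv").write_text(
        "\n".join(f"{s}\t{groups[s]}" for s in samples) + "\n"
    )
    return {
        "hes_specific": roles["hes"],
        "module_lincs": roles["modules"],
        "module_coding": module_coding,
        "conditions": conditions,
    }


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def gen_ontology(cfg: SynthConfig, truth_expr: dict, outdir: Path) -> dict:
    """Write a small OBO DAG, gene→term map, and slim term list.

    Each module's coding genes annotate the module's leaf term, which
    reaches its designated slim ancestor through an is_a → part_of chain
    (leaf is_a intermediate part_of slim is_a root). Decoy terms directly
    under the root annotate the background coding genes; two decoys are
    also placed in the slim to exercise non-significant slim terms.
    """
    rng = _rng(cfg, 2)
    root = "GO:0000001"
    terms = [(root, "biological_process", [])]
    slim_terms, leaf_of_module, slim_of_module = [], [], []
    for m in range(cfg.n_modules):
        slim = f"GO:{10 + m:07d}"
        inter = f"GO:{30 + m:07d}"
        leaf = f"GO:{50 + m:07d}"
        terms.append((slim, f"slim_process_{m}", [("is_a", root)]))
        terms.append((inter, f"intermediate_process_{m}", [("part_of", slim)]))
        terms.append((leaf, f"leaf_process_{m}", [("is_a", inter)]))
        slim_terms.append(slim)
        leaf_of_module.append(leaf)
        slim_of_module.append(slim)
    decoys = [f"GO:{70 + k:07d}" for k in range(cfg.n_decoy_terms)]
    for k, d in enumerate(decoys):
        terms.append((d, f"decoy_process_{k}", [("is_a", root)]))
    slim_list = slim_terms + decoys[:2]

    blocks = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for tid, name, parents in terms:
        blocks.append("[Term]")
        blocks.append(f"id: {tid}")
        blocks.append(f"name: {name}")
        blocks.append("namespace: biological_process")
        for rel, parent in parents:
            if rel == "is_a":
                blocks.append(f"is_a: {parent}")
            else:
                blocks.append(f"relationship: part_of {parent}")
        blocks.append("")
    (outdir / "ontology.obo").write_text("\n".join(blocks) + "\n")
    (outdir / "slim_terms.txt").write_text("\n".join(slim_list) + "\n")

    rows = []
    module_coding = truth_expr["module_coding"]
    in_module = {g for mc in module_coding for g in mc}
    for m, mc in enumerate(module_coding):
        for g in mc:
            rows.append(f"{g}\t{leaf_of_module[m]}")
    for i in range(cfg.n_coding):
        g = f"CG{i:04d}"
        if g in in_module:
            continue
        rows.append(f"{g}\t{decoys[int(rng.integers(len(decoys)))]}")
    (outdir / "gene2term.tsv").write_text("\n".join(rows) + "\n")
    return {
        "leaf_terms": leaf_of_module,
        "slim_terms": slim_of_module,
        "decoy_terms": decoys,
        "slim_list": slim_list,
    }


# ---------------------------------------------------------------------------
# Alignments (gene ages)
# ---------------------------------------------------------------------------

def gen_alignments(cfg: SynthConfig, truth_ann: dict, outdir: Path) -> dict:
    """Write per-species BED block files realizing the intended gene ages.

    Species inside a gene's intended clade get a block covering 95% of
    the gene span; outside species get 40%. Patchy genes are present only
    in the most distant leaf, matching no nested clade, hence undated.
    """
    tree = SpeciesTree.default()
    clades = tree.nested_clades()
    roles = _linc_roles(cfg)
    patchy = set(roles["patchy"])
    distant = sorted(clades[-1] - clades[-2])[0]  # the outermost leaf (mouse)

    ages: dict[str, dict] = {}
    assignments = cfg.age_assignments or {}
    non_patchy = [g for g in roles["ids"] if g not in patchy]
    for i, gid in enumerate(non_patchy):
        rank = assignments.get(gid, i % len(clades))
        if isinstance(rank, str):
            raise DataError(f"unknown branch label {rank!r} for gene {gid}")
        if not 0 <= rank < len(clades):
            raise DataError(f"unknown branch rank {rank} for gene {gid}")
        ages[gid] = {"rank": int(rank), "branch": sorted(clades[rank])}
    for gid in roles["patchy"]:
        ages[gid] = {"rank": None, "branch": None}

    species = sorted(tree.leaves - {tree.focal})
    (outdir / "alignments").mkdir(exist_ok=True)
    for sp in species:
        rows = []
        for gid in roles["ids"]:
            locus = truth_ann["linc_loci"][gid]
            start = locus["exons"][0][0]
            end = locus["exons"][-1][1]
            span = end - start
            if ages[gid]["rank"] is None:
                frac = 0.95 if sp == distant else 0.40
            else:
                frac = 0.95 if sp in ages[gid]["branch"] else 0.40
            rows.append(
                f"{locus['chrom']}\t{start}\t{start + math.ceil(frac * span)}\t{gid}"
            )
        (outdir / "alignments" / f"{sp}.bed").write_text("\n".join(rows) + "\n")
    return {"ages": ages, "species": species}


# ---------------------------------------------------------------------------
# Peaks and variants
# ---------------------------------------------------------------------------

def gen_peaks_and_variants(cfg: SynthConfig, truth_ann: dict, outdir: Path) -> dict:
    """Write ChIP peak BEDs and a variant table with planted DAFs.

    Promoter peaks (H3K4me3) land in the promoter window of ES-specific
    lincRNAs at rate f_group and of all other lincRNAs at rate
    f_background; body peaks (H3K36me3) cover 80% of the gene span in the
    group vs 10% in the background, at the same rates. Variants carry
    Beta(1, 50) DAFs (analytic mean 1/51 < 0.1) for the planted purifying
    genes and Beta(5, 5) otherwise.
    """
    rng = _rng(cfg, 3)
    roles = _linc_roles(cfg)
    f_group, f_bg = cfg.peak_enrichment
    group = set(roles["hes"])
    promoter_rows, body_rows = [], []
    for gid in roles["ids"]:
        locus = truth_ann["linc_loci"][gid]
        start = locus["exons"][0][0]
        end = locus["exons"][-1][1]
        span = end - start
        rate = f_group if gid in group else f_bg
        if rng.random() < rate:
            if locus["strand"] == "+":
                promoter_rows.append(
                    f"{locus['chrom']}\t{max(0, start - 400)}\t{max(1, start - 100)}"
                    f"\t{gid}_pk\t100"
                )
            else:
                promoter_rows.append(
                    f"{locus['chrom']}\t{end + 100}\t{end + 400}\t{gid}_pk\t100"
                )
        if rng.random() < rate:
            frac = 0.8 if gid in group else 0.1
            body_rows.append(
                f"{locus['chrom']}\t{start}\t{start + math.ceil(frac * span)}"
                f"\t{gid}_body\t100"
            )
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "peaks" / "H3K4me3.bed").write_text("\n".join(promoter_rows) + "\n")
    (outdir / "peaks" / "H3K36me3.bed").write_text("\n".join(body_rows) + "\n")

    rng_v = _rng(cfg, 4)
    purifying = set(roles["purifying"])
    var_rows = ["chrom\tpos\tdaf"]
    for gid in roles["ids"]:
        locus = truth_ann["linc_loci"][gid]
        e0 = locus["exons"][0]
        if gid in purifying:
            dafs = rng_v.beta(1, 50, size=5)
        else:
            dafs = rng_v.beta(5, 5, size=5)
        for k, daf in enumerate(dafs):
            var_rows.append(f"{locus['chrom']}\t{e0[0] + 10 * (k + 1)}\t{daf:.6f}")
    (outdir / "variants.tsv").write_text("\n".join(var_rows) + "\n")
    return {
        "peak_group": sorted(group),
        "peak_rates": [f_group, f_bg],
        "purifying": sorted(purifying),
        "promoter_marks": ["H3K4me3"],
        "body_marks": ["H3K36me3"],
    }


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def _pipeline_config(cfg: SynthConfig, species: list[str]) -> dict:
    return {
        "inputs": {
            "known_gtf": "known_coding.gtf",
            "linc_gtf": "linc_candidates.gtf",
            "cpc_labels": "cpc_labels.tsv",
            "fpkm": "fpkm.tsv",
            "groups": "sample_groups.tsv",
            "obo": "ontology.obo",
            "gene2term": "gene2term.tsv",
            "slim": "slim_terms.txt",
            "tree": "tree.nwk",
            "alignments": {sp: f"alignments/{sp}.bed" for sp in species},
            "peaks": {
                "H3K4me3": "peaks/H3K4me3.bed",
                "H3K36me3": "peaks/H3K36me3.bed",
            },
            "promoter_marks": ["H3K4me3"],
            "body_marks": ["H3K36me3"],
            "repeats": "repeats.tsv",
            "variants": "variants.tsv",
        },
        "params": {
            "min_length": 200,
            "min_exons": 2,
            "expressed_min": 1.0,
            "hes_min": 1.0,
            "tau_biased": 0.9,
            "method": "gcc",
            "cutoff": 0.9,
            "low_expr_filter": 1.0,
            "enrich_alpha": 0.01,
            "slim_alpha": 0.05,
            "promoter_upstream": 3000,
            "promoter_downstream": 1000,
            "coverage_cutoff": 0.8,
            "daf_cutoff": 0.1,
            "hes_label": HES,
        },
        "seed": cfg.seed,
    }


def generate_bundle(cfg: SynthConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input plus truth.json and a pipeline config.

    Returns the truth ledger. Paths inside config.yaml are relative to the
    bundle directory, so two bundles from the same config are
    byte-identical wherever they are written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_ann = gen_annotation(cfg, outdir)
    truth_expr = gen_expression(cfg, outdir)
    truth_onto = gen_ontology(cfg, truth_expr, outdir)
    truth_align = gen_alignments(cfg, truth_ann, outdir)
    truth_rep = gen_repeats(cfg, truth_ann, truth_align["ages"], outdir)
    truth_peaks = gen_peaks_and_variants(cfg, truth_ann, outdir)
    (outdir / "tree.nwk").write_text(
        "((((((human,chimp),gorilla),orangutan),rhesus),marmoset),mouse);\n"
    )
    truth = {
        "seed": cfg.seed,
        "noise_sd": cfg.noise_sd,
        "contaminants": truth_ann["contaminants"],
        "linc_ids": truth_ann["linc_ids"],
        "coding_ids": truth_ann["coding_ids"],
        "hes_specific": truth_expr["hes_specific"],
        "modules": [
            {
                "lincs": truth_expr["module_lincs"][m],
                "coding": truth_expr["module_coding"][m],
                "leaf_term": truth_onto["leaf_terms"][m],
                "slim_term": truth_onto["slim_terms"][m],
            }
            for m in range(cfg.n_modules)
        ],
        "slim_list": truth_onto["slim_list"],
        "ages": truth_align["ages"],
        "hervh": truth_rep,
        "peaks": truth_peaks,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_pipeline_config(cfg, truth_align["species"]), fh,
                       sort_keys=True)
    return truth
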