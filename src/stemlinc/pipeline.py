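"""Pipeline orchestration: catalog → call → annotate → date → regulome.

All stage inputs, thresholds and output locations live in a single YAML
config (see :class:`PipelineConfig`); every stage writes its intermediate
tables as TSV and the run ends with a ``report.json`` summarizing counts
at each stage plus a MANIFEST of outputs. Identical config + inputs give
identical outputs: no stage is stochastic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import evolution as evo
from . import expression as expr
from . import genemodels as gm
from . import regulome as reg
from .errors import ConfigError, DataError, StageError

logger = logging.getLogger(__name__)

STAGES = ("catalog", "call", "annotate", "date", "regulome")


@dataclass
class PipelineConfig:
    """Resolved inputs and thresholds for a full run."""

    known_gtf: Path
    linc_gtf: Path
    fpkm: Path
    groups: Path
    obo: Path
    gene2term: Path
    slim: Path
    tree: Path
    alignments: dict[str, Path]
    peaks: dict[str, Path]
    repeats: Path
    variants: Path
    outdir: Path
    cpc_labels: Path | None = None
    promoter_marks: list[str] = field(default_factory=list)
    body_marks: list[str] = field(default_factory=list)
    filter_cfg: gm.FilterConfig = field(default_factory=gm.FilterConfig)
    call_th: expr.CallThresholds = field(default_factory=expr.CallThresholds)
    coexpr_cfg: ann.CoexprConfig = field(default_factory=ann.CoexprConfig)
    promoter_cfg: reg.PromoterConfig = field(default_factory=reg.PromoterConfig)
    coverage_cutoff: float = 0.8
    daf_cutoff: float = 0.1
    hes_label: str = expr.HES_LABEL
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict) or "inputs" not in raw:
            raise ConfigError(f"config {path} lacks an 'inputs' section")
        base = path.parent
        inp = raw["inputs"]
        par = raw.get("params", {})

        def p(key: str, required: bool = True) -> Path | None:
            if key not in inp:
                if required:
                    raise ConfigError(f"config missing input path '{key}'")
                return None
            return (base / inp[key]).resolve()

        cfg = cls(
            known_gtf=p("known_gtf"),
            linc_gtf=p("linc_gtf"),
            cpc_labels=p("cpc_labels", required=False),
            fpkm=p("fpkm"),
            groups=p("groups"),
            obo=p("obo"),
            gene2term=p("gene2term"),
            slim=p("slim"),
            tree=p("tree"),
            alignments={k: (base / v).resolve() for k, v in inp.get("alignments", {}).items()},
            peaks={k: (base / v).resolve() for k, v in inp.get("peaks", {}).items()},
            promoter_marks=list(inp.get("promoter_marks", [])),
            body_marks=list(inp.get("body_marks", [])),
            repeats=p("repeats"),
            variants=p("variants"),
            outdir=Path(outdir),
            filter_cfg=gm.FilterConfig(
                min_length=par.get("min_length", 200),
                min_exons=par.get("min_exons", 2),
                min_fpkm_novel=par.get("min_fpkm_novel", 1.0),
                min_junction_reads=par.get("min_junction_reads", 2),
            ),
            call_th=expr.CallThresholds(
                expressed_min=par.get("expressed_min", 1.0),
                hes_min=par.get("hes_min", 1.0),
                tau_biased=par.get("tau_biased", 0.9),
            ),
            coexpr_cfg=ann.CoexprConfig(
                method=par.get("method", "gcc"),
                cutoff=par.get("cutoff", 0.9),
                low_expr_filter=par.get("low_expr_filter", 1.0),
                enrich_alpha=par.get("enrich_alpha", 0.01),
                slim_alpha=par.get("slim_alpha", 0.05),
            ),
            promoter_cfg=reg.PromoterConfig(
                upstream=par.get("promoter_upstream", 3000),
                downstream=par.get("promoter_downstream", 1000),
            ),
            coverage_cutoff=par.get("coverage_cutoff", 0.8),
            daf_cutoff=par.get("daf_cutoff", 0.1),
            hes_label=par.get("hes_label", expr.HES_LABEL),
            seed=raw.get("seed", 0),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.known_gtf, self.linc_gtf, self.fpkm, self.groups,
                 self.obo, self.gene2term, self.slim, self.tree,
                 self.repeats, self.variants]
        paths += list(self.alignments.values()) + list(self.peaks.values())
        if self.cpc_labels is not None:
            paths.append(self.cpc_labels)
        missing = [str(p) for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise ConfigError(f"input files not found: {missing}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_catalog(cfg: PipelineConfig):
    known_ts = gm.read_gene_models(cfg.known_gtf, "gtf",
                                   default_coding_label="coding")
    known = gm.merge_into_genes(known_ts)
    candidates = gm.read_gene_models(cfg.linc_gtf, "gtf")
    if cfg.cpc_labels is not None:
        labels = pd.read_csv(cfg.cpc_labels, sep="\t")
        label_of = dict(zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1]))
        for t in candidates:
            t.coding_label = label_of.get(t.transcript_id, t.coding_label)
    kept, report = gm.filter_linc_candidates(candidates, known, cfg.filter_cfg)
    genes = gm.merge_into_genes(kept)
    return known, genes, report


def stage_call(cfg: PipelineConfig, gene_ids: list[str]):
    matrix = expr.ExpressionMatrix.from_tsv(cfg.fpkm, cfg.groups)
    profiles = expr.representative_profile(matrix, hes_label=cfg.hes_label)
    missing = [g for g in gene_ids if g not in profiles.index]
    if missing:
        raise DataError(f"catalog genes missing from FPKM matrix: {missing[:5]}")
    linc_profiles = profiles.loc[gene_ids]
    calls = expr.call_table(linc_profiles, cfg.call_th, hes_label=cfg.hes_label)
    return profiles, linc_profiles, calls


def stage_annotate(cfg: PipelineConfig, linc_profiles: pd.DataFrame,
                   coding_profiles: pd.DataFrame, calls: pd.DataFrame):
    slim = [l.strip() for l in Path(cfg.slim).read_text().splitlines() if l.strip()]
    dag = ann.OntologyDAG.from_obo(cfg.obo, slim=slim)
    gmap = ann.load_gene_term_map(cfg.gene2term, dag)
    expressed = calls.index[calls["expressed"]]
    annotations, summary = ann.annotate_all(
        linc_profiles.loc[expressed], coding_profiles, gmap, dag, cfg.coexpr_cfg
    )
    linc_slim = {a.gene_id: a.slim_terms for a in annotations}
    all_lincs = set(linc_slim)
    hes_set = set(calls.index[calls["hes"]]) & all_lincs
    biased_set = set(calls.index[calls["biased"]]) & all_lincs
    enr_hes = ann.set_term_enrichment(hes_set, all_lincs, linc_slim,
                                      cfg.coexpr_cfg.slim_alpha)
    enr_biased = ann.set_term_enrichment(biased_set, all_lincs, linc_slim,
                                         cfg.coexpr_cfg.slim_alpha)
    return annotations, summary, linc_slim, enr_hes, enr_biased


def stage_date(cfg: PipelineConfig, genes: list[gm.Gene], calls: pd.DataFrame):
    tree = evo.SpeciesTree.from_newick(Path(cfg.tree))
    species = sorted(tree.leaves - {tree.focal})
    blocks = {}
    for sp in species:
        path = cfg.alignments.get(sp)
        if path is None:
            logger.warning("no alignment file for species %s", sp)
            blocks[sp] = []
            continue
        blocks[sp] = _read_blocks_bed(path)
    results = []
    for g in genes:
        pv = evo.call_homologs(g, blocks, cutoff=cfg.coverage_cutoff,
                               species=species)
        results.append(evo.date_gene(pv, tree, gene_id=g.gene_id))
    ages = {r.gene_id: r for r in results}
    dated = [r for r in results if r.dated]
    hes_ids = set(calls.index[calls["hes"]])
    a = [r.age for r in dated if r.gene_id in hes_ids]
    b = [r.age for r in dated if r.gene_id not in hes_ids]
    age_p = (evo.compare_age_distributions(a, b, "less").p_value
             if a and b else None)
    return tree, ages, age_p


def _read_blocks_bed(path: Path):
    from .intervals import GenomicInterval

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def stage_regulome(cfg: PipelineConfig, genes: list[gm.Gene],
                   calls: pd.DataFrame, ages: dict):
    by_id = {g.gene_id: g for g in genes}
    group_ids = [g for g in calls.index[calls["biased"]] if g in by_id]
    bg_ids = [g for g in by_id if g not in set(group_ids)]
    group = [by_id[g] for g in group_ids]
    background = [by_id[g] for g in bg_ids]
    mark_results, body_results = [], []
    for mark in cfg.promoter_marks:
        peaks = reg.PeakSet.from_bed(cfg.peaks[mark], name=mark)
        mark_results.append(
            reg.promoter_enrichment(group, background, peaks, cfg.promoter_cfg)
        )
    for mark in cfg.body_marks:
        peaks = reg.PeakSet.from_bed(cfg.peaks[mark], name=mark)
        body_results.append((mark, reg.genebody_mark_test(group, background, peaks)))

    repeats = reg.read_repeats_tsv(cfg.repeats)
    te_by_gene = {g.gene_id: reg.te_content(g, repeats) for g in genes}
    max_rank = max((r.age for r in ages.values() if r.dated), default=None)
    hs = {g for g, r in ages.items() if r.dated and r.age == 0}
    rooted = {g for g, r in ages.items() if r.dated and r.age == max_rank}
    hervh = (reg.te_family_enrichment(hs, rooted, te_by_gene)
             if hs and rooted else None)

    vdf = pd.read_csv(cfg.variants, sep="\t")
    variants = list(zip(vdf["chrom"], vdf["pos"].astype(int),
                        vdf["daf"].astype(float)))
    daf_results = [evo.mean_daf(g, variants, cutoff=cfg.daf_cutoff)
                   for g in genes]
    return mark_results, body_results, te_by_gene, hervh, daf_results


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _enr_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.name, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio, "p_raw": r.p_value,
                "p_adjusted": r.p_adjusted, "significant": r.significant,
                "reason": r.reason or "",
            }
            for r in results
        ]
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write every intermediate table.

    Raises :class:`StageError` on failure, after writing a MANIFEST that
    marks the run incomplete; partial outputs are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"stages": {}}

    def emit(name: str, write) -> None:
        write(out / name)
        manifest.append(name)

    stage = "catalog"
    try:
        known, genes, reject = stage_catalog(cfg)
        emit("rejection_report.tsv",
             lambda p: reject.to_csv(p, sep="\t", index=False))
        kept_ts = [t for g in genes for t in g.transcripts]
        emit("catalog.gtf", lambda p: gm.write_gene_models(kept_ts, p, "gtf"))
        reasons = reject.loc[~reject["kept"], "reason"].value_counts().to_dict()
        report["stages"]["catalog"] = {
            "n_candidates": int(len(reject)),
            "n_kept_transcripts": int(reject["kept"].sum()),
            "rejected_by_reason": {k: int(v) for k, v in sorted(reasons.items())},
            "n_genes": len(genes),
        }

        stage = "call"
        gene_ids = [g.gene_id for g in genes]
        profiles, linc_profiles, calls = stage_call(cfg, gene_ids)
        emit("calls.tsv", lambda p: calls.to_csv(p, sep="\t"))
        report["stages"]["call"] = {
            "n_expressed": int(calls["expressed"].sum()),
            "n_hes": int(calls["hes"].sum()),
            "n_hes_biased": int(calls["biased"].sum()),
        }

        stage = "annotate"
        coding_ids = [g for g in profiles.index if g not in set(gene_ids)]
        annotations, summary, linc_slim, enr_hes, enr_biased = stage_annotate(
            cfg, linc_profiles, profiles.loc[coding_ids], calls
        )
        adf = pd.DataFrame(
            [
                {
                    "gene_id": a.gene_id,
                    "n_neighbors": len(a.neighbors),
                    "enriched_terms": ";".join(sorted(a.enriched_terms)),
                    "slim_terms": ";".join(sorted(a.slim_terms)),
                    "error": a.error or "",
                }
                for a in annotations
            ]
        )
        emit("annotations.tsv", lambda p: adf.to_csv(p, sep="\t", index=False))
        emit("slim_enrichment_hes.tsv",
             lambda p: _enr_frame(enr_hes).to_csv(p, sep="\t", index=False))
        emit("slim_enrichment_biased.tsv",
             lambda p: _enr_frame(enr_biased).to_csv(p, sep="\t", index=False))
        report["stages"]["annotate"] = {
            **summary,
            "significant_slim_hes": sorted(
                r.name for r in enr_hes if r.significant
            ),
            "significant_slim_biased": sorted(
                r.name for r in enr_biased if r.significant
            ),
        }

        stage = "date"
        tree, ages, age_p = stage_date(cfg, genes, calls)
        ddf = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "branch": ",".join(r.branch) if r.dated else "undated",
                    "age": r.age if r.dated else "",
                }
                for r in ages.values()
            ]
        )
        emit("dating.tsv", lambda p: ddf.to_csv(p, sep="\t", index=False))
        per_rank: dict[int, int] = {}
        for r in ages.values():
            if r.dated:
                per_rank[r.age] = per_rank.get(r.age, 0) + 1
        n_dated = sum(per_rank.values())
        report["stages"]["date"] = {
            "n_dated": n_dated,
            "n_undated": len(ages) - n_dated,
            "dated_fraction": n_dated / len(ages) if ages else 0.0,
            "per_rank": {str(k): v for k, v in sorted(per_rank.items())},
            "hes_vs_other_age_p": age_p,
        }

        stage = "regulome"
        marks, bodies, te_by_gene, hervh, dafs = stage_regulome(
            cfg, genes, calls, ages
        )
        rows = [
            {"kind": "promoter", "name": m.name, "a": m.a, "b": m.b,
             "c": m.c, "d": m.d, "odds_ratio": m.odds_ratio, "p": m.p_value}
            for m in marks
        ]
        rows += [
            {"kind": "genebody", "name": name, "a": "", "b": "", "c": "",
             "d": "", "odds_ratio": "", "p": tr.p_value}
            for name, tr in bodies
        ]
        if hervh is not None:
            rows.append(
                {"kind": "te_family", "name": hervh.name, "a": hervh.a,
                 "b": hervh.b, "c": hervh.c, "d": hervh.d,
                 "odds_ratio": hervh.odds_ratio, "p": hervh.p_value}
            )
        rdf = pd.DataFrame(rows)
        emit("regulome.tsv", lambda p: rdf.to_csv(p, sep="\t", index=False))
        daf_df = pd.DataFrame(
            [
                {"gene_id": d.gene_id,
                 "mean_daf": "" if d.mean_daf is None else d.mean_daf,
                 "purifying": "" if d.purifying is None else d.purifying}
                for d in dafs
            ]
        )
        emit("daf.tsv", lambda p: daf_df.to_csv(p, sep="\t", index=False))
        report["stages"]["regulome"] = {
            "promoter_marks": {
                m.name: {"odds_ratio": m.odds_ratio, "p": m.p_value}
                for m in marks
            },
            "genebody_marks": {name: tr.p_value for name, tr in bodies},
            "hervh": (
                None if hervh is None or hervh.reason
                else {"odds_ratio": hervh.odds_ratio, "p": hervh.p_value,
                      "counts": [hervh.a, hervh.b, hervh.c, hervh.d]}
            ),
            "n_purifying": sum(1 for d in dafs if d.purifying),
        }
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "INCOMPLETE\n" + "\n".join(manifest) + "\n"
        )
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, float) and math.isinf(obj):
            return "inf"
        return obj

    (out / "report.json").write_text(
        json.dumps(_clean(report), indent=1, sort_keys=True)
    )
    manifest.append("report.json")
    (out / "MANIFEST").write_text("COMPLETE\n" + "\n".join(manifest) + "\n")
    return report
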