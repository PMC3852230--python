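"""Guilt-by-association functional annotation of lincRNAs.

A lincRNA with unknown function is annotated by its co-expression
"neighbors": protein-coding genes whose expression profile across
conditions correlates strongly with the lincRNA's. The Gini correlation
coefficient (GCC) is the default measure — a hybrid between Pearson
(actual values) and Spearman (ranks) that is robust to outliers while
retaining magnitude information. Neighbors feed a hypergeometric GO term
over-representation test (BH-adjusted); significant terms are projected
onto their GO-slim ancestors for a coarse functional summary, and sets of
lincRNAs are finally tested per slim term with a one-sided Fisher test
(BY-adjusted).

GCC is asymmetric: GCC(x|y) ranks the samples by y and weights the x
values with w_i = 2·rank_i − n − 1 (midranks under ties),

    GCC(x|y) = Σ_j w(rank y_j)·x_j / Σ_j w(rank x_j)·x_j,

whose denominator is the value the numerator takes when x itself provides
the ordering, so GCC(x|x) = 1. The symmetrized value returned by
:func:`correlation` is the direction with the larger absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats as sps

from .errors import ConstantProfileError, DataError
from .stats import EnrichmentResult, ContingencyTable2x2, adjust_bh, adjust_by, fisher_exact, hypergeom_tail

GO_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class CoexprConfig:
    """Knobs of the guilt-by-association pipeline.

    method: correlation measure (gcc, pearson, spearman).
    cutoff: inclusive neighbor threshold (>= 0.9 by default).
    low_expr_filter: genes below this FPKM in every condition are removed
        before any correlation is computed.
    enrich_alpha: BH-adjusted cutoff for assigning a GO term to a lincRNA.
    slim_alpha: BY-adjusted cutoff for lincRNA-set × slim-term association.
    """

    method: str = "gcc"
    cutoff: float = 0.9
    low_expr_filter: float = 1.0
    enrich_alpha: float = 0.01
    slim_alpha: float = 0.05

    def __post_init__(self):
        if self.method not in ("gcc", "pearson", "spearman"):
            raise DataError(f"unknown correlation method {self.method!r}")
        if not 0 < self.cutoff <= 1:
            raise DataError("cutoff must be in (0, 1]")
        for a in (self.enrich_alpha, self.slim_alpha):
            if not 0 < a < 1:
                raise DataError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _rank_weights(v: np.ndarray) -> np.ndarray:
    """Gini rank weights 2·rank − n − 1 with midranks under ties."""
    return 2.0 * sps.rankdata(v) - len(v) - 1.0


def gcc_directional(x: Sequence[float], y: Sequence[float]) -> float:
    """GCC(x|y): x weighted by the rank order of y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = float(_rank_weights(x) @ x)
    if denom == 0.0:
        raise ConstantProfileError("constant x vector: GCC denominator is zero")
    return float(_rank_weights(y) @ x) / denom


def correlation(x: Sequence[float], y: Sequence[float], method: str = "gcc") -> float:
    """Symmetrized correlation between two expression vectors.

    For ``gcc`` the direction (GCC(x|y) or GCC(y|x)) with the larger
    absolute value is returned; ``pearson`` and ``spearman`` are the
    standard coefficients.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("correlation needs two equal-length vectors, n >= 3")
    if method == "gcc":
        gxy = gcc_directional(x, y)
        gyx = gcc_directional(y, x)
        return gxy if abs(gxy) >= abs(gyx) else gyx
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("constant vector: correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise DataError(f"unknown correlation method {method!r}")


def correlation_matrix(
    X: pd.DataFrame, Y: pd.DataFrame, method: str = "gcc"
) -> pd.DataFrame:
    """All-pairs symmetrized correlations between rows of X and rows of Y.

    Rows are genes, columns conditions (shared axis). Pairs involving a
    constant vector yield NaN rather than raising, so a single degenerate
    gene cannot abort a batch.
    """
    if list(X.columns) != list(Y.columns):
        raise DataError("X and Y must share the same condition axis")
    Xv = X.to_numpy(float)
    Yv = Y.to_numpy(float)
    n = Xv.shape[1]
    if method == "gcc":
        Wx = np.apply_along_axis(_rank_weights, 1, Xv)
        Wy = np.apply_along_axis(_rank_weights, 1, Yv)
        den_x = np.einsum("ij,ij->i", Wx, Xv)  # per-x self weighting
        den_y = np.einsum("ij,ij->i", Wy, Yv)
        num_xy = Xv @ Wy.T  # num_xy[i, j] = Σ w(rank y_j)·x_i
        num_yx = Wx @ Yv.T  # num_yx[i, j] = Σ w(rank x_i)·y_j
        with np.errstate(divide="ignore", invalid="ignore"):
            gxy = num_xy / den_x[:, None]
            gyx = num_yx / den_y[None, :]
        out = np.where(np.abs(gxy) >= np.abs(gyx), gxy, gyx)
        out[den_x == 0, :] = np.nan
        out[:, den_y == 0] = np.nan
    else:
        if method == "spearman":
            Xv = np.apply_along_axis(sps.rankdata, 1, Xv)
            Yv = np.apply_along_axis(sps.rankdata, 1, Yv)
        Xc = Xv - Xv.mean(axis=1, keepdims=True)
        Yc = Yv - Yv.mean(axis=1, keepdims=True)
        sx = np.sqrt((Xc**2).sum(axis=1))
        sy = np.sqrt((Yc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (Xc @ Yc.T) / np.outer(sx, sy)
        out[sx == 0, :] = np.nan
        out[:, sy == 0] = np.nan
    return pd.DataFrame(out, index=X.index, columns=Y.index)


def find_neighbors(
    linc: str,
    lincs_expr: pd.DataFrame,
    coding_expr: pd.DataFrame,
    cfg: CoexprConfig | None = None,
) -> set[str]:
    """Coding genes whose correlation with ``linc`` reaches the cutoff.

    The cutoff is inclusive (correlation >= cutoff). Coding genes whose
    correlation is undefined (constant profile) are skipped.
    """
    cfg = cfg or CoexprConfig()
    if linc not in lincs_expr.index:
        raise DataError(f"lincRNA {linc} absent from expression table")
    if coding_expr.empty:
        return set()
    corr = correlation_matrix(
        lincs_expr.loc[[linc]], coding_expr, method=cfg.method
    ).iloc[0]
    if corr.isna().all() and np.ptp(lincs_expr.loc[linc].to_numpy()) == 0:
        raise ConstantProfileError(f"lincRNA {linc} has a constant profile")
    return set(corr.index[corr >= cfg.cutoff])


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

class OntologyDAG:
    """A GO-like DAG with a designated slim subset.

    Edges run child → parent and are restricted to ``is_a`` and ``part_of``
    relations. Roots (terms with no parent) are tracked so that projection
    onto the slim can exclude them.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] | None = None,
        namespaces: Mapping[str, str] | None = None,
        slim: Iterable[str] = (),
    ):
        g = nx.DiGraph()
        if terms:
            g.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel in GO_RELATIONS:
                g.add_edge(child, parent, rel=rel)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("ontology graph contains a cycle")
        self.graph = g
        self.namespaces = dict(namespaces or {})
        self.slim = frozenset(slim)
        unknown_slim = self.slim - set(g.nodes)
        if unknown_slim:
            raise DataError(f"slim terms not in ontology: {sorted(unknown_slim)}")
        self.roots = frozenset(n for n in g.nodes if g.out_degree(n) == 0)
        self._anc_cache: dict[str, frozenset] = {}

    @property
    def terms(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term`` via is_a/part_of (term excluded)."""
        if term not in self.graph:
            raise DataError(f"unknown ontology term {term}")
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self.graph, term))
        return self._anc_cache[term]

    @classmethod
    def from_obo(
        cls, path: str | Path, slim: Iterable[str] = ()
    ) -> "OntologyDAG":
        """Load an OBO 1.2 ontology; only is_a/part_of edges are kept."""
        g = obonet.read_obo(str(path))
        edges = []
        for child, parent, key in g.edges(keys=True):
            edges.append((child, parent, key))
        namespaces = {
            n: d.get("namespace", "") for n, d in g.nodes(data=True)
        }
        return cls(edges, terms=g.nodes, namespaces=namespaces, slim=slim)


def load_gene_term_map(path: str | Path, dag: OntologyDAG | None = None) -> dict[str, set[str]]:
    """Read direct gene→term annotations from a two-column TSV (or GAF).

    GAF 2.x lines (15+ tab fields starting with '!'-comment support) use
    columns 2 (gene) and 5 (term); plain TSVs use the first two columns.
    """
    gmap: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            f = line.split("\t")
            gene, term = (f[1], f[4]) if len(f) >= 15 else (f[0], f[1])
            gmap.setdefault(gene, set()).add(term)
    if dag is not None:
        unknown = {t for ts in gmap.values() for t in ts} - dag.terms
        if unknown:
            raise DataError(f"annotations to unknown terms: {sorted(unknown)[:5]}")
    return gmap


def propagate_annotations(
    gmap: Mapping[str, set[str]], dag: OntologyDAG
) -> dict[str, frozenset]:
    """True-path propagation: each gene inherits all ancestors of its terms."""
    out = {}
    for gene, terms in gmap.items():
        full = set()
        for t in terms:
            full.add(t)
            full |= dag.ancestors(t)
        out[gene] = frozenset(full)
    return out


def enrich_neighbors(
    neighbors: set[str],
    universe: set[str],
    gmap: Mapping[str, set[str]],
    dag: OntologyDAG,
    alpha: float = 0.01,
    propagated: Mapping[str, frozenset] | None = None,
) -> dict[str, tuple[float, float]]:
    """Hypergeometric GO over-representation of a neighbor set.

    Annotations are propagated to ancestors first (true-path rule); the
    universe is restricted to genes carrying at least one term. Raw
    p-values are BH-adjusted across the tested terms and terms with
    adjusted p <= alpha are returned as {term: (raw, adjusted)}.
    """
    if not neighbors <= universe:
        raise DataError("neighbors must be a subset of the universe")
    if not neighbors:
        return {}
    prop = propagated if propagated is not None else propagate_annotations(gmap, dag)
    annotated_universe = {g for g in universe if prop.get(g)}
    n_universe = len(annotated_universe)
    drawn = neighbors & annotated_universe
    if not drawn:
        return {}
    term_universe_count: dict[str, int] = {}
    for g in annotated_universe:
        for t in prop[g]:
            term_universe_count[t] = term_universe_count.get(t, 0) + 1
    term_neighbor_count: dict[str, int] = {}
    for g in drawn:
        for t in prop[g]:
            term_neighbor_count[t] = term_neighbor_count.get(t, 0) + 1
    terms = sorted(term_neighbor_count)
    raw = [
        hypergeom_tail(
            n_universe, term_universe_count[t], len(drawn), term_neighbor_count[t]
        )
        for t in terms
    ]
    adj = adjust_bh(raw)
    return {
        t: (float(r), float(a))
        for t, r, a in zip(terms, raw, adj)
        if a <= alpha
    }


def project_to_slim(
    terms: Iterable[str], dag: OntologyDAG, most_specific: bool = False
) -> set[str]:
    """Map terms onto their slim ancestors (the term itself counts).

    Root terms never appear in the projection. With ``most_specific=True``
    slim hits that are ancestors of another slim hit are dropped, keeping
    only the most specific covering slim terms.
    """
    hits: set[str] = set()
    for t in terms:
        if t not in dag.terms:
            raise DataError(f"unknown ontology term {t}")
        candidates = ({t} | dag.ancestors(t)) & dag.slim
        hits |= candidates
    hits -= dag.roots
    if most_specific:
        redundant = {s for s in hits if any(s in dag.ancestors(o) for o in hits)}
        hits -= redundant
    return hits


def set_term_enrichment(
    query_set: set[str],
    all_lincs: set[str],
    linc_slim: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Association of a lincRNA set with each slim term.

    Per term a 2×2 table (in query / holds term) is tested one-sided
    (greater) with Fisher's exact test; p-values are BY-adjusted across
    terms and a term is flagged significant iff adjusted p <= alpha and
    the odds ratio exceeds 1. Degenerate partitions (empty query or
    query = all lincs) and terms held by no lincRNA are skipped with a
    reason.
    """
    if not query_set <= all_lincs:
        raise DataError("query set must be a subset of all lincRNAs")
    terms = sorted({t for g in all_lincs for t in linc_slim.get(g, ())})
    others = all_lincs - query_set
    results: list[EnrichmentResult] = []
    testable: list[EnrichmentResult] = []
    for term in terms:
        holders = {g for g in all_lincs if term in linc_slim.get(g, ())}
        a = len(query_set & holders)
        b = len(query_set - holders)
        c = len(others & holders)
        d = len(others - holders)
        res = EnrichmentResult(term, a, b, c, d, np.nan, np.nan)
        if not query_set or not others:
            res.reason = "degenerate partition"
        elif not holders:
            res.reason = "term held by no lincRNA"
        else:
            tr = fisher_exact(ContingencyTable2x2(a, b, c, d), "greater")
            res.odds_ratio, res.p_value = tr.statistic, tr.p_value
            testable.append(res)
        results.append(res)
    if testable:
        adj = adjust_by([r.p_value for r in testable])
        for r, p in zip(testable, adj):
            r.p_adjusted = float(p)
            r.significant = bool(p <= alpha and r.odds_ratio > 1)
    return results


# ---------------------------------------------------------------------------
# Whole-catalog annotation
# ---------------------------------------------------------------------------

@dataclass
class LincAnnotation:
    """Per-lincRNA guilt-by-association outcome."""

    gene_id: str
    neighbors: set[str] = field(default_factory=set)
    enriched_terms: dict[str, tuple[float, float]] = field(default_factory=dict)
    slim_terms: set[str] = field(default_factory=set)
    error: str | None = None


def low_expression_filter(expr: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Drop genes whose representative FPKM stays below ``floor`` everywhere."""
    return expr.loc[(expr >= floor).any(axis=1)]


def annotate_all(
    lincs_expr: pd.DataFrame,
    coding_expr: pd.DataFrame,
    gmap: Mapping[str, set[str]],
    dag: OntologyDAG,
    cfg: CoexprConfig | None = None,
) -> tuple[list[LincAnnotation], dict]:
    """Annotate every lincRNA; never aborts the batch on a per-gene error.

    Low-expressed genes are removed from both matrices first. Returns the
    annotations plus a coverage summary (fraction of lincRNAs that
    received at least one slim term).
    """
    cfg = cfg or CoexprConfig()
    lincs_kept = low_expression_filter(lincs_expr, cfg.low_expr_filter)
    coding_kept = low_expression_filter(coding_expr, cfg.low_expr_filter)
    prop = propagate_annotations(gmap, dag)
    universe = {g for g in coding_kept.index if prop.get(g)}
    annotations: list[LincAnnotation] = []
    if len(lincs_kept) and len(coding_kept):
        corr = correlation_matrix(lincs_kept, coding_kept, method=cfg.method)
    else:
        corr = pd.DataFrame(index=lincs_kept.index, columns=coding_kept.index,
                            dtype=float)
    for linc in lincs_expr.index:
        ann = LincAnnotation(gene_id=linc)
        if linc not in lincs_kept.index:
            ann.error = "removed by low-expression filter"
            annotations.append(ann)
            continue
        row = corr.loc[linc] if len(corr.columns) else pd.Series(dtype=float)
        if row.isna().all() and len(row):
            ann.error = "constant profile: correlation undefined"
            annotations.append(ann)
            continue
        ann.neighbors = set(row.index[row >= cfg.cutoff]) & universe
        ann.enriched_terms = enrich_neighbors(
            ann.neighbors, universe, gmap, dag, cfg.enrich_alpha, propagated=prop
        )
        ann.slim_terms = project_to_slim(ann.enriched_terms, dag)
        annotations.append(ann)
    n = len(annotations)
    n_slim = sum(1 for a in annotations if a.slim_terms)
    summary = {
        "n_lincs": n,
        "n_after_filter": int(len(lincs_kept)),
        "n_with_slim": n_slim,
        "annotated_fraction": (n_slim / n) if n else 0.0,
        "method": cfg.method,
        "cutoff": cfg.cutoff,
    }
    return annotations, summary
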