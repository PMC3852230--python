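"""Gini correlation, ontology handling, and guilt-by-association annotation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stemlinc.annotation import (
    CoexprConfig,
    OntologyDAG,
    annotate_all,
    correlation,
    correlation_matrix,
    enrich_neighbors,
    find_neighbors,
    gcc_directional,
    project_to_slim,
    propagate_annotations,
    set_term_enrichment,
)
from stemlinc.errors import ConstantProfileError, DataError

from util import gcc_oracle

RNG = np.random.default_rng(11)


class TestGCC:
    def test_self_correlation_is_one(self):
        for _ in range(20):
            x = RNG.uniform(0, 10, size=int(RNG.integers(3, 15)))
            if np.ptp(x) == 0:
                continue
            assert correlation(x, x, "gcc") == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        assert correlation([1, 2, 3], [3, 2, 1], "gcc") == pytest.approx(-1.0)

    def test_pearson_exact_linearity(self):
        assert correlation([1, 2, 3], [2, 4, 6], "pearson") == pytest.approx(1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantProfileError):
            gcc_directional([2, 2, 2], [1, 2, 3])

    def test_matches_tie_averaging_oracle(self):
        for _ in range(100):
            n = int(RNG.integers(4, 15))
            x = np.round(RNG.uniform(0, 3, size=n), 1)
            y = np.round(RNG.uniform(0, 3, size=n), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert correlation(x, y, "gcc") == pytest.approx(
                gcc_oracle(x, y), abs=1e-10
            )

    def test_bounded_in_unit_interval(self):
        for _ in range(200):
            n = int(RNG.integers(3, 25))
            x, y = RNG.normal(size=n), RNG.normal(size=n)
            assert -1 - 1e-9 <= correlation(x, y, "gcc") <= 1 + 1e-9

    @pytest.mark.parametrize("method", ["gcc", "pearson", "spearman"])
    def test_matrix_agrees_with_scalar(self, method):
        X = pd.DataFrame(RNG.uniform(0, 5, size=(6, 10)),
                         index=[f"l{i}" for i in range(6)])
        Y = pd.DataFrame(RNG.uniform(0, 5, size=(8, 10)),
                         index=[f"c{i}" for i in range(8)])
        M = correlation_matrix(X, Y, method)
        for i in X.index:
            for j in Y.index:
                assert M.loc[i, j] == pytest.approx(
                    correlation(X.loc[i], Y.loc[j], method), abs=1e-10
                )

    def test_matrix_flags_constant_rows_as_nan(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"])
        Y = pd.DataFrame([[1.0, 2.0, 3.0]], index=["c"])
        assert np.isnan(correlation_matrix(X, Y, "gcc").iloc[0, 0])


class TestNeighbors:
    LINC = pd.DataFrame([[1.0, 2.0, 3.0]], index=["l1"])

    def test_inclusive_cutoff_boundary(self):
        # crafted so the symmetrized GCC is exactly 18/20 = 0.9
        coding = pd.DataFrame([[0.0, 10.0, 9.0]], index=["c1"])
        assert correlation([1, 2, 3], [0, 10, 9], "gcc") == pytest.approx(0.9)
        assert find_neighbors("l1", self.LINC, coding) == {"c1"}

    def test_cutoff_one_keeps_only_perfect(self):
        coding = pd.DataFrame(
            [[2.0, 4.0, 6.0], [1.0, 3.0, 2.0]], index=["mono", "non"]
        )
        cfg = CoexprConfig(cutoff=1.0)
        assert find_neighbors("l1", self.LINC, coding, cfg) == {"mono"}

    def test_empty_coding_matrix(self):
        empty = pd.DataFrame(columns=[0, 1, 2], dtype=float)
        assert find_neighbors("l1", self.LINC, empty) == set()

    def test_unknown_linc_errors(self):
        with pytest.raises(DataError):
            find_neighbors("nope", self.LINC, self.LINC)


def tiny_dag():
    """root <- A(slim) <-part_of- B <-is_a- C; D(slim) is a decoy branch."""
    edges = [
        ("A", "root", "is_a"),
        ("B", "A", "part_of"),
        ("C", "B", "is_a"),
        ("D", "root", "is_a"),
    ]
    return OntologyDAG(edges, slim={"A", "D", "root"})


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(DataError):
            OntologyDAG([("a", "b", "is_a"), ("b", "a", "is_a")])

    def test_obo_round_trip(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: root\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:2\nname: mid\nis_a: GO:1\n\n"
            "[Term]\nid: GO:3\nname: leaf\nrelationship: part_of GO:2\n\n"
        )
        dag = OntologyDAG.from_obo(obo, slim=["GO:2"])
        assert dag.ancestors("GO:3") == {"GO:1", "GO:2"}
        assert dag.roots == {"GO:1"}
        assert project_to_slim({"GO:3"}, dag) == {"GO:2"}

    def test_slim_projection_reflexive_and_transitive(self):
        dag = tiny_dag()
        assert project_to_slim({"A"}, dag) == {"A"}        # slim term itself
        assert project_to_slim({"C"}, dag) == {"A"}        # via is_a -> part_of
        assert project_to_slim({"D"}, dag) == {"D"}
        assert "root" not in project_to_slim({"C", "D"}, dag)  # roots excluded

    def test_unknown_term_named_in_error(self):
        with pytest.raises(DataError, match="mystery"):
            project_to_slim({"mystery"}, tiny_dag())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_projection_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        terms = [f"T{i}" for i in range(n)]
        edges = []
        for i in range(1, n):  # parents only among earlier terms: acyclic
            for parent in rng.choice(i, size=min(i, int(rng.integers(1, 3))),
                                     replace=False):
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                edges.append((terms[i], terms[int(parent)], rel))
        slim = set(rng.choice(terms, size=max(1, n // 5), replace=False))
        dag = OntologyDAG(edges, terms=terms, slim=slim)
        g = nx.DiGraph((c, p) for c, p, _ in edges)
        g.add_nodes_from(terms)
        for t in terms:
            closure = {t} | nx.descendants(g, t)
            expected = (closure & slim) - dag.roots
            assert project_to_slim({t}, dag) == expected


class TestEnrichment:
    def test_exact_reference_probability(self):
        universe = {f"g{i}" for i in range(10)}
        gmap = {f"g{i}": {"T"} if i < 5 else {"U"} for i in range(10)}
        dag = OntologyDAG([], terms=["T", "U"])
        neighbors = {f"g{i}" for i in range(5)}
        res = enrich_neighbors(neighbors, universe, gmap, dag, alpha=1.0)
        assert res["T"][0] == pytest.approx(1 / 252, rel=1e-12)

    def test_universal_term_never_kept(self):
        universe = {"a", "b", "c", "d"}
        gmap = {g: {"ALL"} for g in universe}
        dag = OntologyDAG([], terms=["ALL"])
        res = enrich_neighbors({"a", "b"}, universe, gmap, dag, alpha=0.05)
        assert res == {}

    def test_unannotated_neighbors_empty(self):
        dag = OntologyDAG([], terms=["T"])
        assert enrich_neighbors({"x"}, {"x", "y"}, {"y": {"T"}}, dag) == {}

    def test_true_path_propagation(self):
        dag = tiny_dag()
        prop = propagate_annotations({"g": {"C"}}, dag)
        assert prop["g"] == {"C", "B", "A", "root"}


class TestSetTermEnrichment:
    def test_reference_odds_ratio(self):
        lincs = (
            [f"q{i}" for i in range(15)] + [f"o{i}" for i in range(120)]
        )
        slim = {}
        for i in range(15):
            slim[f"q{i}"] = {"X"} if i < 10 else set()
        for i in range(120):
            slim[f"o{i}"] = {"X"} if i < 20 else set()
        res = set_term_enrichment(
            {f"q{i}" for i in range(15)}, set(lincs), slim, alpha=0.05
        )
        (rx,) = [r for r in res if r.name == "X"]
        assert (rx.a, rx.b, rx.c, rx.d) == (10, 5, 20, 100)
        assert rx.odds_ratio == pytest.approx(10.0)

    def test_degenerate_partition_skipped(self):
        slim = {"a": {"X"}, "b": set()}
        res = set_term_enrichment({"a", "b"}, {"a", "b"}, slim)
        assert all(r.reason == "degenerate partition" for r in res)

    def test_term_held_by_no_linc_skipped(self):
        res = set_term_enrichment({"a"}, {"a", "b"}, {"a": set(), "b": set()})
        assert res == []


class TestAnnotateAll:
    def test_constant_profile_logged_not_fatal(self):
        conds = list(range(5))
        lincs = pd.DataFrame(
            [[2.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "ok"], columns=conds
        )
        coding = pd.DataFrame([[1, 2, 3, 4, 5]], index=["c"], columns=conds)
        dag = OntologyDAG([], terms=["T"])
        anns, summary = annotate_all(lincs, coding, {"c": {"T"}}, dag)
        by_id = {a.gene_id: a for a in anns}
        assert by_id["flat"].error is not None
        assert by_id["flat"].slim_terms == set()
        assert by_id["ok"].error is None
        assert summary["n_lincs"] == 2

    def test_empty_linc_list(self):
        conds = list(range(4))
        empty = pd.DataFrame(columns=conds, dtype=float)
        coding = pd.DataFrame([[1, 2, 3, 4]], index=["c"], columns=conds)
        dag = OntologyDAG([], terms=["T"])
        anns, summary = annotate_all(empty, coding, {"c": {"T"}}, dag)
        assert anns == [] and summary["n_lincs"] == 0
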