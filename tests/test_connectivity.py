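"""Drug-gene-eQTL connectivity map construction and summaries."""

import json

import numpy as np
import pandas as pd
import pytest

from cceqtl.connectivity import (
    build_connectivity_map,
    distinct_drug_loci,
    expand_by_ec,
    filter_by_eqtl,
    graph_summaries,
    hypergeom_enrichment,
    load_drug_gene_sets,
    load_ec_map,
    select_representative_lines,
    shared_enzymes,
    write_graph,
)
from cceqtl.data import synthetic_collection
from oracles import hypergeom_tail_exact


@pytest.fixture(scope="module")
def toy():
    paths = synthetic_collection()
    sets = load_drug_gene_sets(paths["drug_sets"])
    ec = load_ec_map(paths["ec_map"])
    calls = pd.read_csv(paths["eqtl_calls"], sep="\t")
    return sets, ec, calls


class TestLoadSets:
    def test_round_trips_simple_collection(self, tmp_path):
        p = tmp_path / "sets.json"
        p.write_text(json.dumps({"irinotecan": [{"gene": "Ces1g", "evidence": "direct"}]}))
        assert load_drug_gene_sets(p) == {"irinotecan": [("Ces1g", "direct")]}

    def test_duplicate_gene_keeps_direct_evidence(self, tmp_path):
        p = tmp_path / "sets.json"
        p.write_text(
            json.dumps(
                {
                    "d": [
                        {"gene": "g", "evidence": "indirect"},
                        {"gene": "g", "evidence": "direct"},
                    ]
                }
            )
        )
        assert load_drug_gene_sets(p) == {"d": [("g", "direct")]}

    def test_empty_collection_is_not_an_error(self, tmp_path):
        p = tmp_path / "sets.json"
        p.write_text("{}")
        assert load_drug_gene_sets(p) == {}

    def test_unknown_evidence_label_rejected(self, tmp_path):
        p = tmp_path / "sets.json"
        p.write_text(json.dumps({"d": [{"gene": "g", "evidence": "rumour"}]}))
        with pytest.raises(ValueError, match="rumour"):
            load_drug_gene_sets(p)

    def test_malformed_record_names_position(self, tmp_path):
        p = tmp_path / "sets.json"
        p.write_text(json.dumps({"d": [{"gene": "g"}]}))
        with pytest.raises(ValueError, match="record 0"):
            load_drug_gene_sets(p)


class TestEcExpansion:
    def test_shared_ec_adds_alternative_gene_as_indirect(self):
        out = expand_by_ec({"d": [("G1", "direct")]}, {"G1": {"1.1.1.1"}, "G2": {"1.1.1.1"}})
        assert out == {"d": [("G1", "direct"), ("G2", "indirect")]}

    def test_gene_without_ec_adds_nothing(self):
        out = expand_by_ec({"d": [("G1", "direct")]}, {"G9": {"1.1.1.1"}})
        assert out == {"d": [("G1", "direct")]}

    def test_expansion_is_single_pass(self, toy):
        # G02 (curated in drugA) shares 1.1.1.1 with G04; G04 shares
        # 1.1.1.2 with G07 -- but only curated members seed expansion, so
        # G07 must not reach drugA
        sets, ec, _ = toy
        out = expand_by_ec(sets, ec)
        assert dict(out["drugA"]) == {"G01": "direct", "G02": "direct", "G04": "indirect"}

    def test_toy_expansion_matches_enumeration(self, toy):
        sets, ec, _ = toy
        out = expand_by_ec(sets, ec)
        assert dict(out["drugB"]) == {
            "G02": "direct", "G03": "direct", "G04": "indirect", "G05": "indirect"
        }
        assert dict(out["drugC"]) == {"G05": "direct", "G06": "direct", "G03": "indirect"}
        assert dict(out["drugD"]) == {
            "G05": "direct", "G07": "direct", "G08": "direct", "G09": "direct",
            "G04": "indirect",  # via G07, EC 1.1.1.2
            "G03": "indirect",  # via G05, EC 2.3.4.5
        }
        assert dict(out["drugE"]) == {"G10": "direct", "G11": "direct"}


class TestEqtlFilter:
    def test_keeps_only_genes_with_calls_and_drops_empty_drugs(self, toy):
        sets, ec, calls = toy
        out = filter_by_eqtl(expand_by_ec(sets, ec), calls)
        assert set(out) == {"drugA", "drugB", "drugC", "drugD"}  # drugE emptied
        assert dict(out["drugA"]) == {"G01": "direct", "G02": "direct", "G04": "indirect"}
        assert dict(out["drugC"]) == {"G05": "direct", "G06": "direct"}

    def test_no_calls_empties_the_collection(self, toy):
        sets, ec, calls = toy
        assert filter_by_eqtl(expand_by_ec(sets, ec), calls.iloc[0:0]) == {}


@pytest.fixture(scope="module")
def toy_graph(toy):
    sets, ec, calls = toy
    return build_connectivity_map(filter_by_eqtl(expand_by_ec(sets, ec), calls), calls)


class TestConnectivityGraph:
    def test_node_and_edge_counts_match_enumeration(self, toy_graph):
        by_type = {"drug": 0, "gene": 0, "eqtl": 0}
        for _, data in toy_graph.nodes(data=True):
            by_type[data["node_type"]] += 1
        assert by_type == {"drug": 4, "gene": 7, "eqtl": 8}
        assert toy_graph.number_of_edges() == 12 + 8  # drug-gene + gene-eqtl

    def test_graph_is_tripartite(self, toy_graph):
        allowed = {frozenset(("drug", "gene")), frozenset(("gene", "eqtl"))}
        for a, b in toy_graph.edges():
            pair = frozenset(
                (toy_graph.nodes[a]["node_type"], toy_graph.nodes[b]["node_type"])
            )
            assert pair in allowed

    def test_dual_type_gene_carries_two_eqtl_edges(self, toy_graph):
        eqtl_nbrs = [
            n for n in toy_graph.neighbors("gene:G02")
            if toy_graph.nodes[n]["node_type"] == "eqtl"
        ]
        assert len(eqtl_nbrs) == 2

    def test_evidence_labels_on_drug_gene_edges(self, toy_graph):
        assert toy_graph.edges["drug:drugA", "gene:G04"]["evidence"] == "indirect"
        assert toy_graph.edges["drug:drugA", "gene:G01"]["evidence"] == "direct"

    def test_unfiltered_gene_violates_contract(self, toy):
        sets, ec, calls = toy
        with pytest.raises(ValueError, match="G10"):
            build_connectivity_map({"drugE": [("G10", "direct")]}, calls)

    def test_two_drugs_one_gene_one_eqtl_enumeration(self):
        calls = pd.DataFrame(
            [("t", "G1", "total-expression", "chr1", 0, 1000, 20.0, 0.0)],
            columns=["trait_id", "gene_id", "eqtl_type", "chrom", "start", "end", "max_lr", "fdr"],
        )
        g = build_connectivity_map(
            {"d1": [("G1", "direct")], "d2": [("G1", "direct")]}, calls
        )
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3

    def test_graph_serialization(self, toy_graph, tmp_path):
        paths = write_graph(toy_graph, tmp_path / "map")
        assert paths["graphml"].exists() and paths["json"].exists()


class TestDistinctLoci:
    def test_toy_counts_with_boundary_case(self, toy_graph):
        # drugD holds chr3 intervals [0,2M] and [12M,14M]: boundary gap of
        # exactly 10 Mb stays distinct; [14M,15M) gap of 1 Mb merges
        assert distinct_drug_loci(toy_graph) == {
            "drugA": 2, "drugB": 3, "drugC": 2, "drugD": 3
        }

    def test_merging_is_order_invariant_single_linkage(self):
        calls = pd.DataFrame(
            [
                ("t1", "G1", "total-expression", "chr1", 10_000_000, 12_000_000, 20.0, 0.0),
                ("t2", "G2", "total-expression", "chr1", 15_000_000, 17_000_000, 20.0, 0.0),
                ("t3", "G3", "total-expression", "chr2", 30_000_000, 32_000_000, 20.0, 0.0),
            ],
            columns=["trait_id", "gene_id", "eqtl_type", "chrom", "start", "end", "max_lr", "fdr"],
        )
        for order in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            g = build_connectivity_map(
                {"d": [("G1", "direct"), ("G2", "direct"), ("G3", "direct")]},
                calls.iloc[order],
            )
            assert distinct_drug_loci(g) == {"d": 2}

    def test_summaries_table(self, toy_graph):
        s = graph_summaries(toy_graph).set_index("drug")
        assert s.loc["drugD", "n_genes"] == 4
        assert s.loc["drugD", "n_eqtls"] == 4
        assert s.loc["drugD", "n_distinct_loci"] == 3


class TestSharedEnzymes:
    def test_toy_shared_enzymes_match_enumeration(self, toy_graph):
        shared = shared_enzymes(toy_graph)
        assert list(shared["gene_id"]) == ["G04", "G05", "G02"]
        assert list(shared["n_drugs"]) == [3, 3, 2]

    def test_threshold_excludes_single_drug_genes(self, toy_graph):
        assert "G01" not in set(shared_enzymes(toy_graph)["gene_id"])

    def test_empty_graph_gives_empty_list(self):
        import networkx as nx

        assert len(shared_enzymes(nx.Graph())) == 0


class TestEnrichment:
    def test_small_closed_form(self):
        p, counts = hypergeom_enrichment(["a", "b"], ["a", "b"], list("abcde"))
        assert p == pytest.approx(0.1, abs=1e-12)
        assert counts == {"universe": 5, "annotated": 2, "targets": 2, "overlap": 2}

    def test_zero_overlap_is_certain(self):
        p, _ = hypergeom_enrichment(["a"], ["b"], ["a", "b", "c"])
        assert p == 1.0

    def test_matches_exact_tail_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 120))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"u{i}" for i in range(N)]
            annotated = list(rng.choice(universe, size=K, replace=False))
            targets = list(rng.choice(universe, size=n, replace=False))
            k = len(set(annotated) & set(targets))
            p, _ = hypergeom_enrichment(targets, annotated, universe)
            assert p == pytest.approx(hypergeom_tail_exact(N, K, n, k), abs=1e-12)

    def test_subset_violations_listed(self):
        with pytest.raises(ValueError, match="ghost"):
            hypergeom_enrichment(["ghost"], ["a"], ["a", "b"])


class TestRepresentativeLines:
    def _blocks(self):
        # two well-separated response blocks of three lines each
        rng = np.random.default_rng(4)
        base_a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        base_b = base_a[::-1]
        rows = [base_a + rng.normal(0, 0.05, 6) for _ in range(3)]
        rows += [base_b + rng.normal(0, 0.05, 6) for _ in range(3)]
        return pd.DataFrame(rows, index=[f"L{i}" for i in range(6)])

    def test_k_equal_n_returns_all_lines(self):
        mat = self._blocks()
        assert select_representative_lines(mat, 6) == list(mat.index)

    def test_two_blocks_yield_one_line_each(self):
        mat = self._blocks()
        reps = select_representative_lines(mat, 2)
        assert len(reps) == 2
        assert ({reps[0], reps[1]} & {"L0", "L1", "L2"}) and (
            {reps[0], reps[1]} & {"L3", "L4", "L5"}
        )

    def test_identical_profiles_collapse_first(self):
        mat = self._blocks()
        mat.loc["L1"] = mat.loc["L0"]  # byte-identical pair
        reps = select_representative_lines(mat, 5)
        assert not {"L0", "L1"} <= set(reps)

    def test_invalid_inputs_rejected(self):
        mat = self._blocks()
        with pytest.raises(ValueError):
            select_representative_lines(mat, 0)
        with pytest.raises(ValueError):
            select_representative_lines(mat, 7)
        with pytest.raises(ValueError):
            select_representative_lines(pd.DataFrame(np.ones((4, 3))), 2)
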