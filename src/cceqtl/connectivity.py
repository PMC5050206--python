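"""The eQTL-drug connectivity map and its summaries.

A tripartite graph links drugs to the enzymes known to take part in their
biotransformation (with direct or indirect evidence) and each enzyme gene
to the proximal eQTLs that regulate it.  Construction follows three
steps: (1) load curated drug-specific gene sets with direct evidence;
(2) expand each set with alternative genes catalyzing the same chemical
reaction (same EC number), added with indirect evidence; (3) keep only
genes associated with at least one proximal eQTL, dropping drugs whose
sets become empty.

Summaries include per-drug counts of distinct genomic loci (eQTLs merged
when closer than 10 Mb), enzymes shared between drugs, hypergeometric
over-representation of eQTL genes in an annotated set, and selection of a
non-redundant panel of representative lines per drug by hierarchical
clustering of expression profiles.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

EVIDENCE_LEVELS = ("direct", "indirect")
MIN_LOCUS_SEPARATION_BP = 10_000_000
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|n\d+)$")

DrugGeneSets = dict[str, list[tuple[str, str]]]  # drug -> [(gene, evidence)]


def load_drug_gene_sets(path) -> DrugGeneSets:
    """Load curated drug gene sets from JSON ``{drug: [{gene, evidence}]}``.

    A gene listed under one drug with both evidence labels is collapsed
    to a single entry keeping the stronger (direct) label.  Malformed
    records raise with the offending drug and entry index.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: drug-set file must be a JSON object")
    sets: DrugGeneSets = {}
    for drug, entries in raw.items():
        seen: dict[str, str] = {}
        if not isinstance(entries, list):
            raise ValueError(f"{path}: drug {drug!r}: expected a list of records")
        for i, rec in enumerate(entries):
            if not isinstance(rec, dict) or "gene" not in rec or "evidence" not in rec:
                raise ValueError(f"{path}: drug {drug!r}, record {i}: need 'gene' and 'evidence'")
            gene, ev = rec["gene"], rec["evidence"]
            if ev not in EVIDENCE_LEVELS:
                raise ValueError(
                    f"{path}: drug {drug!r}, record {i}: unknown evidence {ev!r}"
                )
            if gene in seen:
                if ev == "direct":
                    seen[gene] = "direct"
            else:
                seen[gene] = ev
        sets[drug] = sorted(seen.items())
    return sets


def load_ec_map(path) -> dict[str, set[str]]:
    """Load a gene -> EC-number map from TSV (gene_id, ec); may be partial."""
    table = pd.read_csv(path, sep="\t")
    ec_map: dict[str, set[str]] = {}
    for gene, ec in zip(table["gene_id"], table["ec"]):
        ec = str(ec).strip()
        if not _EC_RE.match(ec):
            raise ValueError(f"{path}: malformed EC number {ec!r} for gene {gene!r}")
        ec_map.setdefault(gene, set()).add(ec)
    return ec_map


def expand_by_ec(sets: DrugGeneSets, ec_map: dict[str, set[str]]) -> DrugGeneSets:
    """Add alternative genes of the same chemical reaction (shared EC number).

    Single pass over the curated members: a gene sharing an EC number with
    any curated member of a drug's set joins that set with indirect
    evidence; genes added this way do not seed further expansion, and
    existing direct members are never downgraded.
    """
    by_ec: dict[str, set[str]] = {}
    for gene, ecs in ec_map.items():
        for ec in ecs:
            by_ec.setdefault(ec, set()).add(gene)
    out: DrugGeneSets = {}
    for drug, members in sets.items():
        merged = dict(members)
        for gene, _ in members:
            for ec in ec_map.get(gene, ()):
                for alt in by_ec[ec]:
                    if alt not in merged:
                        merged[alt] = "indirect"
        out[drug] = sorted(merged.items())
    return out


def filter_by_eqtl(sets: DrugGeneSets, eqtl_calls: pd.DataFrame) -> DrugGeneSets:
    """Keep only genes with at least one eQTL call; drop emptied drugs."""
    with_call = set(eqtl_calls["gene_id"]) if len(eqtl_calls) else set()
    out: DrugGeneSets = {}
    for drug, members in sets.items():
        keep = [(g, ev) for g, ev in members if g in with_call]
        if keep:
            out[drug] = keep
    return out


def build_connectivity_map(filtered_sets: DrugGeneSets, eqtl_calls: pd.DataFrame) -> nx.Graph:
    """Assemble the tripartite drug / gene / eQTL graph.

    Nodes carry ``node_type`` in {drug, gene, eqtl}; eQTL nodes are keyed
    by interval ``chrom:start-end`` (deduplicated) and annotated with the
    eQTL types observed there.  Drug-gene edges carry the evidence label;
    gene-eQTL edges carry the eQTL type(s) linking that gene to that
    interval.
    """
    calls_by_gene: dict[str, list] = {}
    for rec in eqtl_calls.to_dict("records"):
        calls_by_gene.setdefault(rec["gene_id"], []).append(rec)
    missing = sorted(
        {g for members in filtered_sets.values() for g, _ in members} - set(calls_by_gene)
    )
    if missing:
        raise ValueError(f"genes without any eQTL call reached the map builder: {missing}")
    g = nx.Graph()
    for drug, members in filtered_sets.items():
        g.add_node(f"drug:{drug}", node_type="drug", label=drug)
        for gene, ev in members:
            gene_node = f"gene:{gene}"
            if gene_node not in g:
                g.add_node(gene_node, node_type="gene", label=gene)
            g.add_edge(f"drug:{drug}", gene_node, evidence=ev)
            for rec in calls_by_gene[gene]:
                key = f"eqtl:{rec['chrom']}:{rec['start']}-{rec['end']}"
                if key not in g:
                    g.add_node(
                        key, node_type="eqtl", chrom=rec["chrom"],
                        start=int(rec["start"]), end=int(rec["end"]),
                    )
                if g.has_edge(gene_node, key):
                    types = set(g.edges[gene_node, key]["eqtl_types"].split(";"))
                else:
                    types = set()
                types.add(rec["eqtl_type"])
                g.add_edge(gene_node, key, eqtl_types=";".join(sorted(types)))
    return g


def _drug_eqtl_intervals(graph: nx.Graph, drug_node: str) -> list[tuple[str, int, int]]:
    seen = set()
    for gene_node in graph.neighbors(drug_node):
        for nb in graph.neighbors(gene_node):
            if graph.nodes[nb]["node_type"] == "eqtl":
                d = graph.nodes[nb]
                seen.add((d["chrom"], d["start"], d["end"]))
    return sorted(seen)


def distinct_drug_loci(graph: nx.Graph, min_separation: int = MIN_LOCUS_SEPARATION_BP) -> dict[str, int]:
    """Count distinct genomic loci per drug.

    Per chromosome, a drug's eQTL intervals are merged by single linkage
    whenever the boundary gap is smaller than ``min_separation``
    (intervals exactly ``min_separation`` apart stay distinct); the
    number of merged clusters, summed over chromosomes, is the locus
    count.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be nonnegative")
    counts: dict[str, int] = {}
    for node, data in graph.nodes(data=True):
        if data["node_type"] != "drug":
            continue
        intervals = _drug_eqtl_intervals(graph, node)
        n_loci = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            cluster_end = None
            for start, end in ivs:
                if cluster_end is None or start - cluster_end >= min_separation:
                    n_loci += 1
                    cluster_end = end
                else:
                    cluster_end = max(cluster_end, end)
        counts[data["label"]] = n_loci
    return counts


def shared_enzymes(graph: nx.Graph, min_drugs: int = 2) -> pd.DataFrame:
    """Genes participating in the biotransformation of >= ``min_drugs`` drugs."""
    rows = []
    for node, data in graph.nodes(data=True):
        if data["node_type"] != "gene":
            continue
        drugs = sorted(
            graph.nodes[nb]["label"]
            for nb in graph.neighbors(node)
            if graph.nodes[nb]["node_type"] == "drug"
        )
        if len(drugs) >= min_drugs:
            rows.append(dict(gene_id=data["label"], n_drugs=len(drugs), drugs=";".join(drugs)))
    return pd.DataFrame(rows, columns=["gene_id", "n_drugs", "drugs"]).sort_values(
        ["n_drugs", "gene_id"], ascending=[False, True], ignore_index=True
    )


def hypergeom_enrichment(target_genes, annotated_set, universe) -> tuple[float, dict]:
    """One-sided over-representation test of ``target_genes`` in ``annotated_set``.

    With ``N = |universe|``, ``K = |annotated_set|``, ``n = |target_genes|``
    and overlap ``k``, returns ``P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)`` computed by summing the exact pmf,
    plus the counts used.
    """
    target, annotated, univ = set(target_genes), set(annotated_set), set(universe)
    bad_t = sorted(target - univ)
    bad_a = sorted(annotated - univ)
    if bad_t or bad_a:
        raise ValueError(
            f"sets must be subsets of the universe; offending targets {bad_t}, annotated {bad_a}"
        )
    big_n, big_k, n = len(univ), len(annotated), len(target)
    k = len(target & annotated)
    upper = min(big_k, n)
    p = float(np.sum(hypergeom.pmf(np.arange(k, upper + 1), big_n, big_k, n)))
    p = min(1.0, p)
    counts = dict(universe=big_n, annotated=big_k, targets=n, overlap=k)
    return p, counts


def select_representative_lines(expression_submatrix: pd.DataFrame, k: int) -> list[str]:
    """Pick ``k`` lines covering the variety of expression responses.

    Rows are lines (mean expression over a drug's eQTL-target genes);
    columns are standardized per gene.  Lines are clustered by
    average-linkage hierarchical clustering on correlation distance, the
    tree is cut into ``k`` clusters, and the line nearest its cluster
    centroid (Euclidean, in standardized space) represents each cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(expression_submatrix):
        raise ValueError("k cannot exceed the number of lines")
    mat = expression_submatrix.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("expression matrix is constant; lines are indistinguishable")
    std = (mat - mat.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    row_sd = std.std(axis=1)
    if np.any(row_sd == 0):
        flat = list(expression_submatrix.index[row_sd == 0])
        raise ValueError(f"constant line profiles have undefined correlation: {flat}")
    if k == len(expression_submatrix):
        return list(expression_submatrix.index)
    dist = pdist(std, metric="correlation")
    tree = linkage(dist, method="average")
    assignment = fcluster(tree, t=k, criterion="maxclust")
    reps = []
    for c in range(1, k + 1):
        members = np.flatnonzero(assignment == c)
        centroid = std[members].mean(axis=0)
        best = members[int(np.argmin(np.linalg.norm(std[members] - centroid, axis=1)))]
        reps.append(expression_submatrix.index[best])
    return sorted(reps)


def graph_summaries(graph: nx.Graph, min_separation: int = MIN_LOCUS_SEPARATION_BP) -> pd.DataFrame:
    """Per-drug summary: number of genes, eQTLs and distinct loci."""
    loci = distinct_drug_loci(graph, min_separation)
    rows = []
    for node, data in graph.nodes(data=True):
        if data["node_type"] != "drug":
            continue
        genes = [nb for nb in graph.neighbors(node) if graph.nodes[nb]["node_type"] == "gene"]
        eqtls = {
            nb
            for g in genes
            for nb in graph.neighbors(g)
            if graph.nodes[nb]["node_type"] == "eqtl"
        }
        rows.append(
            dict(drug=data["label"], n_genes=len(genes), n_eqtls=len(eqtls),
                 n_distinct_loci=loci[data["label"]])
        )
    return pd.DataFrame(rows, columns=["drug", "n_genes", "n_eqtls", "n_distinct_loci"]).sort_values(
        "drug", ignore_index=True
    )


def write_graph(graph: nx.Graph, out_prefix) -> dict[str, Path]:
    """Write the map as GraphML and node-link JSON."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": out_prefix.with_suffix(".graphml"),
        "json": out_prefix.with_suffix(".json"),
    }
    nx.write_graphml(graph, paths["graphml"])
    with open(paths["json"], "w") as fh:
        json.dump(nx.node_link_data(graph, edges="edges"), fh, indent=1, sort_keys=True)
    return paths
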