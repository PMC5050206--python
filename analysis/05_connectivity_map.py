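#!/usr/bin/env python
"""Build the eQTL-drug connectivity map over the study's called genes.

Assembles a synthetic curated drug-gene collection over the study's gene
universe (each drug gets a handful of member genes, some of which carry
eQTL calls), expands it by shared EC numbers, filters to eQTL-associated
genes, and builds the tripartite drug/gene/eQTL graph with its
summaries: distinct loci per drug (>= 10 Mb apart), shared enzymes,
hypergeometric enrichment of drug genes among eQTL genes, and a
representative, non-redundant panel of lines per drug.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cceqtl.connectivity import (
    build_connectivity_map,
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
from cceqtl.rng import substream
from cceqtl.simulate import read_trait_matrix

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
STUDY = Path(__file__).resolve().parent.parent / "results" / "study"
OUT = Path(__file__).resolve().parent.parent / "results" / "connectivity"


def synthesize_drug_collection(genes, called, rng, n_drugs=12):
    """Random curated sets over the study genes, enriched in called genes."""
    sets = {}
    called = [g for g in genes if g in called]
    uncalled = [g for g in genes if g not in called]
    for d in range(n_drugs):
        n_hit = int(rng.integers(0, min(4, len(called)) + 1))
        n_miss = int(rng.integers(1, 4))
        members = list(rng.choice(called, size=n_hit, replace=False)) if n_hit else []
        members += list(rng.choice(uncalled, size=n_miss, replace=False))
        sets[f"drug{d + 1:02d}"] = [
            {"gene": g, "evidence": "direct"} for g in sorted(set(members))
        ]
    return sets


def synthesize_ec_map(genes, rng, n_pairs=10):
    rows = []
    picks = rng.choice(genes, size=(n_pairs, 2), replace=True)
    for i, (a, b) in enumerate(picks):
        ec = f"{1 + i % 4}.{1 + i % 6}.{1 + i % 3}.{i + 1}"
        rows.append((a, ec))
        rows.append((b, ec))
    return pd.DataFrame(rows, columns=["gene_id", "ec"]).drop_duplicates()


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    calls = pd.read_csv(STUDY / "eqtl_calls.tsv", sep="\t")
    annotation = pd.read_csv(STUDY / "annotation.tsv", sep="\t")
    genes = sorted(annotation["gene_id"])
    called = set(calls["gene_id"])
    rng = substream(SEED, "drug-collection")

    sets_path = OUT / "drug_sets.synthetic.json"
    sets_path.write_text(
        json.dumps(synthesize_drug_collection(genes, called, rng), indent=1, sort_keys=True)
    )
    ec_path = OUT / "ec_map.synthetic.tsv"
    synthesize_ec_map(genes, rng).to_csv(ec_path, sep="\t", index=False)

    sets = load_drug_gene_sets(sets_path)
    ec = load_ec_map(ec_path)
    expanded = expand_by_ec(sets, ec)
    filtered = filter_by_eqtl(expanded, calls)
    if not filtered:
        print("no drug retained any eQTL-associated gene; map is empty")
        return
    graph = build_connectivity_map(filtered, calls)
    write_graph(graph, OUT / "connectivity_map")
    summaries = graph_summaries(graph)
    summaries.to_csv(OUT / "drug_summaries.tsv", sep="\t", index=False)
    shared = shared_enzymes(graph)
    shared.to_csv(OUT / "shared_enzymes.tsv", sep="\t", index=False)

    types = [d["node_type"] for _, d in graph.nodes(data=True)]
    print(f"map: {types.count('drug')} drugs, {types.count('gene')} genes, "
          f"{types.count('eqtl')} eQTLs, {graph.number_of_edges()} edges")
    multi = (summaries["n_distinct_loci"] >= 2).sum()
    print(f"{multi} drugs are hit by >= 2 distinct loci (>= 10 Mb apart)")
    print(f"{len(shared)} enzymes serve >= 2 drugs")

    # enrichment: are drug-set genes over-represented among eQTL genes?
    drug_genes = {g for members in expanded.values() for g, _ in members}
    p, counts = hypergeom_enrichment(
        sorted(drug_genes), sorted(called & set(genes)), genes
    )
    print(f"drug genes vs eQTL genes: overlap {counts['overlap']} "
          f"(P = {p:.3g}, hypergeometric)")

    # representative lines over the most-connected drug's gene panel
    top_drug = summaries.sort_values("n_genes", ascending=False).iloc[0]["drug"]
    panel = [g for g, _ in filtered[top_drug]]
    total = read_trait_matrix(STUDY / "traits_total.tsv")
    sub = total.values.loc[total.meta["gene_id"].isin(panel).to_numpy()]
    if len(sub) >= 1:
        line_means = sub.T.groupby(
            total.samples.set_index("sample_id")["line_id"]
        ).mean()
        k = min(6, len(line_means))
        try:
            reps = select_representative_lines(np.log1p(line_means), k)
            print(f"{top_drug}: {k} representative lines out of "
                  f"{len(line_means)}: {', '.join(reps)}")
        except ValueError as exc:
            print(f"{top_drug}: representative-line selection degenerate ({exc})")


if __name__ == "__main__":
    main()
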