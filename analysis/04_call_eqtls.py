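#!/usr/bin/env python
"""Permutation FDR and eQTL calling.

Builds the null distribution of the per-trait max LR by re-scanning all
traits under 100 shared shufflings of the line labels, computes the
permutation FDR curve C_perm/C_real, and calls eQTLs at FDR < 0.01.
Writes the null, the FDR curve, the calls and the dual-eQTL gene list
under results/study/, and compares the calls with the simulated truth.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cceqtl.scan import prepare_traitset_contexts, scan_traitset
from cceqtl.significance import call_eqtls, dual_eqtl_genes, fdr_curve, null_scan
from cceqtl.simulate import FounderDosageTable, read_trait_matrix
from cceqtl.transform import select_traits

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_PERM = 100
STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main():
    dosage = FounderDosageTable.from_frame(pd.read_csv(STUDY / "dosages.tsv", sep="\t"))
    total = read_trait_matrix(STUDY / "traits_total.tsv")
    isoform = read_trait_matrix(STUDY / "traits_isoform.tsv")
    annotation = pd.read_csv(STUDY / "annotation.tsv", sep="\t")
    trait_set = select_traits(total, isoform, annotation)

    contexts = prepare_traitset_contexts(trait_set, dosage)
    scans = scan_traitset(trait_set, dosage, contexts=contexts)
    null = null_scan(trait_set, dosage, n_perm=N_PERM, seed=SEED, contexts=contexts)
    real = np.array([r.max_lr if r.scannable else np.nan for r in scans])
    table = fdr_curve(real, null)
    calls = call_eqtls(scans, table, dosage, target_fdr=0.01)
    dual = dual_eqtl_genes(calls)

    null.to_frame().to_csv(STUDY / "null_max_lr.tsv", sep="\t", index=False)
    table.to_frame().to_csv(STUDY / "fdr_curve.tsv", sep="\t", index=False)
    calls.to_csv(STUDY / "eqtl_calls.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": dual}).to_csv(STUDY / "dual_eqtl_genes.tsv", sep="\t", index=False)

    by_type = calls["eqtl_type"].value_counts()
    print(f"{len(calls)} eQTLs at permutation FDR < 0.01 ({N_PERM} permutations):")
    for t, n in by_type.items():
        print(f"  {n:4d}  {t}")
    print(f"{len(dual)} genes carry both a total-expression and an isoform-ratio eQTL")

    truth = pd.read_csv(STUDY / "ground_truth.tsv", sep="\t")
    causal = set(truth.loc[truth["causal_start"] >= 0, "trait_id"])
    called = set(calls["trait_id"])
    tp = len(called & causal)
    # isoform percentages are coupled within a gene, so a cis effect on one
    # isoform is legitimately detectable through a sibling isoform: judge
    # false calls at the gene level
    causal_genes = set(truth.loc[truth["causal_start"] >= 0, "gene_id"])
    false_genes = set(calls["gene_id"]) - causal_genes
    print(f"against the simulated truth: {tp} causal traits recovered directly, "
          f"{len(false_genes)} called genes carry no causal effect")


if __name__ == "__main__":
    main()
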