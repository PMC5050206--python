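#!/usr/bin/env python
"""Simulate the study population and expression data.

Generates a CC-like panel of 29 inbred lines (1-3 replicates each, ~55
samples) with mosaic founder genomes on two 100-Mb chromosomes, then
simulates total-expression (FPKM-scale) and isoform-ratio (percent)
traits with a known ground-truth table of cis effects, and writes the
fixture consumed by the downstream steps to results/study/.
"""

import sys
from pathlib import Path

from cceqtl.pipeline import StudyConfig, annotation_table, build_trait_specs
from cceqtl.simulate import (
    dosage_from_mosaic,
    ground_truth_table,
    simulate_cc_population,
    simulate_isoform_ratios,
    simulate_total_expression,
    write_fixture,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main():
    config = StudyConfig()
    genome = config.genome()
    mosaics = simulate_cc_population(config.n_lines, genome, config.recomb_rate_per_mb, SEED)
    dosage = dosage_from_mosaic(mosaics, config.dosage_uncertainty)
    total_specs, gene_specs = build_trait_specs(config, SEED)
    total = simulate_total_expression(dosage, total_specs, config.rep_probs, SEED)
    isoform = simulate_isoform_ratios(dosage, gene_specs, config.rep_probs, SEED)
    annotation = annotation_table(total_specs, gene_specs)
    truth = ground_truth_table(genome, total_specs, gene_specs)
    paths = write_fixture(dosage, [total, isoform], annotation, OUT, ground_truth=truth)

    n_causal = int((truth["causal_start"] >= 0).sum())
    print(f"simulated {config.n_lines} lines, {len(total.samples)} samples")
    print(f"{len(total.values)} total-expression traits, {len(isoform.values)} isoform traits")
    print(f"{n_causal} traits carry a cis founder allelic series (see ground_truth.tsv)")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
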