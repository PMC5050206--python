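#!/usr/bin/env python
"""Transform and filter the expression traits.

Reads the simulated fixture, applies the bin-size rounding and van der
Waerden normal-scores transformation, and filters to the association
trait set: expressed total traits (v_M >= 2, >= 12 distinct rounded
levels) and one isoform-ratio trait per expressed gene (the isoform with
the most distinct rounded levels).  Writes the transformed matrix and a
per-trait selection report under results/study/.
"""

from pathlib import Path

import pandas as pd

from cceqtl.simulate import read_trait_matrix
from cceqtl.transform import select_traits

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main():
    total = read_trait_matrix(STUDY / "traits_total.tsv")
    isoform = read_trait_matrix(STUDY / "traits_isoform.tsv")
    annotation = pd.read_csv(STUDY / "annotation.tsv", sep="\t")
    trait_set = select_traits(total, isoform, annotation)

    trait_set.report.to_csv(STUDY / "trait_selection.tsv", sep="\t", index=False)
    trait_set.to_frame().to_csv(STUDY / "traits_transformed.tsv", sep="\t")

    rep = trait_set.report
    for kind in ("total", "isoform_ratio"):
        sub = rep[rep["kind"] == kind]
        print(
            f"{kind}: {int(sub['kept'].sum())} of {len(sub)} traits retained "
            f"({(~sub['kept']).sum()} filtered)"
        )
    reasons = rep.loc[~rep["kept"], "reason"].value_counts()
    print("exclusion reasons:")
    for reason, n in reasons.items():
        print(f"  {n:4d}  {reason}")


if __name__ == "__main__":
    main()
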