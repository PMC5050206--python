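"""Packaged synthetic fixtures.

A small hand-curated drug-gene collection (5 drugs, 12 genes), an EC map
and a matching synthetic eQTL call table, used to exercise the
connectivity-map construction end to end.  All values are invented; the
files are labelled ``synthetic`` accordingly.
"""

from importlib import resources
from pathlib import Path


def synthetic_collection() -> dict[str, Path]:
    """Paths of the synthetic drug-set / EC-map / eQTL-call fixture."""
    base = resources.files(__name__)
    return {
        "drug_sets": Path(str(base / "drug_sets.synthetic.json")),
        "ec_map": Path(str(base / "ec_map.synthetic.tsv")),
        "eqtl_calls": Path(str(base / "eqtl_calls.synthetic.tsv")),
    }
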