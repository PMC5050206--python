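"""Genome interval grids.

The association machinery works on a fixed grid of genome intervals tiling
each chromosome (the analogue of the haplotype-reconstruction grid of a
genotyping array).  Coordinates are 0-based half-open (BED convention); a
transcription start site (TSS) is a 0-based point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FOUNDERS = 8


class ConfigurationError(ValueError):
    """Raised for invalid genome or simulation configuration."""


@dataclass(frozen=True)
class GenomeSpec:
    """A genome as a list of chromosomes tiled by equal-size intervals.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    interval_size
        Interval width in bp.  Each chromosome is tiled left to right;
        the final interval is truncated at the chromosome end.
    """

    chromosomes: tuple[tuple[str, int], ...]
    interval_size: int

    def __init__(self, chromosomes, interval_size: int):
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in chromosomes))
        object.__setattr__(self, "interval_size", int(interval_size))
        if self.interval_size <= 0:
            raise ConfigurationError(f"interval_size must be positive, got {interval_size}")
        if not self.chromosomes:
            raise ConfigurationError("genome must contain at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name!r} has non-positive length {length}")

    def intervals(self) -> pd.DataFrame:
        """Return the interval grid as a DataFrame (chrom, start, end).

        Intervals tile each chromosome without overlap; the row index is
        the global interval id used by dosage tables and scan results.
        """
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.interval_size, dtype=np.int64)
            ends = np.minimum(starts + self.interval_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        out = pd.concat(rows, ignore_index=True)
        out.index.name = "interval_id"
        return out

    @property
    def n_intervals(self) -> int:
        return sum(-(-length // self.interval_size) for _, length in self.chromosomes)
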