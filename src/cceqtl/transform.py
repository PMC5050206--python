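"""Trait transformation and filtering.

Expression traits (FPKM or isoform percentages) are prepared for
association testing in three steps:

1. round each trait to its bin size ``delta = max(0.5, v_M / 200)``,
   where ``v_M`` is the trait's maximum over samples — 0.5 is a fixed
   accuracy floor and ``v_M/200`` is 0.5% of the maximum;
2. apply the van der Waerden normal-scores transformation to the rounded
   values, ``u_i = Phi^{-1}(r*_i / (n + 1))`` with average ranks for ties;
3. filter: total-expression traits are kept when expressed (``v_M >= 2``)
   and variable (>= 12 distinct rounded levels); for each expressed gene a
   single isoform-ratio trait — the isoform with the most distinct rounded
   levels — is kept under the same variability filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from cceqtl.simulate import ExpressionMatrix

MIN_EXPRESSED_VM = 2.0
MIN_DISTINCT_LEVELS = 12


def bin_size(values) -> float:
    """Bin size ``delta = max(0.5, v_M / 200)`` of a trait."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bin_size requires at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("bin_size requires finite values")
    return max(0.5, float(values.max()) / 200.0)


def round_to_bins(values, delta: float) -> np.ndarray:
    """Round values to multiples of ``delta``, halves away from zero.

    Idempotent: re-rounding already-rounded values is a no-op (a small
    relative tolerance absorbs representation error of ``v/delta``).
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    values = np.asarray(values, dtype=float)
    scaled = values / delta
    # nudge exact-half representations before floor-based half-away rounding
    rounded = np.floor(np.abs(scaled) + 0.5 + 1e-9) * np.sign(scaled)
    return rounded * delta


def distinct_level_count(values, delta: float | None = None) -> int:
    """Number of distinct rounded levels of a trait.

    If ``delta`` is None the values are assumed already rounded;
    otherwise they are rounded to ``delta`` first.
    """
    values = np.asarray(values, dtype=float)
    if delta is not None:
        values = round_to_bins(values, delta)
    return int(np.unique(values).size)


def normal_scores(values, delta: float | None = None) -> np.ndarray:
    """Van der Waerden normal scores of a trait.

    Values are rounded to the bin size (computed from the data when
    ``delta`` is None), ranked with average ranks for ties, and mapped
    through ``Phi^{-1}(r / (n + 1))``.  The output is strictly monotone in
    the rounded values; an all-tied input maps to all zeros.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("normal_scores requires at least two values")
    if delta is None:
        delta = bin_size(values)
    rounded = round_to_bins(values, delta)
    ranks = rankdata(rounded, method="average")
    return norm.ppf(ranks / (n + 1))


@dataclass
class TransformedTrait:
    trait_id: str
    gene_id: str
    kind: str
    tss: tuple[str, int]
    u: np.ndarray
    delta: float
    rounded: np.ndarray
    distinct_levels: int


@dataclass
class TraitSet:
    """Retained transformed traits plus a per-trait selection report."""

    traits: list[TransformedTrait]
    samples: pd.DataFrame  # sample_id, line_id
    report: pd.DataFrame  # trait_id, kind, v_M, delta, distinct_levels, kept, reason

    def __len__(self) -> int:
        return len(self.traits)

    def to_frame(self) -> pd.DataFrame:
        """Transformed values as a trait x sample table."""
        rows = {t.trait_id: t.u for t in self.traits}
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.samples["sample_id"])


def _transform_row(trait_id, gene_id, kind, tss, values) -> TransformedTrait:
    delta = bin_size(values)
    rounded = round_to_bins(values, delta)
    return TransformedTrait(
        trait_id=trait_id,
        gene_id=gene_id,
        kind=kind,
        tss=tss,
        u=normal_scores(values, delta),
        delta=delta,
        rounded=rounded,
        distinct_levels=distinct_level_count(rounded),
    )


def select_traits(
    total: ExpressionMatrix | None,
    isoform: ExpressionMatrix | None,
    annotation: pd.DataFrame,
    min_vm: float = MIN_EXPRESSED_VM,
    min_levels: int = MIN_DISTINCT_LEVELS,
) -> TraitSet:
    """Apply the expression and variability filters and transform traits.

    Total-expression traits are retained when ``v_M >= min_vm`` and the
    number of distinct rounded levels is at least ``min_levels``.  For
    isoform-ratio traits, each expressed gene contributes one candidate —
    the isoform with the largest distinct-level count (ties: higher mean
    percentage, then lexicographically smallest isoform id; isoforms that
    are zero in every sample are not candidates) — retained under the same
    distinct-level filter.
    """
    known_genes = set(annotation["gene_id"])
    kept: list[TransformedTrait] = []
    report_rows = []
    samples = None
    expressed_genes: set[str] = set()
    genes_with_total: set[str] = set(total.meta["gene_id"]) if total is not None else set()

    if total is not None:
        samples = total.samples
        order = np.argsort(total.meta["trait_id"].to_numpy(), kind="stable")
        for i in order:
            row = total.meta.iloc[i]
            vals = total.values.iloc[i].to_numpy(dtype=float)
            v_m = float(vals.max())
            delta = bin_size(vals)
            levels = distinct_level_count(vals, delta)
            keep, reason = True, "kept"
            if v_m < min_vm:
                keep, reason = False, f"v_M {v_m:g} < {min_vm:g}"
            elif levels < min_levels:
                keep, reason = False, f"{levels} distinct levels < {min_levels}"
            if v_m >= min_vm:
                expressed_genes.add(row["gene_id"])
            report_rows.append(
                dict(trait_id=row["trait_id"], kind="total", v_M=v_m, delta=delta,
                     distinct_levels=levels, kept=keep, reason=reason)
            )
            if keep:
                kept.append(
                    _transform_row(row["trait_id"], row["gene_id"], "total",
                                   (row["tss_chrom"], int(row["tss_pos"])), vals)
                )

    if isoform is not None:
        if samples is None:
            samples = isoform.samples
        missing = sorted(set(isoform.meta["gene_id"]) - known_genes)
        if missing:
            raise ValueError(f"isoform traits reference genes absent from annotation: {missing}")
        meta = isoform.meta
        for gene_id in sorted(meta["gene_id"].unique()):
            # the expression filter applies through the gene's total trait;
            # genes without one cannot be assessed and pass through
            if gene_id in genes_with_total and gene_id not in expressed_genes:
                for tid in meta.loc[meta["gene_id"] == gene_id, "trait_id"]:
                    report_rows.append(
                        dict(trait_id=tid, kind="isoform_ratio", v_M=np.nan, delta=np.nan,
                             distinct_levels=0, kept=False, reason="gene not expressed")
                    )
                continue
            sub = meta.index[meta["gene_id"] == gene_id]
            best = None  # (levels, mean, trait_id, values, row)
            for i in sub:
                row = meta.loc[i]
                vals = isoform.values.loc[row["trait_id"]].to_numpy(dtype=float)
                if not np.any(vals > 0):
                    report_rows.append(
                        dict(trait_id=row["trait_id"], kind="isoform_ratio", v_M=0.0,
                             delta=0.5, distinct_levels=1, kept=False, reason="undetected isoform")
                    )
                    continue
                delta = bin_size(vals)
                levels = distinct_level_count(vals, delta)
                cand = (levels, float(vals.mean()), row["trait_id"], vals, row)
                if best is None or (cand[0], cand[1], _neg_id(cand[2])) > (
                    best[0], best[1], _neg_id(best[2])
                ):
                    if best is not None:
                        report_rows.append(_iso_report(best, "not the selected isoform"))
                    best = cand
                else:
                    report_rows.append(_iso_report(cand, "not the selected isoform"))
            if best is None:
                continue
            levels, _, tid, vals, row = best
            if levels < min_levels:
                report_rows.append(_iso_report(best, f"{levels} distinct levels < {min_levels}"))
            else:
                report_rows.append(_iso_report(best, "kept"))
                kept.append(
                    _transform_row(tid, gene_id, "isoform_ratio",
                                   (row["tss_chrom"], int(row["tss_pos"])), vals)
                )

    report = pd.DataFrame(
        report_rows,
        columns=["trait_id", "kind", "v_M", "delta", "distinct_levels", "kept", "reason"],
    )
    return TraitSet(traits=kept, samples=samples, report=report)


class _neg_id(str):
    """String wrapper with reversed ordering, for 'smallest id wins' in a max."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _iso_report(cand, reason):
    levels, mean_v, tid, vals, _ = cand
    return dict(
        trait_id=tid, kind="isoform_ratio", v_M=float(np.max(vals)),
        delta=bin_size(vals), distinct_levels=levels, kept=reason == "kept", reason=reason,
    )
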