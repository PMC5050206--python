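"""Permutation-based FDR and eQTL calling.

The null distribution of the trait-level max-LR statistic is built by
shuffling CC line labels: each permutation replicate reassigns genotypes
to lines by a uniform random bijection (replicates of a line stay
together, so only the fixed genetic effect is randomized while the
line-level random effect structure is preserved) and rescans every trait
over the same proximal intervals.

For a threshold ``t``, ``C_real(t)`` counts traits whose real max LR
exceeds ``t`` and ``C_perm(t)`` the average count over permutation
replicates; the permutation FDR is ``C_perm(t) / C_real(t)``, clipped to
[0, 1] and made monotone so that raising the threshold never raises the
FDR.  An eQTL is a trait whose max LR clears the minimal threshold with
FDR below the target (default 0.01); its reported interval is the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cceqtl.rng import substream
from cceqtl.scan import (
    PROXIMAL_WINDOW_BP,
    ScanResult,
    prepare_traitset_contexts,
    scan_from_context,
    scan_traitset,
)
from cceqtl.simulate import FounderDosageTable
from cceqtl.transform import TraitSet

DEFAULT_N_PERM = 100
DEFAULT_TARGET_FDR = 0.01


def permute_line_labels(line_ids, seed: int, replicate: int = 0) -> np.ndarray:
    """Uniform random bijection on line ids, as a permutation array.

    Entry ``i`` gives the index of the line whose genotype line ``i``
    receives.  All samples of a line keep their line, so within-line
    replicate structure is untouched.
    """
    line_ids = list(line_ids)
    if len(line_ids) < 2:
        raise ValueError("permutation requires at least 2 lines")
    rng = substream(seed, "perm", replicate)
    return rng.permutation(len(line_ids))


@dataclass
class NullDistribution:
    """Per-permutation, per-trait max-LR values under label shuffling."""

    max_lr: np.ndarray  # (n_perm, n_traits); NaN for unscannable traits
    trait_ids: list[str]
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in range(self.n_perm):
            for t, tid in enumerate(self.trait_ids):
                rows.append((p, tid, self.max_lr[p, t]))
        return pd.DataFrame(rows, columns=["perm_index", "trait_id", "max_lr"])


def null_scan(
    trait_set: TraitSet,
    dosage_table: FounderDosageTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    window: int = PROXIMAL_WINDOW_BP,
    contexts: list | None = None,
) -> NullDistribution:
    """Build the permutation null of the trait-level max LR.

    One shared line-label permutation per replicate is applied to all
    traits (preserving inter-trait correlation under the null); traits
    with no proximal interval are carried as NaN, to be excluded
    symmetrically from real and null counts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = trait_set.samples["line_id"].to_numpy()
    line_ids = sorted(set(labels))
    if contexts is None:
        contexts = prepare_traitset_contexts(trait_set, dosage_table, window)
    trait_ids = [c.trait_id for c in contexts]
    out = np.empty((n_perm, len(trait_ids)))
    for p in range(n_perm):
        perm = permute_line_labels(line_ids, seed, replicate=p)
        for t, ctx in enumerate(contexts):
            r = scan_from_context(ctx, line_perm=perm, compute_alpha=False)
            out[p, t] = r.max_lr if r.scannable else np.nan
    return NullDistribution(max_lr=out, trait_ids=trait_ids, n_perm=n_perm, seed=seed)


@dataclass
class FdrTable:
    """Permutation-FDR curve over the grid of observed max-LR thresholds."""

    thresholds: np.ndarray  # sorted ascending (the real max-LR values)
    c_real: np.ndarray  # traits with real max LR > t
    c_perm: np.ndarray  # mean over replicates of null exceedances
    fdr: np.ndarray  # monotone-adjusted C_perm/C_real in [0, 1]
    raw_fdr: np.ndarray

    def min_threshold(self, target_fdr: float) -> float:
        """Smallest threshold whose (monotone) FDR is below ``target_fdr``."""
        ok = np.flatnonzero(self.fdr < target_fdr)
        return float(self.thresholds[ok[0]]) if ok.size else np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "c_real": self.c_real,
                "c_perm": self.c_perm,
                "raw_fdr": self.raw_fdr,
                "fdr": self.fdr,
            }
        )


def fdr_curve(real_max_lr, null_distribution: NullDistribution) -> FdrTable:
    """Permutation FDR ``C_perm(t) / C_real(t)`` over observed thresholds.

    ``real_max_lr`` may be an array aligned with the null's traits or a
    mapping trait_id -> max LR.  Traits that are NaN (unscannable) are
    dropped from both real and null counts.  The raw ratio is clipped to
    [0, 1]; with no real discoveries above a threshold the FDR is defined
    as 0.  A cumulative minimum over increasing thresholds enforces that
    the curve is non-increasing in the threshold, so call sets are nested.
    """
    if isinstance(real_max_lr, dict):
        real = np.array([real_max_lr[t] for t in null_distribution.trait_ids], dtype=float)
    else:
        real = np.asarray(real_max_lr, dtype=float)
        if real.size != len(null_distribution.trait_ids):
            raise ValueError("real statistics do not match the null's trait universe")
    keep = ~np.isnan(real)
    real = real[keep]
    null = null_distribution.max_lr[:, keep]
    thresholds = np.sort(real)
    c_real = (real[None, :] > thresholds[:, None]).sum(axis=1).astype(float)
    flat = null[~np.isnan(null)]
    # mean over replicates of exceedance counts == pooled count / n_perm
    c_perm = (flat[None, :] > thresholds[:, None]).sum(axis=1) / null_distribution.n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(c_real > 0, c_perm / np.maximum(c_real, 1e-300), 0.0)
    raw = np.clip(raw, 0.0, 1.0)
    fdr = np.minimum.accumulate(raw)  # running min over increasing t: non-increasing curve
    return FdrTable(thresholds=thresholds, c_real=c_real, c_perm=c_perm, fdr=fdr, raw_fdr=raw)


def call_eqtls(
    scan_results: list[ScanResult],
    fdr_table: FdrTable,
    dosage_table: FounderDosageTable,
    target_fdr: float = DEFAULT_TARGET_FDR,
) -> pd.DataFrame:
    """Call eQTLs: traits whose max LR exceeds the minimal passing threshold.

    Returns a tidy table (trait_id, gene_id, eqtl_type, chrom, start, end,
    max_lr, fdr) where eqtl_type is ``total-expression`` or
    ``isoform-ratio`` according to the trait kind and the interval is the
    scan argmax.  An empty table is a valid outcome.
    """
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must lie in (0, 1)")
    t_star = fdr_table.min_threshold(target_fdr)
    rows = []
    iv = dosage_table.intervals
    for r in scan_results:
        if not r.scannable or not (r.max_lr > t_star):
            continue
        pos = np.searchsorted(fdr_table.thresholds, r.max_lr, side="right") - 1
        fdr_at = float(fdr_table.fdr[pos]) if pos >= 0 else 1.0
        loc = iv.iloc[r.argmax_interval]
        rows.append(
            dict(
                trait_id=r.trait_id,
                gene_id=r.gene_id,
                eqtl_type="total-expression" if r.kind == "total" else "isoform-ratio",
                chrom=loc["chrom"],
                start=int(loc["start"]),
                end=int(loc["end"]),
                max_lr=r.max_lr,
                fdr=fdr_at,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["trait_id", "gene_id", "eqtl_type", "chrom", "start", "end", "max_lr", "fdr"],
    )


def call_eqtls_per_class(
    scan_results: list[ScanResult],
    null_distribution: NullDistribution,
    dosage_table: FounderDosageTable,
    target_fdr: float = DEFAULT_TARGET_FDR,
) -> pd.DataFrame:
    """Variant of :func:`call_eqtls` thresholding each trait class separately.

    Total-expression and isoform-ratio traits get their own FDR curves
    (each over its own trait universe); the union of calls is returned.
    """
    by_id = {r.trait_id: r for r in scan_results}
    frames = []
    kinds = {tid: by_id[tid].kind for tid in null_distribution.trait_ids if tid in by_id}
    for kind in sorted(set(kinds.values())):
        idx = [i for i, tid in enumerate(null_distribution.trait_ids) if kinds.get(tid) == kind]
        sub_null = NullDistribution(
            max_lr=null_distribution.max_lr[:, idx],
            trait_ids=[null_distribution.trait_ids[i] for i in idx],
            n_perm=null_distribution.n_perm,
            seed=null_distribution.seed,
        )
        sub_results = [by_id[t] for t in sub_null.trait_ids]
        real = np.array([r.max_lr if r.scannable else np.nan for r in sub_results])
        table = fdr_curve(real, sub_null)
        frames.append(call_eqtls(sub_results, table, dosage_table, target_fdr))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["trait_id", "gene_id", "eqtl_type", "chrom", "start", "end", "max_lr", "fdr"]
        )
    return pd.concat(frames, ignore_index=True)


def dual_eqtl_genes(calls: pd.DataFrame) -> list[str]:
    """Genes with at least one call of each eQTL type (loci need not match)."""
    if calls.empty:
        return []
    kinds = calls.groupby("gene_id")["eqtl_type"].agg(lambda s: set(s))
    return sorted(g for g, ks in kinds.items() if {"total-expression", "isoform-ratio"} <= ks)
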