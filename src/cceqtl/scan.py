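"""Proximal genome scans: per-interval LR scores and founder effects.

For each trait, every genome interval on the trait's chromosome whose
distance to the transcription start site (TSS) is strictly less than the
proximal window (default 5 Mbp) is tested with the founder-dosage mixed
model; the trait-level statistic is the maximum LR over those intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cceqtl.genome import N_FOUNDERS
from cceqtl.lmm import LmmFit, _fit_profiled, line_statistics, scan_statistics
from cceqtl.simulate import FounderDosageTable
from cceqtl.transform import TraitSet

PROXIMAL_WINDOW_BP = 5_000_000


@dataclass
class ScanResult:
    """Per-trait scan: LR per proximal interval and the argmax summary."""

    trait_id: str
    gene_id: str
    kind: str
    interval_ids: np.ndarray  # global interval ids scanned
    lr: np.ndarray
    max_lr: float
    argmax_interval: int  # global interval id (ties: smallest coordinate)
    alpha_hat: np.ndarray  # (8,) sum-to-zero estimate at the argmax
    founder_effect: np.ndarray  # alpha_hat / max|alpha_hat|
    degenerate_effects: bool
    scannable: bool = True


def proximal_intervals(trait_tss: tuple[str, int], dosage_table: FounderDosageTable,
                       window: int = PROXIMAL_WINDOW_BP) -> np.ndarray:
    """Interval ids on the TSS chromosome strictly closer than ``window``.

    Distance is 0 when the TSS falls inside the interval, otherwise the
    distance to the nearest interval boundary.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    chrom, pos = trait_tss
    iv = dosage_table.intervals
    on_chrom = iv["chrom"].to_numpy() == chrom
    if not on_chrom.any():
        warnings.warn(f"TSS chromosome {chrom!r} absent from the dosage table")
        return np.array([], dtype=int)
    start = iv["start"].to_numpy()
    end = iv["end"].to_numpy()
    dist = np.maximum.reduce([start - pos, pos - end, np.zeros(len(iv), dtype=np.int64)])
    return np.flatnonzero(on_chrom & (dist < window))


def founder_effects(alpha_hat) -> tuple[np.ndarray, bool]:
    """Normalize founder effects by the maximum absolute effect.

    Returns ``(alpha / max|alpha|, degenerate)``; an all-zero input is
    returned unchanged with the degenerate flag set (no division).
    """
    alpha = np.asarray(alpha_hat, dtype=float)
    if alpha.shape != (N_FOUNDERS,):
        raise ValueError(f"founder effects require an 8-vector, got shape {alpha.shape}")
    peak = np.abs(alpha).max()
    if peak == 0.0:
        return np.zeros(N_FOUNDERS), True
    return alpha / peak, False


def _line_design(dosage_table: FounderDosageTable, line_ids) -> np.ndarray:
    """Dosage array rows for ``line_ids`` in the given order: (L, I, 8)."""
    pos = dosage_table.line_index()
    missing = [l for l in line_ids if l not in pos]
    if missing:
        raise ValueError(f"lines absent from the dosage table: {missing}")
    idx = np.fromiter((pos[l] for l in line_ids), dtype=int, count=len(line_ids))
    return dosage_table.dosages[idx]


@dataclass
class TraitScanContext:
    """Precomputed, permutation-invariant scan state for one trait.

    The per-line sufficient statistics, the proximal interval set, the
    line-ordered dosage designs and the null-model fit all survive
    line-label shuffling unchanged, so the permutation null reuses them.
    """

    trait_id: str
    gene_id: str
    kind: str
    stats: object
    prox: np.ndarray
    lines_dosage: np.ndarray | None  # (L, n_prox, 8)
    null_fit: LmmFit | None

    @property
    def scannable(self) -> bool:
        return self.prox.size > 0


def prepare_scan_context(
    u,
    line_labels,
    dosage_table: FounderDosageTable,
    trait_tss: tuple[str, int],
    window: int = PROXIMAL_WINDOW_BP,
    trait_id: str = "",
    gene_id: str = "",
    kind: str = "total",
) -> TraitScanContext:
    stats = line_statistics(u, line_labels)
    if len(stats.line_ids) < 2:
        raise ValueError("the scan requires at least 2 lines")
    prox = proximal_intervals(trait_tss, dosage_table, window)
    if prox.size == 0:
        return TraitScanContext(trait_id, gene_id, kind, stats, prox, None, None)
    lines_dosage = _line_design(dosage_table, stats.line_ids)[:, prox, :]
    null_fit = _fit_profiled(stats, None)
    return TraitScanContext(trait_id, gene_id, kind, stats, prox, lines_dosage, null_fit)


def scan_from_context(
    ctx: TraitScanContext,
    line_perm: np.ndarray | None = None,
    compute_alpha: bool = True,
) -> ScanResult:
    """Scan a prepared trait, optionally under a line-label permutation.

    ``line_perm`` assigns to each (sorted) line the genotype of another
    line — the label-shuffling device of the permutation null.
    """
    if not ctx.scannable:
        return ScanResult(
            trait_id=ctx.trait_id, gene_id=ctx.gene_id, kind=ctx.kind,
            interval_ids=ctx.prox, lr=np.array([]), max_lr=np.nan, argmax_interval=-1,
            alpha_hat=np.zeros(N_FOUNDERS), founder_effect=np.zeros(N_FOUNDERS),
            degenerate_effects=True, scannable=False,
        )
    dos = ctx.lines_dosage if line_perm is None else ctx.lines_dosage[line_perm]
    designs = [dos[:, i, :] for i in range(ctx.prox.size)]
    lrs, fits = scan_statistics(ctx.stats, designs, null_fit=ctx.null_fit, compute_alpha=False)
    best = int(np.argmax(lrs))  # np.argmax takes the first max: smallest coordinate
    if compute_alpha:
        alpha = _fit_profiled(ctx.stats, designs[best]).alpha_hat
    else:
        alpha = np.zeros(N_FOUNDERS)
    eff, degen = founder_effects(alpha)
    return ScanResult(
        trait_id=ctx.trait_id, gene_id=ctx.gene_id, kind=ctx.kind,
        interval_ids=ctx.prox, lr=lrs, max_lr=float(lrs[best]),
        argmax_interval=int(ctx.prox[best]), alpha_hat=alpha,
        founder_effect=eff, degenerate_effects=degen,
    )


def scan_trait(
    u,
    line_labels,
    dosage_table: FounderDosageTable,
    trait_tss: tuple[str, int],
    window: int = PROXIMAL_WINDOW_BP,
    trait_id: str = "",
    gene_id: str = "",
    kind: str = "total",
    line_perm: np.ndarray | None = None,
) -> ScanResult:
    """Scan one trait over its proximal intervals."""
    ctx = prepare_scan_context(
        u, line_labels, dosage_table, trait_tss, window,
        trait_id=trait_id, gene_id=gene_id, kind=kind,
    )
    return scan_from_context(ctx, line_perm=line_perm)


def prepare_traitset_contexts(
    trait_set: TraitSet,
    dosage_table: FounderDosageTable,
    window: int = PROXIMAL_WINDOW_BP,
) -> list[TraitScanContext]:
    labels = trait_set.samples["line_id"].to_numpy()
    return [
        prepare_scan_context(
            t.u, labels, dosage_table, t.tss, window,
            trait_id=t.trait_id, gene_id=t.gene_id, kind=t.kind,
        )
        for t in trait_set.traits
    ]


def scan_traitset(
    trait_set: TraitSet,
    dosage_table: FounderDosageTable,
    window: int = PROXIMAL_WINDOW_BP,
    line_perm: np.ndarray | None = None,
    contexts: list[TraitScanContext] | None = None,
) -> list[ScanResult]:
    """Scan every retained trait of a :class:`~cceqtl.transform.TraitSet`."""
    if contexts is None:
        contexts = prepare_traitset_contexts(trait_set, dosage_table, window)
    return [scan_from_context(c, line_perm=line_perm) for c in contexts]


def scan_table(results: list[ScanResult], dosage_table: FounderDosageTable) -> pd.DataFrame:
    """Tidy per-interval scan table (one row per trait x scanned interval)."""
    iv = dosage_table.intervals
    rows = []
    for r in results:
        for j, lr in zip(r.interval_ids, r.lr):
            rec = {
                "trait_id": r.trait_id, "gene_id": r.gene_id, "kind": r.kind,
                "chrom": iv.iloc[j]["chrom"], "start": int(iv.iloc[j]["start"]),
                "end": int(iv.iloc[j]["end"]), "lr": lr,
                "is_argmax": bool(j == r.argmax_interval),
            }
            if j == r.argmax_interval:
                for k in range(N_FOUNDERS):
                    rec[f"alpha_{k + 1}"] = r.alpha_hat[k]
                    rec[f"founder_effect_{k + 1}"] = r.founder_effect[k]
            else:
                for k in range(N_FOUNDERS):
                    rec[f"alpha_{k + 1}"] = np.nan
                    rec[f"founder_effect_{k + 1}"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)
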