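"""End-to-end synthetic eQTL studies.

Bundles the full analysis — simulate a CC-like population, transform and
filter traits, scan proximal intervals, build the permutation null, call
eQTLs — behind one configuration object, so that analysis scripts, tests
and the acceptance checks all run the identical code path.

The default configuration mirrors the real hepatic study design at desk
scale: 29 inbred lines with 1-3 replicates each (expected ~55 samples),
an interval grid tiling two 100-Mb chromosomes at 2 Mb, a 5-Mb proximal
window, 100 line-label permutations and a target FDR of 0.01.  Causal
traits carry a founder allelic series at an interval near their TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cceqtl.genome import N_FOUNDERS, GenomeSpec
from cceqtl.rng import substream
from cceqtl.scan import (
    PROXIMAL_WINDOW_BP,
    prepare_traitset_contexts,
    scan_table,
    scan_traitset,
)
from cceqtl.significance import (
    DEFAULT_N_PERM,
    DEFAULT_TARGET_FDR,
    call_eqtls,
    call_eqtls_per_class,
    dual_eqtl_genes,
    fdr_curve,
    null_scan,
)
from cceqtl.simulate import (
    IsoformGeneSpec,
    TraitSpec,
    dosage_from_mosaic,
    ground_truth_table,
    simulate_cc_population,
    simulate_isoform_ratios,
    simulate_total_expression,
    write_fixture,
)
from cceqtl.transform import select_traits


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a synthetic eQTL study."""

    n_lines: int = 29
    rep_probs: tuple[float, float, float] = (0.3, 0.5, 0.2)  # counts 1,2,3 per line
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 100_000_000), ("chr2", 100_000_000))
    interval_size: int = 2_000_000
    recomb_rate_per_mb: float = 0.05
    dosage_uncertainty: float = 0.0
    n_total_traits: int = 300
    n_causal_total: int = 60
    n_isoform_genes: int = 80
    n_causal_isoform: int = 20
    n_unexpressed: int = 10  # low-abundance traits exercising the v_M filter
    effect_size: float = 2.0
    n_carrier_founders: int = 4
    sigma_line: float = 0.3
    sigma_eps: float = 0.3
    baseline_mean: float = 3.0
    baseline_sd: float = 0.8
    n_perm: int = DEFAULT_N_PERM
    target_fdr: float = DEFAULT_TARGET_FDR
    window: int = PROXIMAL_WINDOW_BP
    per_class_fdr: bool = False

    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.chromosomes, self.interval_size)


def _allelic_series(rng, effect_size: float, n_carriers: int) -> np.ndarray:
    """Centered founder allelic series: ``n_carriers`` founders share the effect."""
    alpha = np.zeros(N_FOUNDERS)
    carriers = rng.choice(N_FOUNDERS, size=n_carriers, replace=False)
    alpha[carriers] = effect_size
    return alpha - alpha.mean()


def build_trait_specs(config: StudyConfig, seed: int) -> tuple[list[TraitSpec], list[IsoformGeneSpec]]:
    """Draw the generative trait specifications for a study.

    The first ``n_causal_total`` total traits (and ``n_causal_isoform``
    isoform genes) carry a cis allelic series at an interval containing
    their TSS; the remainder are genotype-independent.  ``n_unexpressed``
    extra traits sit far below the expression filter.
    """
    genome = config.genome()
    intervals = genome.intervals()
    rng = substream(seed, "specs")
    total_specs: list[TraitSpec] = []
    n_all = config.n_total_traits + config.n_unexpressed
    for t in range(n_all):
        causal = t < config.n_causal_total and t < config.n_total_traits
        j = int(rng.integers(len(intervals)))
        row = intervals.iloc[j]
        tss = (row["chrom"], int((row["start"] + row["end"]) // 2))
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        if t >= config.n_total_traits:  # unexpressed: far below the v_M >= 2 floor
            baseline = -4.0 + rng.normal(0.0, 0.3)
        total_specs.append(
            TraitSpec(
                trait_id=f"T{t + 1:04d}",
                gene_id=f"G{t + 1:04d}",
                kind="total",
                tss=tss,
                causal_interval=j if causal else None,
                alpha=_allelic_series(rng, config.effect_size, config.n_carrier_founders)
                if causal
                else np.zeros(N_FOUNDERS),
                sigma_line=config.sigma_line,
                sigma_eps=config.sigma_eps,
                baseline=baseline,
            )
        )
    # isoform-ratio traits belong to genes that also have a total trait
    # (dual annotation), so genes can carry both eQTL types; the isoform
    # cis effect sits at an interval near the shared TSS but is drawn
    # independently of the total trait's effect
    gene_specs: list[IsoformGeneSpec] = []
    n_iso_genes = min(config.n_isoform_genes, config.n_total_traits)
    for t in range(n_iso_genes):
        parent = total_specs[t]
        causal = t < config.n_causal_isoform
        tss_interval = intervals.index[
            (intervals["chrom"] == parent.tss[0])
            & (intervals["start"] <= parent.tss[1])
            & (parent.tss[1] < intervals["end"])
        ][0]
        n_iso = int(rng.integers(2, 5))
        gene_specs.append(
            IsoformGeneSpec(
                gene_id=parent.gene_id,
                tss=parent.tss,
                isoform_baselines=rng.normal(0.0, 0.7, size=n_iso),
                causal_interval=int(tss_interval) if causal else None,
                alpha=_allelic_series(rng, config.effect_size, config.n_carrier_founders)
                if causal
                else np.zeros(N_FOUNDERS),
                sigma_line=config.sigma_line,
                sigma_eps=config.sigma_eps,
                target_isoform=0,
            )
        )
    return total_specs, gene_specs


def annotation_table(total_specs, gene_specs) -> pd.DataFrame:
    rows = {
        s.gene_id: dict(gene_id=s.gene_id, chrom=s.tss[0], tss=s.tss[1], strand="+")
        for s in list(total_specs) + list(gene_specs)
    }
    return pd.DataFrame(list(rows.values()), columns=["gene_id", "chrom", "tss", "strand"])


@dataclass
class StudyResult:
    """Everything a completed synthetic study produced."""

    config: StudyConfig
    seed: int
    dosage: object
    total: object
    isoform: object
    annotation: pd.DataFrame
    ground_truth: pd.DataFrame
    trait_set: object
    scans: list
    null: object
    fdr_table: object
    calls: pd.DataFrame
    dual_genes: list


def run_study(config: StudyConfig, seed: int, out_dir=None) -> StudyResult:
    """Run a complete synthetic study; optionally write all tables under ``out_dir``."""
    genome = config.genome()
    mosaics = simulate_cc_population(config.n_lines, genome, config.recomb_rate_per_mb, seed)
    dosage = dosage_from_mosaic(mosaics, config.dosage_uncertainty)
    total_specs, gene_specs = build_trait_specs(config, seed)
    total = simulate_total_expression(dosage, total_specs, config.rep_probs, seed)
    isoform = (
        simulate_isoform_ratios(dosage, gene_specs, config.rep_probs, seed)
        if gene_specs
        else None
    )
    annotation = annotation_table(total_specs, gene_specs)
    truth = ground_truth_table(genome, total_specs, gene_specs)

    trait_set = select_traits(total, isoform, annotation)
    contexts = prepare_traitset_contexts(trait_set, dosage, window=config.window)
    scans = scan_traitset(trait_set, dosage, window=config.window, contexts=contexts)
    null = null_scan(
        trait_set, dosage, n_perm=config.n_perm, seed=seed, window=config.window,
        contexts=contexts,
    )
    real = np.array([r.max_lr if r.scannable else np.nan for r in scans])
    table = fdr_curve(real, null)
    if config.per_class_fdr:
        calls = call_eqtls_per_class(scans, null, dosage, config.target_fdr)
    else:
        calls = call_eqtls(scans, table, dosage, config.target_fdr)
    dual = dual_eqtl_genes(calls)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traits = [total] + ([isoform] if isoform is not None else [])
        write_fixture(dosage, traits, annotation, out_dir, ground_truth=truth)
        trait_set.report.to_csv(out_dir / "trait_selection.tsv", sep="\t", index=False)
        trait_set.to_frame().to_csv(out_dir / "traits_transformed.tsv", sep="\t")
        scan_table(scans, dosage).to_csv(out_dir / "scan.tsv", sep="\t", index=False)
        null.to_frame().to_csv(out_dir / "null_max_lr.tsv", sep="\t", index=False)
        table.to_frame().to_csv(out_dir / "fdr_curve.tsv", sep="\t", index=False)
        calls.to_csv(out_dir / "eqtl_calls.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": dual}).to_csv(out_dir / "dual_eqtl_genes.tsv", sep="\t", index=False)

    return StudyResult(
        config=config, seed=seed, dosage=dosage, total=total, isoform=isoform,
        annotation=annotation, ground_truth=truth, trait_set=trait_set, scans=scans,
        null=null, fdr_table=table, calls=calls, dual_genes=dual,
    )


def recovery_metrics(result: StudyResult, cosine_threshold: float = 0.9) -> dict[str, float]:
    """Detection, localization and founder-effect accuracy against the truth.

    Detection: fraction of causal traits called.  Localization: fraction
    of detected causal traits whose argmax interval lies within 5 Mb of
    the true causal interval.  Effect accuracy: fraction of detected
    causal traits whose centered founder effects, estimated at the true
    causal interval, have cosine similarity >= ``cosine_threshold`` with
    the true centered allelic series (the argmax interval answers the
    localization question; the true interval is where the generative
    effects are defined).
    """
    from cceqtl.lmm import fit_lmm_genetic

    truth = result.ground_truth
    causal = truth[truth["causal_start"] >= 0]
    scans_by_id = {r.trait_id: r for r in result.scans}
    traits_by_id = {t.trait_id: t for t in result.trait_set.traits}
    called = set(result.calls["trait_id"]) if len(result.calls) else set()
    labels = result.trait_set.samples["line_id"].to_numpy()
    line_ids = sorted(set(labels))
    pos = result.dosage.line_index()
    line_rows = np.fromiter((pos[l] for l in line_ids), dtype=int, count=len(line_ids))
    iv = result.dosage.intervals
    interval_of = {(c, s): j for j, (c, s) in enumerate(zip(iv["chrom"], iv["start"]))}
    n_causal = n_detected = n_local = n_cos = 0
    for rec in causal.to_dict("records"):
        r = scans_by_id.get(rec["trait_id"])
        n_causal += 1
        if r is None or rec["trait_id"] not in called:
            continue
        n_detected += 1
        loc = iv.iloc[r.argmax_interval]
        same_chrom = loc["chrom"] == rec["causal_chrom"]
        gap = max(loc["start"] - rec["causal_end"], rec["causal_start"] - loc["end"], 0)
        if same_chrom and gap <= 5_000_000:
            n_local += 1
        j = interval_of[(rec["causal_chrom"], rec["causal_start"])]
        X = result.dosage.dosages[line_rows, j, :]
        fit = fit_lmm_genetic(traits_by_id[rec["trait_id"]].u, labels, X)
        true_alpha = np.array([rec[f"alpha_{k + 1}"] for k in range(N_FOUNDERS)])
        # a founder with no dosage mass among the lines is inestimable at
        # this interval; the comparison is defined over represented founders
        present = X.sum(axis=0) > 1e-8
        ta = true_alpha[present]
        ea = fit.alpha_hat[present]
        ta = ta - ta.mean()
        ea = ea - ea.mean()
        denom = np.linalg.norm(ta) * np.linalg.norm(ea)
        if denom > 0 and float(ta @ ea) / denom >= cosine_threshold:
            n_cos += 1
    return dict(
        n_causal=n_causal,
        n_detected=n_detected,
        detection_rate=n_detected / n_causal if n_causal else np.nan,
        localization_rate=n_local / n_detected if n_detected else np.nan,
        effect_cosine_rate=n_cos / n_detected if n_detected else np.nan,
        n_false_calls=len(called - set(causal["trait_id"])),
    )
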