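"""Synthetic Collaborative-Cross-like populations with known ground truth.

Generates the three inputs the association pipeline consumes — founder
haplotype dosages, total-expression traits (FPKM scale) and isoform-ratio
traits (percent scale) — from an explicit generative model, so that every
downstream stage can be validated against a known truth table.

Model
-----
Each inbred line carries a single homozygous mosaic of the 8 founder
haplotypes, generated as a first-order Markov chain along each chromosome:
the founder at the first interval is uniform on {1..8}; at each subsequent
interval the chain switches to a uniformly chosen *other* founder with
probability ``1 - exp(-rate * interval_size_Mb)``.

A trait's latent value for sample ``i`` of line ``m`` is

    y_i = mu + sum_k alpha_k g_{k,m} + beta_m + eps_i,

with line effect ``beta_m ~ N(0, sigma_line^2)`` and residual
``eps_i ~ N(0, sigma_eps^2)``.  Total-expression traits are mapped to a
nonnegative FPKM-like scale through ``exp``; because the downstream
transformation is rank-based, any strictly monotone map is equivalent.
Isoform-ratio traits pass per-isoform latent scores through a sum-to-100
softmax per gene and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cceqtl.genome import N_FOUNDERS, ConfigurationError, GenomeSpec
from cceqtl.rng import substream


# ---------------------------------------------------------------------------
# containers


@dataclass
class FounderMosaicSet:
    """Homozygous founder mosaics for a set of inbred lines.

    ``founder[l, j]`` is the founder index (0-based, 0..7) of line ``l``
    at genome interval ``j`` of ``genome.intervals()``.
    """

    genome: GenomeSpec
    line_ids: list[str]
    founder: np.ndarray  # (n_lines, n_intervals) int8

    def __post_init__(self):
        self.founder = np.asarray(self.founder, dtype=np.int8)
        if self.founder.shape != (len(self.line_ids), self.genome.n_intervals):
            raise ValueError("founder matrix shape does not match lines x intervals")
        if self.founder.min() < 0 or self.founder.max() >= N_FOUNDERS:
            raise ValueError("founder indices must lie in 0..7")


@dataclass
class FounderDosageTable:
    """Founder haplotype probabilities g_{k,m} per interval and line.

    ``dosages[l, j, k]`` is the probability that line ``l`` carries founder
    ``k``'s haplotype at interval ``j``.  Rows sum to 1.
    """

    intervals: pd.DataFrame  # chrom, start, end; index = interval_id
    line_ids: list[str]
    dosages: np.ndarray  # (n_lines, n_intervals, 8) float

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.intervals), N_FOUNDERS):
            raise ValueError("dosage array shape does not match lines x intervals x 8")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line_index(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.line_ids)}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: chrom, start, end, line_id, f1..f8."""
        n_l, n_i, _ = self.dosages.shape
        iv = self.intervals.reset_index(drop=True)
        rec = {
            "chrom": np.tile(iv["chrom"].to_numpy(), n_l),
            "start": np.tile(iv["start"].to_numpy(), n_l),
            "end": np.tile(iv["end"].to_numpy(), n_l),
            "line_id": np.repeat(np.asarray(self.line_ids, dtype=object), n_i),
        }
        flat = self.dosages.reshape(n_l * n_i, N_FOUNDERS)
        for k in range(N_FOUNDERS):
            rec[f"f{k + 1}"] = flat[:, k]
        return pd.DataFrame(rec)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FounderDosageTable":
        cols = [f"f{k + 1}" for k in range(N_FOUNDERS)]
        iv = (
            frame[["chrom", "start", "end"]]
            .drop_duplicates()
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        iv.index.name = "interval_id"
        line_ids = list(dict.fromkeys(frame["line_id"]))
        key = {(c, s): j for j, (c, s) in enumerate(zip(iv["chrom"], iv["start"]))}
        dos = np.zeros((len(line_ids), len(iv), N_FOUNDERS))
        lidx = {l: i for i, l in enumerate(line_ids)}
        rows_j = np.fromiter(
            (key[(c, s)] for c, s in zip(frame["chrom"], frame["start"])), dtype=int, count=len(frame)
        )
        rows_l = np.fromiter((lidx[l] for l in frame["line_id"]), dtype=int, count=len(frame))
        dos[rows_l, rows_j] = frame[cols].to_numpy(dtype=float)
        return cls(intervals=iv, line_ids=line_ids, dosages=dos)


@dataclass
class TraitSpec:
    """Generative specification of a single total-expression trait."""

    trait_id: str
    gene_id: str
    kind: str  # "total" | "isoform_ratio"
    tss: tuple[str, int]
    causal_interval: int | None
    alpha: np.ndarray  # (8,) latent-scale founder effects
    sigma_line: float
    sigma_eps: float
    baseline: float = 0.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (N_FOUNDERS,):
            raise ValueError(f"alpha must be an 8-vector, got shape {self.alpha.shape}")
        if self.sigma_line < 0 or self.sigma_eps < 0:
            raise ValueError("variance components must be nonnegative")
        has_effect = bool(np.any(self.alpha != 0))
        if has_effect and self.causal_interval is None:
            raise ValueError(f"trait {self.trait_id}: nonzero alpha requires a causal interval")
        if not has_effect and self.causal_interval is not None:
            raise ValueError(f"trait {self.trait_id}: causal interval requires nonzero alpha")


@dataclass
class IsoformGeneSpec:
    """Generative specification of one gene's isoform-ratio traits.

    The cis effect (``alpha`` at ``causal_interval``) shifts the latent
    score of isoform ``target_isoform``; all isoform percentages then
    renormalize to 100 through the softmax.
    """

    gene_id: str
    tss: tuple[str, int]
    isoform_baselines: np.ndarray  # (n_isoforms,)
    causal_interval: int | None
    alpha: np.ndarray  # (8,)
    sigma_line: float
    sigma_eps: float
    target_isoform: int = 0

    def __post_init__(self):
        self.isoform_baselines = np.asarray(self.isoform_baselines, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.isoform_baselines.size < 2:
            raise ValueError(f"gene {self.gene_id}: isoform-ratio traits need >= 2 isoforms")
        if self.alpha.shape != (N_FOUNDERS,):
            raise ValueError("alpha must be an 8-vector")
        if not (0 <= self.target_isoform < self.isoform_baselines.size):
            raise ValueError("target_isoform out of range")
        has_effect = bool(np.any(self.alpha != 0))
        if has_effect and self.causal_interval is None:
            raise ValueError(f"gene {self.gene_id}: nonzero alpha requires a causal interval")
        if not has_effect and self.causal_interval is not None:
            raise ValueError(f"gene {self.gene_id}: causal interval requires nonzero alpha")

    @property
    def n_isoforms(self) -> int:
        return self.isoform_baselines.size


@dataclass
class ExpressionMatrix:
    """Trait-by-sample expression values plus trait and sample metadata.

    ``values`` has one row per trait (index = trait_id) and one column per
    sample; ``meta`` carries trait_id, gene_id, isoform_id, kind, tss;
    ``samples`` maps sample_id -> line_id.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    samples: pd.DataFrame


# ---------------------------------------------------------------------------
# population


def simulate_cc_population(
    n_lines: int,
    genome_spec: GenomeSpec,
    recomb_rate_per_mb: float,
    seed: int,
) -> FounderMosaicSet:
    """Simulate homozygous founder mosaics for ``n_lines`` inbred lines.

    Each chromosome is an independent first-order Markov chain over the
    interval grid with per-interval switch probability
    ``1 - exp(-recomb_rate_per_mb * interval_size_Mb)``; on a switch the
    new founder is uniform over the other seven.
    """
    if n_lines < 1:
        raise ConfigurationError(f"n_lines must be >= 1, got {n_lines}")
    if recomb_rate_per_mb < 0:
        raise ConfigurationError("recomb_rate_per_mb must be nonnegative")
    p_switch = 1.0 - np.exp(-recomb_rate_per_mb * genome_spec.interval_size / 1e6)
    intervals = genome_spec.intervals()
    n_int = len(intervals)
    founder = np.empty((n_lines, n_int), dtype=np.int8)
    chrom_codes = intervals["chrom"].to_numpy()
    for l in range(n_lines):
        rng = substream(seed, "mosaic", l)
        pos = 0
        for name, _ in genome_spec.chromosomes:
            span = np.flatnonzero(chrom_codes == name)
            m = span.size
            states = np.empty(m, dtype=np.int8)
            states[0] = rng.integers(N_FOUNDERS)
            if m > 1:
                switches = rng.random(m - 1) < p_switch
                # uniform over the 7 other founders, via an offset in 1..7
                offsets = rng.integers(1, N_FOUNDERS, size=m - 1)
                for j in range(1, m):
                    if switches[j - 1]:
                        states[j] = (states[j - 1] + offsets[j - 1]) % N_FOUNDERS
                    else:
                        states[j] = states[j - 1]
            founder[l, span] = states
            pos += m
    line_ids = [f"CC{l + 1:03d}" for l in range(n_lines)]
    return FounderMosaicSet(genome=genome_spec, line_ids=line_ids, founder=founder)


def dosage_from_mosaic(mosaics: FounderMosaicSet, uncertainty: float = 0.0) -> FounderDosageTable:
    """Convert true mosaics to founder-probability dosages.

    The true founder receives probability ``1 - uncertainty``; the
    remaining mass is spread uniformly over the other seven founders,
    emulating soft haplotype-reconstruction output.
    """
    if not (0.0 <= uncertainty < 1.0):
        raise ValueError(f"uncertainty must be in [0, 1), got {uncertainty}")
    n_l, n_i = mosaics.founder.shape
    dos = np.full((n_l, n_i, N_FOUNDERS), uncertainty / (N_FOUNDERS - 1))
    idx_l, idx_i = np.meshgrid(np.arange(n_l), np.arange(n_i), indexing="ij")
    dos[idx_l, idx_i, mosaics.founder] = 1.0 - uncertainty
    return FounderDosageTable(
        intervals=mosaics.genome.intervals(), line_ids=list(mosaics.line_ids), dosages=dos
    )


# ---------------------------------------------------------------------------
# replicate structure


def assign_replicates(line_ids: Sequence[str], reps_per_line, seed: int) -> pd.DataFrame:
    """Build the sample sheet (sample_id, line_id).

    ``reps_per_line`` may be an int (same count for all lines), a mapping
    line_id -> count, or a length-3 probability vector over counts
    {1, 2, 3} from which per-line counts are drawn.
    """
    rng = substream(seed, "replicates")
    if isinstance(reps_per_line, int):
        counts = {l: reps_per_line for l in line_ids}
    elif isinstance(reps_per_line, Mapping):
        counts = {l: int(reps_per_line[l]) for l in line_ids}
    else:
        probs = np.asarray(reps_per_line, dtype=float)
        if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("replicate distribution must be 3 probabilities summing to 1")
        draws = rng.choice([1, 2, 3], size=len(line_ids), p=probs)
        counts = dict(zip(line_ids, (int(d) for d in draws)))
    bad = [l for l, c in counts.items() if c not in (1, 2, 3)]
    if bad:
        raise ValueError(f"replicate counts must be in {{1,2,3}}; offending lines: {bad}")
    rows = []
    for l in line_ids:
        for r in range(counts[l]):
            rows.append((f"{l}_r{r + 1}", l))
    return pd.DataFrame(rows, columns=["sample_id", "line_id"])


def _as_dosage(dosages_or_mosaics) -> FounderDosageTable:
    if isinstance(dosages_or_mosaics, FounderMosaicSet):
        return dosage_from_mosaic(dosages_or_mosaics, uncertainty=0.0)
    return dosages_or_mosaics


# ---------------------------------------------------------------------------
# expression traits


def _latent_trait(
    dosage: FounderDosageTable,
    samples: pd.DataFrame,
    causal_interval: int | None,
    alpha: np.ndarray,
    sigma_line: float,
    sigma_eps: float,
    baseline: float,
    rng_line: np.random.Generator,
    rng_eps: np.random.Generator,
) -> np.ndarray:
    """Latent values mu + sum_k alpha_k g_{k,m} + beta_m + eps_i per sample."""
    line_pos = dosage.line_index()
    sample_line = np.fromiter(
        (line_pos[l] for l in samples["line_id"]), dtype=int, count=len(samples)
    )
    genetic = np.zeros(dosage.n_lines)
    if causal_interval is not None:
        if not (0 <= causal_interval < len(dosage.intervals)):
            raise ValueError(f"causal interval {causal_interval} not on the dosage grid")
        genetic = dosage.dosages[:, causal_interval, :] @ alpha
    beta = rng_line.normal(0.0, sigma_line, size=dosage.n_lines)
    eps = rng_eps.normal(0.0, sigma_eps, size=len(samples))
    return baseline + genetic[sample_line] + beta[sample_line] + eps


def simulate_total_expression(
    dosages_or_mosaics,
    trait_specs: Sequence[TraitSpec],
    reps_per_line,
    seed: int,
    fpkm_scale: float = 1.0,
) -> ExpressionMatrix:
    """Simulate FPKM-scale total-expression traits.

    Latent Gaussian values from the mixed model are mapped to the
    observation scale through ``fpkm_scale * exp(latent)``; the map is
    strictly monotone, so the rank-based transformation downstream sees
    the latent order unchanged, and all outputs are nonnegative.
    """
    dosage = _as_dosage(dosages_or_mosaics)
    samples = assign_replicates(dosage.line_ids, reps_per_line, seed)
    values = np.empty((len(trait_specs), len(samples)))
    for t, spec in enumerate(trait_specs):
        latent = _latent_trait(
            dosage,
            samples,
            spec.causal_interval,
            spec.alpha,
            spec.sigma_line,
            spec.sigma_eps,
            spec.baseline,
            substream(seed, "total", spec.trait_id, "line"),
            substream(seed, "total", spec.trait_id, "eps"),
        )
        values[t] = fpkm_scale * np.exp(latent)
    meta = pd.DataFrame(
        {
            "trait_id": [s.trait_id for s in trait_specs],
            "gene_id": [s.gene_id for s in trait_specs],
            "isoform_id": [""] * len(trait_specs),
            "kind": ["total"] * len(trait_specs),
            "tss_chrom": [s.tss[0] for s in trait_specs],
            "tss_pos": [s.tss[1] for s in trait_specs],
        }
    )
    vals = pd.DataFrame(values, index=meta["trait_id"], columns=samples["sample_id"])
    return ExpressionMatrix(values=vals, meta=meta, samples=samples)


def simulate_isoform_ratios(
    dosages_or_mosaics,
    gene_specs: Sequence[IsoformGeneSpec],
    reps_per_line,
    seed: int,
) -> ExpressionMatrix:
    """Simulate IsoPct-scale isoform-ratio traits (percent, sum 100 per gene).

    Per gene and sample, isoform latent scores are the isoform baselines
    plus — for the target isoform only — the cis founder effect, the line
    effect and residual noise; percentages are ``100 * softmax(scores)``.
    """
    dosage = _as_dosage(dosages_or_mosaics)
    samples = assign_replicates(dosage.line_ids, reps_per_line, seed)
    blocks, meta_rows = [], []
    for spec in gene_specs:
        shift = _latent_trait(
            dosage,
            samples,
            spec.causal_interval,
            spec.alpha,
            spec.sigma_line,
            spec.sigma_eps,
            0.0,
            substream(seed, "isoform", spec.gene_id, "line"),
            substream(seed, "isoform", spec.gene_id, "eps"),
        )
        scores = np.tile(spec.isoform_baselines[:, None], (1, len(samples)))
        scores[spec.target_isoform] += shift
        scores -= scores.max(axis=0, keepdims=True)
        exps = np.exp(scores)
        pct = 100.0 * exps / exps.sum(axis=0, keepdims=True)
        blocks.append(pct)
        for j in range(spec.n_isoforms):
            meta_rows.append(
                {
                    "trait_id": f"{spec.gene_id}.iso{j + 1}",
                    "gene_id": spec.gene_id,
                    "isoform_id": f"{spec.gene_id}.iso{j + 1}",
                    "kind": "isoform_ratio",
                    "tss_chrom": spec.tss[0],
                    "tss_pos": spec.tss[1],
                }
            )
    meta = pd.DataFrame(meta_rows)
    vals = pd.DataFrame(np.vstack(blocks), index=meta["trait_id"], columns=samples["sample_id"])
    return ExpressionMatrix(values=vals, meta=meta, samples=samples)


# ---------------------------------------------------------------------------
# fixture serialization


def ground_truth_table(
    genome: GenomeSpec,
    trait_specs: Sequence[TraitSpec] = (),
    gene_specs: Sequence[IsoformGeneSpec] = (),
) -> pd.DataFrame:
    """Tabulate the simulated truth: causal interval and effects per trait."""
    intervals = genome.intervals()
    rows = []

    def interval_coords(j):
        if j is None:
            return "", -1, -1
        r = intervals.iloc[j]
        return r["chrom"], int(r["start"]), int(r["end"])

    for s in trait_specs:
        c, a, b = interval_coords(s.causal_interval)
        rows.append(
            dict(
                trait_id=s.trait_id,
                gene_id=s.gene_id,
                kind="total",
                causal_chrom=c,
                causal_start=a,
                causal_end=b,
                **{f"alpha_{k + 1}": s.alpha[k] for k in range(N_FOUNDERS)},
                sigma_line=s.sigma_line,
                sigma_eps=s.sigma_eps,
            )
        )
    for s in gene_specs:
        c, a, b = interval_coords(s.causal_interval)
        rows.append(
            dict(
                trait_id=f"{s.gene_id}.iso{s.target_isoform + 1}",
                gene_id=s.gene_id,
                kind="isoform_ratio",
                causal_chrom=c,
                causal_start=a,
                causal_end=b,
                **{f"alpha_{k + 1}": s.alpha[k] for k in range(N_FOUNDERS)},
                sigma_line=s.sigma_line,
                sigma_eps=s.sigma_eps,
            )
        )
    return pd.DataFrame(rows)


def write_fixture(
    dosage: FounderDosageTable,
    traits: Sequence[ExpressionMatrix],
    annotation: pd.DataFrame,
    out_dir,
    ground_truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the file set consumed by the downstream pipeline.

    Emits dosages.tsv (long format), one trait matrix TSV per
    ExpressionMatrix (traits_total.tsv / traits_isoform.tsv by kind),
    samples.tsv, annotation.tsv and, when provided, ground_truth.tsv.
    Raises a validation error listing offending ids when tables are
    inconsistent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    problems = []
    known_lines = set(dosage.line_ids)
    known_genes = set(annotation["gene_id"])
    for tm in traits:
        bad_lines = sorted(set(tm.samples["line_id"]) - known_lines)
        if bad_lines:
            problems.append(f"sample sheet lines missing from dosages: {bad_lines}")
        bad_genes = sorted(set(tm.meta["gene_id"]) - known_genes)
        if bad_genes:
            problems.append(f"trait genes missing from annotation: {bad_genes}")
    if problems:
        raise ValueError("inconsistent fixture tables: " + "; ".join(problems))

    paths: dict[str, Path] = {}
    paths["dosages"] = out_dir / "dosages.tsv"
    dosage.to_frame().to_csv(paths["dosages"], sep="\t", index=False)
    for tm in traits:
        kind = tm.meta["kind"].iloc[0]
        name = "traits_total" if kind == "total" else "traits_isoform"
        paths[name] = out_dir / f"{name}.tsv"
        table = pd.concat([tm.meta.reset_index(drop=True), tm.values.reset_index(drop=True)], axis=1)
        table.to_csv(paths[name], sep="\t", index=False)
        paths["samples"] = out_dir / "samples.tsv"
        tm.samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["annotation"] = out_dir / "annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    if ground_truth is not None:
        paths["ground_truth"] = out_dir / "ground_truth.tsv"
        ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def read_trait_matrix(path) -> ExpressionMatrix:
    """Read a trait matrix TSV written by :func:`write_fixture`."""
    table = pd.read_csv(path, sep="\t", dtype={"isoform_id": str}, keep_default_na=False)
    meta_cols = ["trait_id", "gene_id", "isoform_id", "kind", "tss_chrom", "tss_pos"]
    meta = table[meta_cols].copy()
    meta["tss_pos"] = meta["tss_pos"].astype(int)
    vals = table.drop(columns=meta_cols)
    vals = vals.astype(float)
    vals.index = meta["trait_id"]
    sample_path = Path(path).with_name("samples.tsv")
    samples = pd.read_csv(sample_path, sep="\t")
    return ExpressionMatrix(values=vals, meta=meta, samples=samples)
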