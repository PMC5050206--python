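# Methods

This note records the models implemented in `cceqtl`, the choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about real data.

## Trait transformation

Expression traits arrive on two observation scales: FPKM-like
nonnegative abundances (total expression) and percentages summing to
100 within a gene (isoform ratios).  Both are discretized to a bin size
δ = max(0.5, v_M/200) before ranking — the floor models the limited
accuracy of small quantification values, and v_M/200 fixes the relative
resolution at 0.5% of the trait's maximum.  Rounding uses
half-away-from-zero (a deterministic, platform-independent tie rule; a
small relative tolerance makes it idempotent on already-rounded values).
The van der Waerden transform u_i = Φ⁻¹(r*_i/(n+1)) with average-rank
ties then maps each trait to approximate normality; an all-tied trait
maps to all zeros.  The transform is computed once per trait over all
samples (the model indexes individuals, not lines).

Filters: total-expression traits are tested only when expressed
(v_M ≥ 2) and variable (≥ 12 distinct rounded levels).  Each expressed
gene contributes at most one isoform-ratio trait — the isoform with the
most distinct rounded levels, subject to the same ≥ 12 filter.  Open
details resolved here: the per-gene argmax is taken before the ≥ 12
filter; isoforms that are zero in every sample are not candidates;
ties on the distinct-level count go to the higher mean percentage, then
the lexicographically smallest isoform id; genes without a total trait
cannot be assessed for expression and pass through to isoform
candidacy.

## The mixed model and its likelihood

Both models (null: intercept + line random effect; genetic: adds eight
founder-dosage fixed effects) are fitted by full maximum likelihood —
not REML — because the LR compares models with different fixed effects,
for which REML likelihoods are not comparable.  The LR is reported on
the 2·Δlogℓ scale (a likelihood *ratio* is exp(LR/2)); since eQTL calls
depend only on threshold crossings of a trait-wise statistic compared
against its own permutation null, any strictly monotone rescaling of
the LR yields identical calls.

The likelihood is profiled over the variance ratio λ = σ_line²/σ².
With samples grouped by line, the covariance is block diagonal and the
GLS problem collapses onto line means with weights n_m/(1 + λ n_m),
giving σ̂² and the coefficients in closed form per λ.  The 1-D profile
is maximized on a log₁₀ λ grid over [−6, 6] (31 points plus the exact
λ = 0 boundary) with two 17-point zoom refinements; agreement with a
brute-force 2-D variance-grid GLS oracle is ≤ 4×10⁻⁴ in log-likelihood
over 50 random small instances.  Two exact special cases bypass the
grid: all-singleton lines (σ_line and σ are confounded; the profile is
flat and λ is pinned at 0, i.e. a total-variance parameterization), and
balanced designs (equal replicates m per line), where the GLS weights
are equal, the coefficients reduce to the OLS line-mean fit for every
λ, and the profile maximum has the closed form
t* = L·SSW/((n−L)·m·RSS₀) with t = 1/(1+λm), SSW the within-line
scatter and RSS₀ the OLS line-mean residual sum of squares.  A variance
floor of 10⁻⁸·var(u) keeps the log-likelihood finite on degenerate
traits (flagged as boundary fits).

Because the eight founder probabilities sum to one per line, the
intercept is confounded with the founder effects; and on intervals where
some founder has no dosage mass among the lines (common in small
panels) further directions are unidentifiable.  The design is therefore
reduced to full column rank by SVD for fitting (the likelihood is
unaffected), and the reported α̂ is the minimum-norm sum-to-zero vector
reproducing the fitted line means — exactly zero on monomorphic
intervals, and the ordinary recentered coefficients on full-rank
designs.  Normalized founder effects are α̂_k/max|α̂_k| (all-zero input
returns all zeros with a degeneracy flag, no division).

Proximal scan: same-chromosome intervals whose boundary distance to the
TSS is strictly less than 5 Mb (0-based, half-open BED coordinates; a
TSS inside an interval has distance 0).  The trait-level statistic is
the maximum LR over these intervals; argmax ties break to the smallest
genomic coordinate.  Traits with no proximal interval are flagged
unscannable and excluded symmetrically from real and null counts.

## Permutation FDR

The null shuffles CC *line labels*: each replicate draws one uniform
bijection on lines (shared across all traits, preserving inter-trait
correlation) and reassigns genotypes accordingly, so the genetic fixed
effect is randomized while replicate structure and the line random
effect are untouched.  All traits are rescanned per replicate over
their own proximal windows; the per-line sufficient statistics, null
fits and interval designs are permutation-invariant and are reused.

For thresholds t on the grid of sorted real max-LR values,
C_real(t) = #{traits: max LR > t} and C_perm(t) is the mean count over
replicates; FDR(t) = C_perm(t)/C_real(t) clipped to [0,1], with
FDR := 0 where C_real = 0 (no discoveries, nothing falsely
discovered).  A cumulative minimum over increasing thresholds makes the
curve non-increasing so call sets are nested in the target.  Calls are
traits whose max LR exceeds the minimal threshold with FDR below the
target (default 0.01, 100 permutations); each call reports the argmax
interval and the trait kind (total-expression vs isoform-ratio eQTL).
Total and isoform traits are thresholded jointly by default — the two
statistics live on the same LR scale and share the null machinery — and
a per-class mode (`call_eqtls_per_class`) thresholds each trait class
against its own curve.  Genes with at least one call of each type are
the dual-eQTL genes; the loci need not coincide.

## Connectivity map

Step 1 loads curated drug→gene sets (JSON; a gene listed twice keeps
the stronger, direct evidence).  Step 2 adds, per drug, every gene
sharing an EC number with a *curated* member (indirect evidence); the
expansion is single-pass — added genes do not seed further expansion,
because it is the curated sets that define the reactions.  Step 3 keeps
only genes with at least one eQTL call and drops drugs whose sets
empty.  The graph is strictly tripartite; eQTL nodes are deduplicated
by interval, and gene–eQTL edges carry the eQTL type(s).

Distinct loci per drug merge a drug's eQTL intervals per chromosome by
single linkage whenever the boundary gap is < 10 Mb; intervals exactly
10 Mb apart remain distinct ("at least 10 Mb apart" is distinct).
Boundary-gap comparison (rather than midpoints or peak markers) is the
choice here, exposed as `min_separation`.  Over-representation uses the
one-sided hypergeometric tail P(X ≥ overlap), computed by exact pmf
summation.  Representative lines: line-mean expression profiles over a
drug's eQTL-target genes are standardized per gene, clustered by
average-linkage on correlation distance, the tree cut into k clusters,
and each cluster represented by the line nearest its centroid —
identical profiles collapse first, so redundant lines are never
co-selected.

## Synthetic data: what it emulates, what it does not

Mosaic genomes are first-order Markov chains over the interval grid:
uniform founder at the chromosome start, switch probability
1 − exp(−rate·Δ_Mb) per interval, uniform choice among the other seven
founders.  This reproduces the dosage structure the analysis consumes —
dense recombination, spatial founder correlation, occasional local
absence of a founder — but not CC funnel pedigrees, founder-specific
ancestry proportions, or residual heterozygosity.  Haplotype
reconstruction uncertainty is emulated by spreading (1 − p) of the
probability mass uniformly over the seven non-true founders.

Expression follows the mixed model exactly on a latent Gaussian scale;
total expression maps to FPKM through exp(·) (any strictly monotone map
is equivalent downstream, and exp guarantees nonnegativity and a
realistically right-skewed dynamic range that stresses the δ-rounding),
and isoform scores map through a sum-to-100 softmax, which couples
sibling isoforms as real IsoPct values are coupled.  Cis effects are
founder allelic series (a random subset of founders sharing an effect,
centered).  Replicates per line are drawn from a user distribution over
{1, 2, 3}.  One user seed drives keyed substreams per (stage, line,
trait), so adding traits never perturbs genotypes and all outputs are
byte-reproducible.  Not emulated: read-level sampling noise,
library-size effects, mapping bias, trans-regulation, and
quantification error correlated between isoforms of a gene beyond the
softmax coupling.  Passing tests therefore establish the correctness
and calibration of the *pipeline*, not the biology of any real tissue.

## Study conditions used by the checks

The default study mirrors the real design at desk scale: 29 lines,
replicate counts drawn with probabilities (0.3, 0.5, 0.2) over {1,2,3}
(~55–57 samples), two 100-Mb chromosomes at 2-Mb intervals, 0.05
recombinations/Mb, 310 total traits (60 causal) plus 10 unexpressed
ones, 80 dual-annotated isoform genes (20 causal), σ_line = σ_eps =
0.3, log-baseline ~ N(3, 0.8), biallelic 4/4 allelic series of size 2,
100 permutations, FDR < 0.01.  Calibration and power checks use 300
traits on 30 lines × 2 replicates over a 50-interval chromosome; the
causal allelic series explains ~85% of latent trait variance (well
above the ≥ 50% regime these checks address), a level typical of strong
cis-eQTLs in inbred panels and chosen so that per-founder estimation
noise, (σ_line² + σ²/2)·8/L ≈ 0.04, is small against unit effects.
Founder-effect accuracy is scored at the true causal interval and only
over founders with dosage mass among the lines — the effect of a
founder absent from the panel at a locus is inestimable in any method,
and with 30 lines roughly one interval in seven lacks a founder.  The
in-suite calibration test uses 20 permutations to stay fast; the
acceptance script runs the full 100.

## Known limitations

- The line random effect is the only variance component: no kinship /
  polygenic term, so relatedness beyond line identity is unmodeled (as
  in the proximal-scan setting this targets).
- Only proximal (cis-window) scans; no genome-wide trans scans and no
  interval-level confidence regions.
- The permutation null assumes line exchangeability; population
  structure among lines would violate it.
- FDR is a ratio-of-counts estimator; with very few tested traits it is
  coarse, and the smallest observed statistic can never itself be
  called (thresholds are the observed values, counts use strict
  exceedance).
- EC-based expansion is only as good as the EC map; genes without EC
  annotations never expand.
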