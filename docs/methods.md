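# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make the pipeline deterministic.

## Counting model

Reads are assigned to guides by exact string equality on the spacer. No
mismatch tolerance is applied: the spacer is the identity of the guide, the
library is constructed so spacers are unique (duplicates are rejected when
the index is loaded, because a duplicated spacer would make read assignment
ambiguous in a way no counting rule can repair), and sequencing error simply
moves a read into the unmatched pool rather than to a wrong guide. The
default mode scans each read for any library spacer because single-round
amplicon PCR designs commonly stagger the spacer offset within the read;
when the offset is fixed and known, `exact` mode is a faster drop-in. Reads
are searched on the given strand only — amplicon orientation is fixed by the
PCR primers — with reverse-complement search available as a flag. Each read
increments at most one guide (left-most match wins), so per-sample totals
obey matched + unmatched = total.

## Per-sgRNA negative-binomial test

Counts for guide *i* in sample *j* are modelled as NB with mean
`μ_ij = s_j q_i 2^(β_i x_j)` and variance `μ + α_i μ²`, where `x_j`
indicates the contrast condition. This is the standard RNA-seq-style count
GLM applied per guide; the implementation is deliberately minimal and fully
documented rather than delegating to an external fitter.

**Size factors** are median-of-ratios: for guides positive in every sample,
the median over guides of `count_ij / geomean_i`, rescaled to geometric mean
one. The median is taken on the ratio scale (with an even number of guides
this averages the two middle ratios arithmetically; log-scale medians would
average them geometrically — the difference is ~1e-3 relative and a matter
of convention).

**Dispersions** come from a three-step scheme. (1) A method-of-moments
estimate per guide, `(var − ξ·mean)/mean²` on normalized counts pooled
across conditions with ≥2 replicates (weights = degrees of freedom); `ξ`,
the mean reciprocal size factor, is the Poisson-noise term on the normalized
scale and equals 1 when all factors are 1. (2) A mean–dispersion trend
`α(μ) = a₁/μ + a₀` fitted by least squares over guides with positive raw
estimates. (3) Log-scale interpolation of the raw estimate toward the trend.
The interpolation weight is estimated from the data: with `d` pooled
residual degrees of freedom the raw estimate behaves roughly like
`α·χ²_d/d`, whose log has variance `trigamma(d/2)`; the excess of the
observed spread of `log α̂` around the trend over that sampling variance
estimates the true guide-to-guide dispersion variation, and the trend weight
is `noise/(noise + excess)`. At screen-typical replication (2–4 replicates,
d = 2–6) the raw estimates are extremely noisy, so most weight lands on the
trend — which is what keeps the Wald test calibrated; a simulation with the
true dispersion supplied shows the test itself is calibrated at 2+2
replicates, so any miscalibration enters through dispersion noise, and
under-shrinking demonstrably inflates type-I error (~10% at nominal 5% with
a fixed half-weight). When guides genuinely differ in dispersion the excess
term grows and per-guide estimates regain weight. Guides with a zero raw
estimate carry no dispersion signal and take the trend value outright.
Dispersions are floored at 1e-8.

**Wald test.** The two parameters (log baseline, β in log2 units) are fitted
per guide by damped Newton iteration on the exact NB log-likelihood with the
observed Hessian, vectorised across all guides; steps are halved until the
likelihood does not decrease, and convergence is declared when the score
norm falls below 1e-8 relative to the guide's total count (the score scales
with counts, so an absolute cutoff would be unreachable in float64 for deep
samples). The standard error is the inverse observed information; p is the
two-sided normal tail of β/se. Guides with all-zero counts in the contrast
are excluded (NA); guides whose Hessian degenerates (one condition entirely
zero drives β to infinity) or that exhaust 100 iterations are flagged NA
rather than crashing. BH adjustment runs across all tested guides, with NA
excluded from the denominator. There is no independent filtering, no outlier
refitting, and no LFC shrinkage — the aLFC reported downstream is the plain
mean of raw per-guide log2FCs.

One stated idealisation does not survive contact with the MLE: rescaling a
single sample's counts rescales its size factor exactly, but β is only
approximately invariant, because the pooled condition mean `Σk/Σs` reweights
the scaled sample within its condition. β is exactly invariant under
whole-matrix rescaling, and that is the property the tests assert.

## Gene aggregation

Guides are ranked by `r = sign(log2FC)·(−log10 max(padj, 1e-300))`,
descending, ties broken by guide id — one deterministic ranking serving both
directions. Each gene's guide set is scored with the running-sum enrichment
statistic: walking the ranked list, member guides add an increment and
non-members subtract `1/(N−n)`; the ES is the signed maximum deviation, in
[−1, 1], negative when the gene's guides sit at the depleted end. When the
positive and negative extremes tie in magnitude (within 1e-12) the positive
one is returned so the statistic is stable under floating-point reordering.

The default uses uniform increments (`1/n`, the classic unweighted KS form)
rather than |r|-weighted increments. The weighted form is available, but
under a guide-level permutation null it loses essentially all power in a
screen with strong hits: a random guide set that happens to contain one
strongly depleted guide scores an ES near −1 — the single heavy weight
dominates the walk — so a fully depleted 4-guide gene (ES ≈ −0.96) is not
separable from the null and no gene reaches a small permutation p even when
the ranking is perfect. With uniform increments a gene needs *all* its
guides near the bottom to reach an extreme ES, which is precisely the
consistent-across-guides signal a knockout screen looks for.

The null redraws uniform random guide sets of the same size from the ranked
list (gene-label permutation); p uses the add-one estimator, so its floor is
`1/(n_perm+1)` and it is never zero. Because the null depends only on set
size, one seeded null distribution per distinct guide count is shared across
genes — statistically identical to redrawing per gene and what makes 1,000
permutations per gene affordable at genome scale. BH runs across genes
separately per direction; a gene's headline `padj` follows its dominant
(smaller-raw-p) direction, and both direction-specific columns are kept. Hit
calling requires adjusted p ≤ 0.05 (a `use_raw_p` flag relaxes this to the
raw permutation p) *and* an aLFC sign consistent with the requested
direction. Non-targeting controls share a reserved pseudo-gene label; they
stay in the ranked background but get no gene row.

## Network and complex annotation

Gene identity is by upper-cased symbol throughout; no identifier-mapping
service is consulted. Bait–prey rows survive only if both partners are hits;
(A,B)/(B,A) collapse to one undirected edge, self-pairs are dropped, and the
node set is the endpoints of surviving edges — a hit with no within-hit
interaction is not a network node. Catalog entries with fewer than two
distinct subunits (homodimers) are removed before scoring. Completeness is
`100·|subunits ∩ list|/|subunits|` against the hit list (screen) and the
node set (network); exact fractions are kept internally and displayed
rounded half-up to the nearest integer. A protein in several complexes is
assigned the complex with the highest screen completeness — the quantity the
annotation ranks on — with ties broken by larger roster, then lexicographic
id. Exports are sorted node/edge TSVs loadable by standard graph tools.

`known_complexes` carries literature-curated rosters (BORC, CCC/Commander,
Ragulator, retromer) under their catalog symbol aliases, used as fixed
inputs for completeness checks.

## Over-representation analysis

Each gene set is intersected with the universe and tested with a two-sided
Fisher exact test on the 2×2 hit × membership table; two-sided means the sum
of hypergeometric point masses not exceeding the observed one (stated
explicitly because "two-sided Fisher" has variants). The default universe is
the screened gene set, not the genome: genes the library never targeted
cannot become hits, and using them as background would manufacture
enrichment. The test itself is `scipy.stats.fisher_exact`; the test suite
verifies it against direct hypergeometric enumeration to 1e-10.

## Synthetic screens

The generator emulates the screen design at desk scale. Defaults, chosen
once as the study conditions: 1,000 genes × 4 guides; controls scaled from
the genome-wide control rate (142 per 18,053 genes); two fractions
(PhagoNeg, PhagoLate) at 2 replicates; 500 expected reads per guide — a
desk-scale stand-in for a 3000×-coverage screen, deep enough that counts are
informative but small enough that a full analysis runs in seconds;
log-normal guide-abundance spread σ = 0.8 (the right order for a cloned
genome-wide library); NB dispersion α₀ = 0.1 (screen-typical
overdispersion); 5% of genes planted with log2 effect −2 applied to all
their guides in the sorted fraction, with additive per-guide jitter (σ =
0.3) so knockout-efficiency heterogeneity is present but the mean realized
effect equals the planted effect; mild per-sample depth variation (log-normal
σ = 0.15). Effects multiply the sorted-fraction mean only — depletion caused
by loss of function, not by library composition. Controls are never planted.
One RNG stream per call, seeded from the config; outputs are bit-identical
across runs. FASTQ emission embeds each spacer in constant flanks so
end-to-end tests can start from reads.

Deliberately not modelled: sorting impurity, PCR jackpotting, off-target
guide effects, guide-efficiency covariates. Passing recovery tests therefore
show the statistics behave correctly under the stated model, not that real
screens are free of these artefacts.

The network generator plants complexes (rosters sampled from the protein
pool, possibly overlapping), draws within-complex bait–prey edges at a high
probability over a sparse background, and samples hits with elevated weight
for complex members so completeness varies across complexes.

## Problem sizes and determinism

Calibration and recovery analyses run at 1,000 genes × 4 guides with 1,000
permutations per gene; oracle-equivalence checks run on instances of tens to
hundreds of items where brute-force enumeration is exact. Every stochastic
step takes an explicit seed, permutation nulls are shared per set size from
one seeded stream, sorts use stable algorithms with explicit tie-breaks, and
pipeline manifests record SHA-256 checksums so reruns can be verified
byte-identical.

## Known limitations

- Two-condition contrasts only; no continuous covariates or multi-level
  designs.
- The Wald test at 2 replicates per condition leans on the dispersion trend;
  strongly guide-specific dispersion at that replication depth is not
  identifiable and residual type-I error sits slightly above nominal
  (~5.5% at the 5% level in null simulations).
- The deposited screen tables (per-gene statistics, interaction/assignment
  tables) are inputs the package can recompute summary quantities from
  (`phagoscreen.supplement`) but are not bundled; the corresponding checks
  require a local copy.
- Permutation p-values are bounded below by 1/(n_perm+1); ranking below that
  floor relies on the ES and aLFC.
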