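# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that affect results.

## Evidence model and confidence bounds

Each candidate SNV carries ref/alt read counts from up to four sequencing
technologies (Illumina discovery data plus orthogonal BGI, Element and
PacBio HiFi datasets). Counts are treated as binomial draws at the true VAF;
all screening decisions are made on one-sided Wilson score bounds rather
than raw fractions, so low-coverage variants are neither promoted nor
dismissed on noise.

A one-sided confidence coefficient `c` is implemented as the Wilson interval
with `z = Φ⁻¹(c)` — numerically identical to the two-sided interval at
`α = 2(1−c)` — and callers consume only the relevant side. Per-technology
bounds use `c = 0.95`, the pooled bound `c = 0.99`. The Wilson method is the
default; Agresti–Coull is available as an alternative since both belong to
the same score-interval family and the choice is not fully determined by
convention. Both bounds are clipped to [0, 1] (relevant for Agresti–Coull
near the boundaries).

Before any bound is computed, a per-technology minimum of 2 alt reads is
applied: a technology with a single alt read has its alt count zeroed but
keeps its depth, so it still contributes denominator to the pooled bound.
Zeroing (rather than dropping the variant or the dataset) was chosen because
a singleton alt read is indistinguishable from a sequencing error and the
remaining depth is still informative about the absence of the variant; the
alternative (dropping the technology) is reachable by filtering supports
before summarization.

Low-coverage variants are removed by empirical depth thresholds: the 0.5%
quantile (linear interpolation between order statistics, the numpy default;
the definition matters at these tail quantiles and is fixed here) of the
pooled depth and of the HiFi depth, computed over the variants that survive
the confident-reference filter — the population whose coverage distribution
the quantile is meant to describe. Thresholds are recomputed per run.

The pooled ("combined") bound includes the Illumina discovery data by
default alongside the orthogonal technologies; `EvidenceConfig.orthogonal_only()`
excludes it for analyses that require strict independence from the
discovery callset.

## Decision tree

Rules fire in a fixed order (see `mosaicbench.tree`); each classification
carries an ordered reason trail with the compared values, so any category is
reproducible from its trail. Comparisons follow the rule statements
literally: the bound thresholds (≤ 0.03, ≥ 0.05) are inclusive, the
alt-ratio rule (> 0.5) and the depth rule ("below the quantile") are strict.
The easy-to-map lower-bound threshold defaults to 0.05; a looser 0.01
screen exists as a config value for sensitivity analysis. An ingestion gate
(drop variants flagged as detected in the normal sample; require tumor
allele read depth > 5) runs before the tree.

Difficult-to-map, non-homopolymer variants require HiFi support: a missing
HiFi summary there is an error rather than a silent pass, because long reads
are the only evidence that distinguishes a real variant from a short-read
mapping artifact in those regions.

Curation verdicts are applied afterwards: KEEP with pooled VAF in
[0.05, 0.30] enters the benchmark; a KEEP outside that range is flagged and
excluded, never silently included; REMOVE excludes from the VCF only;
UNCERTAIN (and every tree-unresolved variant) marks the position for
flanked removal from the regions.

## Benchmark regions

Intervals are 0-based half-open everywhere; conversion to/from 1-based VCF
positions happens only at the I/O boundary. Region construction subtracts
all context exclusions (homopolymers, tandem repeats, germline indels), then
a 101-bp window (the variant base ±50 bp) around each unresolved position,
and finally drops intervals shorter than 50 bp — once, after all
subtractions, so fragments created by any subtraction are caught. Benchmark
variants whose own position ends up inside subtracted context are dropped
from the VCF with a funnel entry: a truth variant outside the regions can
never be scored and would only mislead.

The v1.1 region set is modeled as v1.0 minus two additional flanked
positions supplied through configuration.

## Callset comparison

The comparator matches on exact (chrom, pos, ref, alt) identity within the
benchmark regions ("squash-ploidy": genotype and zygosity are ignored).
This is a deliberate simplification relative to haplotype-aware tools such
as hap.py/vcfeval and is sound only because benchmark variants are isolated
SNVs by construction; it would be wrong for indels or clustered variants.
Query calls matching a supplied germline truth set are not counted as
callset-only. The optional VAF pre-filter (default 5–30% for mosaic-focused
comparisons) is applied after the region restriction; records without a
reported VAF pass unfiltered so that callers which omit the field are not
silently dropped.

## Limit of detection

A mixture containing a fraction `f` of the variant-carrier sample dilutes a
heterozygous carrier-specific variant to expected AF `f/2`. The standard
ladder (f = 1.0, 0.5, 0.2, 0.1, 0.02, 0) gives AFs of 50/25/10/5/1/0%.
The simulation draws per-variant depth from Poisson(mean) and alt reads
from Binomial(depth, p) with `p = af(1−e) + (1−af)e/3` under a uniform
per-base error `e = 10⁻³` (a third of errors hit the specific alt base).
The default detector (alt ≥ 5 and one-sided 95% Wilson lower bound > 0.01)
is a pluggable stand-in for a somatic caller; `detection_power` provides
the exact analytic power of that rule for cross-checking simulated recall.
Recall values from the original real-read experiments (where an actual
caller ran on subsampled alignments) are not reproducible by this
simulation and are not claimed by it; the simulation answers the design
question — at which AF does a threshold rule at this depth lose recall —
not the caller-specific one.

## Batch-effect model

Observations are (variant, DNA source, platform) read counts. The global
model is a binomial GLMM on the logit scale with fixed effects for DNA
source and platform (the platform term enters only when ≥ 2 platforms are
present) and a Gaussian random intercept per variant. The marginal
likelihood integrates the scalar random effect by adaptive Gauss–Hermite
quadrature: per variant, the integrand's mode and curvature are found by
Newton iteration and 25 Hermite nodes are centered and scaled there;
log-sum-exp keeps the node sum stable. The default of 25 nodes is generous
for binomial data at these depths — refining to 101 nodes changes the
log-likelihood by < 10⁻⁴ in tests. Optimization is L-BFGS-B over
(β, log σ_u) with σ_u bounded in [10⁻⁶, 20]; at σ_u → 0 the likelihood
reduces analytically to the pooled GLM, which is verified against
statsmodels to 10⁻⁶. Standard errors come from a finite-difference Hessian.
The global test is a 1-df LRT against the model without the DNA-source
term.

Per-variant tests are binomial GLMs (IRLS via statsmodels) with the
log-odds for the RM source, Wald 95% CI and p-value, adjusted across
variants by Benjamini–Hochberg. When the aggregated 2×2 table has a zero
cell the estimate separates; the Haldane–Anscombe correction (+0.5 to all
four cells) is applied and the result flagged rather than dropped. The
per-variant model is source-only by default; platform can be included but
with two observations per source per platform the interaction is barely
identified, so the simpler model is the default.

## Synthetic-data generator

The generator emulates the construction conditions: per-technology mean
depths 300× (Illumina), 100× (BGI), 136× (Element, both insert libraries
pooled), 106× (HiFi, Sequel + Revio pooled), Poisson depth per variant
(coverage variability is what exercises the depth-quantile filter),
binomial alt reads at the true VAF with the same error model as the LOD
simulation. Three classes:

* **mosaic** — true VAF from Beta(2, 2) scaled onto [0.05, 0.30]
  (mean 0.175). The edge density vanishes by design: a curated benchmark's
  inclusion rule demands confident separation from the class boundaries, so
  true VAFs sitting exactly at 5% or 30% are rare in the population the
  generator emulates.
* **low** — true VAF uniform on [0, 0.02): variants the pipeline must
  confidently ignore.
* **artifact** — no true variant; alt support inflated in exactly one
  short-read technology and absent from long reads, placed inside
  low-mappability regions — the signature of segmental-duplication mapping
  errors.

Stratification BEDs are random disjoint interval sets at configurable
densities (low-mappability 10%, homopolymer 4%, tandem repeat 4%, germline
indel 1% of a ~1 Mbp toy genome); realized coverage equals the requested
density up to rounding by construction. Batch-count tables draw RM counts
at logit(VAF) and non-RM counts at logit(VAF) − shift (default 0.5),
with per-platform depths mirroring the Element/Revio comparison (81/100×
and 48/120×).

What passing tests on this data do **not** show: robustness to alignment
artifacts correlated across technologies, non-binomial overdispersion from
PCR or mapping bias, reference bias, or the behavior of any real somatic
caller. The generator validates the screening logic and the statistics, not
read-level processing.

## Problem sizes and determinism

Test and acceptance simulations run at desk scale chosen to make the checked
properties statistically sharp: 450-variant databases over 5 seeds for the
decision-tree recovery check, 10⁴ variants for LOD-vs-power agreement
(±2%), 500 replicates for LRT type-I error (nominal 5%, accepted band
3–7%), 100 replicates for batch-shift recovery (mean bias < 0.05), 2 000
simulated null draws per CI-coverage check. Every stochastic component
takes an explicit seed; there is no global random state, and design points
use independent seed substreams so adding one does not perturb the others.

## Known limitations

* The comparator is exact-match only; representation differences that
  haplotype-aware tools reconcile would be scored as discrepancies.
* The GLMM supports a single scalar random intercept — no random slopes,
  no crossed effects.
* Multi-allelic VCF records are rejected, not split; normalize upstream.
* The released benchmark's exact VCF INFO/FORMAT layout is a convention of
  this package (INFO/VAF + GT 0/1), not a reproduction of any particular
  distribution file.
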