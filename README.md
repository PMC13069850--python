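# mosaicbench

Tools for constructing and evaluating a **mosaic SNV benchmark**: a truth set
of low-fraction single-nucleotide variants (variant allele fraction, VAF,
5–30%) plus benchmark regions inside which every base is confidently either a
benchmark variant or homozygous reference. The pipeline mirrors how such a
benchmark is built for a deeply sequenced reference cell line: candidate
somatic calls from a trio-based tumor/normal analysis are screened against
read support from several independent sequencing technologies (Illumina, BGI,
Element, PacBio HiFi), routed through a decision tree, manually curated, and
turned into a VCF + BED pair usable with standard benchmarking tools.

It is aimed at people developing or validating low-frequency variant callers
and at benchmark maintainers who want the screening statistics, the region
algebra, and the evaluation machinery as a testable library rather than a
collection of one-off scripts.

## What is inside

| Module | Purpose |
| --- | --- |
| `mosaicbench.ci` | One-sided binomial score (Wilson) bounds on VAF; pooled counts across technologies |
| `mosaicbench.evidence` | Per-variant evidence summaries, ≥2-read support minima, 0.5% depth-quantile thresholds |
| `mosaicbench.tree` | The decision-tree classifier (candidate / confident-reference / excluded / unresolved) |
| `mosaicbench.regions` | Interval algebra (0-based half-open), benchmark BED construction, region and gene-coverage statistics |
| `mosaicbench.compare` | Region-aware squash-ploidy SNV comparison of a query callset against the benchmark |
| `mosaicbench.lod` | In-silico mixture designs and simulated limit-of-detection (recall vs allele fraction) |
| `mosaicbench.batch` | Binomial GLMM (adaptive Gauss–Hermite) + LRT for batch effects; per-variant GLMs with BH FDR |
| `mosaicbench.synth` | Synthetic evidence databases, stratification BEDs and batch-count tables with known truth |
| `mosaicbench.pipeline` / `cli` | End-to-end build with a count funnel; `mosaicbench` console script |

## The statistics at the core

For a variant with `x` alt reads out of `n` total, the VAF screen uses the
Wilson score bound at a one-sided confidence coefficient `c`
(`z = Φ⁻¹(c)`):

```
lower/upper = ( p̂ + z²/2n ∓ z·√(p̂(1−p̂)/n + z²/4n²) ) / (1 + z²/n)
```

Per-technology bounds use `c = 0.95`; the bound on counts pooled across
technologies uses `c = 0.99`. The decision tree then applies, in order:
confident-reference (pooled upper ≤ 0.03), low-coverage removal (below the
0.5% depth quantile of pooled or HiFi coverage), germline-indel overlap,
pooled alt fraction > 0.5, and mappability-dependent lower-bound screens
(pooled lower ≥ 0.05 for easy-to-map variants, HiFi lower ≥ 0.05 otherwise).
Unresolved variants are cut out of the regions with ±50 bp flanks, and
intervals shorter than 50 bp are dropped.

Batch effects between DNA sources are tested with a binomial GLMM
(logit link, fixed effects for DNA source and platform, a Gaussian random
intercept per variant, marginal likelihood by 25-node adaptive Gauss–Hermite
quadrature) and a 1-df likelihood-ratio test, plus per-variant binomial GLMs
with Benjamini–Hochberg correction.

## Worked example

Generate a synthetic study (180 candidate variants: 80 true mosaics, 80
low-fraction, 20 mapping artifacts), then build a benchmark from it:

```bash
mosaicbench synth --seed 7 --out-dir demo --n-mosaic 80 --n-low 80 --n-artifact 20
# ... write demo/config.yaml pointing at the generated files and a curation
#     sheet (tests/test_pipeline.py shows this end to end), then:
mosaicbench build --config demo/config.yaml
```

```
{
  "input": 180,
  "post_ingestion_gate": 98,
  "post_upper_ci": 98,
  "post_depth": 96,
  "post_germline_indel": 95,
  "post_ratio": 95,
  "easy_to_map": 81,
  "easy_to_map_pass": 68,
  "not_easy_to_map": 14,
  "not_easy_to_map_pass": 8,
  "candidates_for_curation": 76,
  "benchmark_variants": 76,
  "benchmark_regions": 61,
  "benchmark_region_bases": 912294,
  "benchmark_variants_in_regions": 65
}
```

Reading the funnel: the ingestion gate (caller filter token and tumor
allele read depth > 5) removes most low-fraction candidates; none of the
survivors are confidently reference (their pooled upper bounds exceed 3%);
coverage, germline-indel and alt-ratio rules trim a few more; 76 variants
pass the mappability-dependent lower-bound screens and, after curation
labels, all 76 enter the benchmark VCF, of which 65 lie inside the final
benchmark regions (the rest sit in subtracted homopolymer/tandem-repeat
context). The simulated limit of detection at 300× coverage:

```bash
mosaicbench lod --n-variants 2000 --seed 17
```

```
 expected_af  n_truth  n_detected  recall  defined
        0.50     2000        2000  1.0000     True
        0.25     2000        2000  1.0000     True
        0.10     2000        2000  1.0000     True
        0.05     2000        1992  0.9960     True
        0.01     2000         169  0.0845     True
        0.00     2000           0  0.0000     True
```

Recall stays ≥ 99% down to a 5% allele fraction and collapses near 1%,
which is why 5% is the sensible inclusion floor for a benchmark built at
these depths.

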