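"""End-to-end benchmark construction: ingest -> classify -> curate -> regions.

``run_build`` is a pure function of its configuration and input files: it
reads the evidence database and stratification BEDs, applies the ingestion
gate and the decision tree, applies curation labels, constructs benchmark
regions, and writes the benchmark VCF and BED plus a count funnel recording
how many variants survive each gate in order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .evidence import EvidenceConfig, depth_thresholds, summarize
from .regions import IntervalSet, build_benchmark_bed, region_stats
from .tree import (
    BenchmarkSelection,
    Category,
    ClassificationResult,
    TreeConfig,
    classification_table,
    classify,
    derive_flags,
    finalize_benchmark,
    pre_tree_gate,
)

logger = logging.getLogger("mosaicbench")

#: positions cut (with 50 bp flanks) from the v1.0 regions to produce v1.1:
#: two likely-mosaic variants identified during external validation.
DEFAULT_V11_EXCLUSIONS = (("chr6", 150458314), ("chr1", 242208421))


@dataclass
class RunConfig:
    """Inputs and thresholds for a benchmark build."""

    evidence: str
    base_regions: str
    strat_low_mappability: str
    strat_homopolymer: str
    strat_tandem_repeat: str
    germline_indels: str
    curation: str
    out_vcf: str
    out_bed: str
    out_funnel: str | None = None
    version: str = "v1.0"  # v1.0 | v1.1 | custom
    extra_region_exclusions: list = field(default_factory=list)  # (chrom, pos) 1-based
    min_tar_depth: int = 6
    flank: int = 50
    min_region_len: int = 50
    tree: TreeConfig = field(default_factory=TreeConfig)
    evidence_config: EvidenceConfig = field(default_factory=EvidenceConfig)

    def __post_init__(self) -> None:
        if self.version not in ("v1.0", "v1.1", "custom"):
            raise ValueError(f"version must be v1.0, v1.1 or custom, got {self.version!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tree_kwargs = raw.pop("tree", {})
        ev_kwargs = raw.pop("evidence_config", {})
        if "benchmark_vaf_range" in tree_kwargs:
            tree_kwargs["benchmark_vaf_range"] = tuple(tree_kwargs["benchmark_vaf_range"])
        defaults = cls.__dataclass_fields__
        unknown = set(raw) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in {**tree_kwargs, **ev_kwargs}.items():
            logger.info("config override: %s = %r", key, val)
        return cls(tree=TreeConfig(**tree_kwargs), evidence_config=EvidenceConfig(**ev_kwargs), **raw)


@dataclass
class BuildResult:
    funnel: dict[str, int]
    classifications: list[ClassificationResult]
    selection: BenchmarkSelection
    benchmark_regions: IntervalSet
    #: benchmark variants written to the VCF: the curated KEEP set restricted
    #: to the final regions (a variant in subtracted context cannot be
    #: benchmarked and is dropped with a funnel entry)
    benchmark_variants: list = field(default_factory=list)


def run_build(config: RunConfig) -> BuildResult:
    """Execute the full benchmark build; writes VCF, BED and the funnel."""
    funnel: dict[str, int] = {}

    def stage(name: str, count: int) -> None:
        funnel[name] = count
        logger.info("funnel %-28s %d", name, count)

    try:
        db = mio.read_evidence_table(config.evidence)
        stage("input", len(db))

        gated = pre_tree_gate(db, min_tar_depth=config.min_tar_depth)
        stage("post_ingestion_gate", len(gated))

        strats = {
            "low_mappability": IntervalSet.from_dataframe(mio.read_bed(config.strat_low_mappability)),
            "homopolymer": IntervalSet.from_dataframe(mio.read_bed(config.strat_homopolymer)),
            "tandem_repeat": IntervalSet.from_dataframe(mio.read_bed(config.strat_tandem_repeat)),
            "germline_indel": IntervalSet.from_dataframe(mio.read_bed(config.germline_indels)),
        }
        base = IntervalSet.from_dataframe(mio.read_bed(config.base_regions))
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc

    try:
        ecfg, tcfg = config.evidence_config, config.tree
        summaries = {ev.key: summarize(ev, ecfg) for ev in gated}
        survivors = [s for s in summaries.values() if s.combined.upper > tcfg.upper_ci_max]
        thresholds = depth_thresholds(survivors or list(summaries.values()), ecfg.depth_quantile)

        results = []
        flags_by_key = {}
        for ev in gated:
            flags = derive_flags(ev.key, strats) | ev.flags
            flags_by_key[ev.key] = flags
            results.append(classify(summaries[ev.key], flags, thresholds, tcfg))

        by_cat = {cat: [r for r in results if r.category is cat] for cat in Category}
        n = len(results)
        n -= len(by_cat[Category.REFERENCE_CONFIDENT]); stage("post_upper_ci", n)
        n -= len(by_cat[Category.EXCLUDED_LOW_DEPTH]); stage("post_depth", n)
        n -= len(by_cat[Category.EXCLUDED_GERMLINE_INDEL]); stage("post_germline_indel", n)
        n -= len(by_cat[Category.EXCLUDED_HIGH_RATIO]); stage("post_ratio", n)

        reached_partition = [
            r for r in results
            if r.category in (Category.CANDIDATE_FOR_CURATION, Category.UNCERTAIN_REMOVE_REGION,
                              Category.EXCLUDED_HOMOPOLYMER)
        ]
        easy = [r for r in reached_partition if mio.ContextFlag.EASY_TO_MAP in flags_by_key[r.key]]
        not_easy = [r for r in reached_partition if mio.ContextFlag.EASY_TO_MAP not in flags_by_key[r.key]]
        stage("easy_to_map", len(easy))
        stage("easy_to_map_pass", sum(r.category is Category.CANDIDATE_FOR_CURATION for r in easy))
        stage("not_easy_to_map", len(not_easy))
        stage("not_easy_to_map_pass",
              sum(r.category is Category.CANDIDATE_FOR_CURATION for r in not_easy))
        stage("candidates_for_curation", len(by_cat[Category.CANDIDATE_FOR_CURATION]))
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    try:
        labels = mio.read_curation_csv(config.curation)
        selection = finalize_benchmark(results, summaries, labels, tcfg.benchmark_vaf_range)
        stage("benchmark_variants", len(selection.benchmark))
    except Exception as exc:
        raise RuntimeError(f"stage 'curate' failed: {exc}") from exc

    try:
        uncertain = list(selection.bed_exclusion_positions)
        if config.version == "v1.1":
            uncertain += [tuple(p) for p in DEFAULT_V11_EXCLUSIONS]
        uncertain += [tuple(p) for p in config.extra_region_exclusions]
        regions = build_benchmark_bed(
            base,
            exclusions=[strats["homopolymer"], strats["tandem_repeat"], strats["germline_indel"]],
            uncertain_positions=uncertain,
            flank=config.flank,
            min_len=config.min_region_len,
        )
        stats = region_stats(regions)
        stage("benchmark_regions", stats.n_regions)
        stage("benchmark_region_bases", stats.total_bases)
        final = [(k, v) for k, v in selection.benchmark if regions.contains_key(k)]
        stage("benchmark_variants_in_regions", len(final))
    except Exception as exc:
        raise RuntimeError(f"stage 'regions' failed: {exc}") from exc

    try:
        mio.write_benchmark_vcf(final, config.out_vcf)
        mio.write_bed(regions, config.out_bed)
        classification_table(results)  # validated here; callers may re-derive it
        if config.out_funnel:
            with open(config.out_funnel, "w") as fh:
                json.dump(funnel, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage 'write' failed: {exc}") from exc

    return BuildResult(
        funnel=funnel, classifications=results, selection=selection,
        benchmark_regions=regions, benchmark_variants=final,
    )
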