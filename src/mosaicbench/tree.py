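"""The decision-tree classifier that screens candidate mosaic SNVs.

Every candidate in the evidence database is routed through an ordered set of
rules to one of three outcomes: a candidate for manual curation, a position
confidently homozygous-reference (so it stays inside benchmark regions), or
an exclusion (from the VCF, and for unresolved cases from the regions too).

Rule order, with defaults:

1. combined upper bound <= 0.03           -> confidently reference
2. combined or HiFi depth below the 0.5% quantile -> excluded (low depth)
3. overlaps a germline indel              -> excluded
4. pooled alt fraction x_ci/n_ci > 0.5    -> excluded (likely germline/artifact)
5. easy-to-map: combined lower >= 0.05    -> curation candidate, else unresolved
6. difficult-to-map homopolymer           -> excluded
7. difficult-to-map otherwise: HiFi lower >= 0.05 -> curation candidate,
   else unresolved (long-read support is mandatory off the easy bin)

Unresolved ("could not be confidently determined to be <2% or >=5% VAF")
variants are later cut out of the benchmark regions with flanking sequence.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import (
    DepthThresholds,
    EvidenceConfig,
    EvidenceSummary,
    depth_thresholds,
    summarize,
)
from .io import ContextFlag, CurationLabel, VariantEvidence, VariantKey, Verdict
from .regions import IntervalSet


class Category(enum.Enum):
    CANDIDATE_FOR_CURATION = "CANDIDATE_FOR_CURATION"
    REFERENCE_CONFIDENT = "REFERENCE_CONFIDENT"
    EXCLUDED_LOW_DEPTH = "EXCLUDED_LOW_DEPTH"
    EXCLUDED_GERMLINE_INDEL = "EXCLUDED_GERMLINE_INDEL"
    EXCLUDED_HIGH_RATIO = "EXCLUDED_HIGH_RATIO"
    EXCLUDED_HOMOPOLYMER = "EXCLUDED_HOMOPOLYMER"
    UNCERTAIN_REMOVE_REGION = "UNCERTAIN_REMOVE_REGION"


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree thresholds (VAF scale, proportions).

    ``lower_ci_min`` is the combined lower-bound threshold for easy-to-map
    variants; an alternative looser screen at 0.01 exists for sensitivity
    analysis but 0.05 is the value that defines the benchmark.
    """

    upper_ci_max: float = 0.03
    lower_ci_min: float = 0.05
    hifi_lower_ci_min: float = 0.05
    ratio_max: float = 0.5
    ref_vaf_max: float = 0.02
    benchmark_vaf_range: tuple[float, float] = (0.05, 0.30)

    def __post_init__(self) -> None:
        lo, hi = self.benchmark_vaf_range
        if not self.ref_vaf_max < lo <= hi:
            raise ValueError("need ref_vaf_max < benchmark_vaf_range.low <= .high")


@dataclass(frozen=True)
class ClassificationResult:
    key: VariantKey
    category: Category
    #: ordered (rule_id, human-readable comparison) pairs along the path taken
    reasons: tuple[tuple[str, str], ...]


class MissingHiFiError(ValueError):
    """A difficult-to-map variant lacks HiFi read support."""


def classify(
    summary: EvidenceSummary,
    flags: set[ContextFlag],
    thresholds: DepthThresholds,
    config: TreeConfig = TreeConfig(),
) -> ClassificationResult:
    """Route one variant through the decision tree.

    Threshold comparisons are inclusive for the bound rules (<= / >=) and
    strict for the alt-ratio and low-depth rules, per the rule statements.
    """
    reasons: list[tuple[str, str]] = []
    cc = summary.combined_counts

    reasons.append(("upper_ci", f"combined upper {summary.combined.upper:.4f} vs <= {config.upper_ci_max}"))
    if summary.combined.upper <= config.upper_ci_max:
        return ClassificationResult(summary.key, Category.REFERENCE_CONFIDENT, tuple(reasons))

    reasons.append((
        "low_depth",
        f"n_ci {cc.n_ci} vs >= {thresholds.min_combined_reads:.1f}; "
        f"hifi depth {summary.hifi_depth} vs >= {thresholds.min_hifi_reads:.1f}",
    ))
    if cc.n_ci < thresholds.min_combined_reads or summary.hifi_depth < thresholds.min_hifi_reads:
        return ClassificationResult(summary.key, Category.EXCLUDED_LOW_DEPTH, tuple(reasons))

    reasons.append(("germline_indel", f"overlaps germline indel: {ContextFlag.OVERLAPS_GERMLINE_INDEL in flags}"))
    if ContextFlag.OVERLAPS_GERMLINE_INDEL in flags:
        return ClassificationResult(summary.key, Category.EXCLUDED_GERMLINE_INDEL, tuple(reasons))

    ratio = cc.point
    reasons.append(("high_ratio", f"x_ci/n_ci {ratio:.4f} vs <= {config.ratio_max}"))
    if ratio > config.ratio_max:
        return ClassificationResult(summary.key, Category.EXCLUDED_HIGH_RATIO, tuple(reasons))

    easy = ContextFlag.EASY_TO_MAP in flags
    reasons.append(("mappability", f"easy_to_map: {easy}"))
    if easy:
        reasons.append(("combined_lower", f"combined lower {summary.combined.lower:.4f} vs >= {config.lower_ci_min}"))
        if summary.combined.lower >= config.lower_ci_min:
            return ClassificationResult(summary.key, Category.CANDIDATE_FOR_CURATION, tuple(reasons))
        return ClassificationResult(summary.key, Category.UNCERTAIN_REMOVE_REGION, tuple(reasons))

    reasons.append(("homopolymer", f"homopolymer: {ContextFlag.HOMOPOLYMER in flags}"))
    if ContextFlag.HOMOPOLYMER in flags:
        return ClassificationResult(summary.key, Category.EXCLUDED_HOMOPOLYMER, tuple(reasons))

    if summary.hifi is None:
        raise MissingHiFiError(
            f"{summary.key}: difficult-to-map variant without HiFi support; "
            "long-read evidence is mandatory outside the easy-to-map bin"
        )
    reasons.append(("hifi_lower", f"hifi lower {summary.hifi.lower:.4f} vs >= {config.hifi_lower_ci_min}"))
    if summary.hifi.lower >= config.hifi_lower_ci_min:
        return ClassificationResult(summary.key, Category.CANDIDATE_FOR_CURATION, tuple(reasons))
    return ClassificationResult(summary.key, Category.UNCERTAIN_REMOVE_REGION, tuple(reasons))


def derive_flags(key: VariantKey, strats: Mapping[str, IntervalSet]) -> set[ContextFlag]:
    """Genomic-context flags from stratification membership.

    Recognized stratification names: ``low_mappability``, ``homopolymer``,
    ``tandem_repeat``, ``germline_indel``, ``complex_or_sv``.  EASY_TO_MAP is
    the complement of the low-mappability set.
    """
    flags: set[ContextFlag] = set()
    lowmap = strats.get("low_mappability")
    if lowmap is None or not lowmap.contains_key(key):
        flags.add(ContextFlag.EASY_TO_MAP)
    mapping = {
        "homopolymer": ContextFlag.HOMOPOLYMER,
        "tandem_repeat": ContextFlag.TANDEM_REPEAT,
        "germline_indel": ContextFlag.OVERLAPS_GERMLINE_INDEL,
        "complex_or_sv": ContextFlag.IN_COMPLEX_OR_SV,
    }
    for name, flag in mapping.items():
        strat = strats.get(name)
        if strat is not None and strat.contains_key(key):
            flags.add(flag)
    return flags


def pre_tree_gate(
    evidences: Iterable[VariantEvidence],
    min_tar_depth: int = 6,
    drop_filter_tokens: Sequence[str] = ("VARIANT_DETECTED_IN_NORMAL",),
) -> list[VariantEvidence]:
    """Ingestion gate applied before the tree.

    Drops candidates flagged by the caller as detected in the normal sample
    and those whose tumor allele read depth (TAR) is below ``min_tar_depth``
    (the caller-level "TAR > 5" retention rule).
    """
    tokens = set(drop_filter_tokens)
    out = []
    for ev in evidences:
        if tokens & set(ev.caller_filter.split(";")):
            continue
        if ev.tar_depth < min_tar_depth:
            continue
        out.append(ev)
    return out


def classify_all(
    db: Sequence[VariantEvidence],
    strats: Mapping[str, IntervalSet],
    config: TreeConfig = TreeConfig(),
    evidence_config: EvidenceConfig = EvidenceConfig(),
    thresholds: DepthThresholds | None = None,
) -> tuple[list[ClassificationResult], Counter]:
    """Classify a whole database; returns (results, tally per category).

    Depth thresholds, when not supplied, are the 0.5% quantiles computed over
    the variants that survive the upper-bound filter (the screen population
    whose coverage distribution the quantile is meant to describe).
    """
    summaries = [summarize(ev, evidence_config) for ev in db]
    if thresholds is None:
        survivors = [s for s in summaries if s.combined.upper > config.upper_ci_max]
        ref_set = survivors if survivors else summaries
        thresholds = depth_thresholds(ref_set, evidence_config.depth_quantile) if ref_set else DepthThresholds(0, 0)
    results = []
    for ev, summ in zip(db, summaries):
        flags = derive_flags(ev.key, strats) | ev.flags
        results.append(classify(summ, flags, thresholds, config))
    tally = Counter(r.category for r in results)
    return results, tally


@dataclass
class BenchmarkSelection:
    """Outcome of applying curation labels to the tree's candidates."""

    benchmark: list[tuple[VariantKey, float]] = field(default_factory=list)
    vcf_exclusions: list[VariantKey] = field(default_factory=list)
    bed_exclusion_positions: list[VariantKey] = field(default_factory=list)
    out_of_range: list[tuple[VariantKey, float]] = field(default_factory=list)


def finalize_benchmark(
    classifications: Sequence[ClassificationResult],
    summaries: Mapping[VariantKey, EvidenceSummary],
    curation: Sequence[CurationLabel],
    vaf_range: tuple[float, float] = (0.05, 0.30),
) -> BenchmarkSelection:
    """Apply curation verdicts to curation candidates.

    KEEP with combined VAF inside ``vaf_range`` enters the benchmark; REMOVE
    is excluded from the VCF only (the position stays a confident-reference
    base); UNCERTAIN verdicts and tree-unresolved variants mark positions for
    flanked removal from the benchmark regions.  A KEEP whose VAF falls
    outside the range is flagged (``out_of_range``), never silently included.
    Every candidate must carry a label.
    """
    labels = {lab.key: lab for lab in curation}
    unlabeled = [
        str(c.key) for c in classifications
        if c.category is Category.CANDIDATE_FOR_CURATION and c.key not in labels
    ]
    if unlabeled:
        raise ValueError("curation candidates without labels: " + ", ".join(unlabeled))

    sel = BenchmarkSelection()
    lo, hi = vaf_range
    for c in classifications:
        if c.category is Category.UNCERTAIN_REMOVE_REGION:
            sel.bed_exclusion_positions.append(c.key)
            continue
        if c.category is not Category.CANDIDATE_FOR_CURATION:
            continue
        lab = labels[c.key]
        point = summaries[c.key].combined.point
        if lab.verdict is Verdict.KEEP:
            if lo <= point <= hi:
                sel.benchmark.append((c.key, point))
            else:
                sel.out_of_range.append((c.key, point))
        elif lab.verdict is Verdict.REMOVE:
            sel.vcf_exclusions.append(c.key)
        else:  # UNCERTAIN: evidence unclear -> cut the region too
            sel.bed_exclusion_positions.append(c.key)
    return sel


def classification_table(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    rows = [
        dict(
            chrom=r.key.chrom, pos=r.key.pos, ref=r.key.ref, alt=r.key.alt,
            category=r.category.value,
            reasons=" | ".join(f"{rid}: {txt}" for rid, txt in r.reasons),
        )
        for r in results
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "category", "reasons"])
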