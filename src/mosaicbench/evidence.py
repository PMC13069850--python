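"""Per-variant evidence summaries: VAF confidence bounds and depth thresholds.

Raw per-technology read counts are turned into the quantities the decision
tree consumes: a score bound per technology (one-sided 95%), a combined
bound over the pooled counts (one-sided 99%), a long-read-only bound
(one-sided 95%), and empirical low-coverage thresholds (the 0.5% depth
quantile of combined and of HiFi coverage).

A per-technology minimum alt-read rule is applied first: a technology whose
alt count falls below the minimum (default 2 reads) has its alt count zeroed
but keeps its depth, so it still contributes denominator to the combined
bound.  This mirrors treating singleton alt reads as sequencing noise rather
than dropping the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .ci import CIMethod, CombinedCounts, ConfidenceBound, combine_counts, wilson_bound
from .io import Technology, TechReadSupport, VariantEvidence, VariantKey


@dataclass(frozen=True)
class EvidenceConfig:
    """Tunables for evidence summarization.

    min_alt_per_tech
        Alt counts below this per technology are zeroed (depth kept).
    ci_level_single / ci_level_combined
        One-sided confidence coefficients for per-technology and pooled
        bounds.
    combined_techs
        Technologies pooled into the combined bound.  The Illumina discovery
        data is included by default alongside the orthogonal datasets; set
        ``orthogonal_only()`` to exclude it.
    depth_quantile
        Fraction for the low-coverage thresholds.
    """

    min_alt_per_tech: int = 2
    ci_level_single: float = 0.95
    ci_level_combined: float = 0.99
    combined_techs: tuple[Technology, ...] = (
        Technology.ILLUMINA, Technology.BGI, Technology.ELEMENT, Technology.HIFI,
    )
    depth_quantile: float = 0.005
    method: CIMethod = CIMethod.WILSON

    @staticmethod
    def orthogonal_only() -> "EvidenceConfig":
        return EvidenceConfig(
            combined_techs=(Technology.BGI, Technology.ELEMENT, Technology.HIFI)
        )


@dataclass(frozen=True)
class EvidenceSummary:
    """All VAF bounds and pooled counts for one candidate variant."""

    key: VariantKey
    per_tech: dict[Technology, ConfidenceBound]
    combined: ConfidenceBound
    combined_counts: CombinedCounts
    hifi: ConfidenceBound | None
    hifi_depth: int


@dataclass(frozen=True)
class DepthThresholds:
    """Empirical low-coverage cutoffs (reads) at a small depth quantile."""

    min_combined_reads: float
    min_hifi_reads: float
    quantile: float = 0.005

    def __post_init__(self) -> None:
        if self.min_combined_reads < 0 or self.min_hifi_reads < 0:
            raise ValueError("depth thresholds must be non-negative")
        if not 0 <= self.quantile < 0.5:
            raise ValueError(f"quantile must be in [0, 0.5), got {self.quantile}")


def apply_support_minimum(
    supports: Iterable[TechReadSupport], min_alt: int
) -> list[TechReadSupport]:
    """Zero alt counts below ``min_alt`` per technology; depth is retained."""
    if min_alt < 0:
        raise ValueError("min_alt must be >= 0")
    out = []
    for s in supports:
        if s.alt_count < min_alt:
            s = replace(s, alt_count=0)
        out.append(s)
    return out


def summarize(evidence: VariantEvidence, config: EvidenceConfig = EvidenceConfig()) -> EvidenceSummary:
    """Compute per-technology, combined, and HiFi-only VAF bounds.

    The minimum-support rule is applied before any bound.  Raises if the
    variant has no read support or zero total depth.
    """
    if not evidence.supports:
        raise ValueError(f"{evidence.key}: no read support")
    supports = apply_support_minimum(evidence.supports, config.min_alt_per_tech)

    per_tech: dict[Technology, ConfidenceBound] = {}
    for s in supports:
        if s.depth > 0:
            per_tech[s.technology] = wilson_bound(
                s.alt_count, s.depth, level=config.ci_level_single, method=config.method
            )

    counts = combine_counts(supports, include=config.combined_techs)
    if counts.n_ci == 0:
        raise ValueError(f"{evidence.key}: zero total depth across combined technologies")
    combined = wilson_bound(
        counts.x_ci, counts.n_ci, level=config.ci_level_combined, method=config.method
    )

    hifi_support = next((s for s in supports if s.technology is Technology.HIFI), None)
    hifi_depth = hifi_support.depth if hifi_support else 0
    hifi = per_tech.get(Technology.HIFI)

    return EvidenceSummary(
        key=evidence.key,
        per_tech=per_tech,
        combined=combined,
        combined_counts=counts,
        hifi=hifi,
        hifi_depth=hifi_depth,
    )


def depth_thresholds(
    summaries: Sequence[EvidenceSummary], quantile: float = 0.005
) -> DepthThresholds:
    """Empirical depth quantiles of combined and HiFi coverage.

    Uses the linear-interpolation quantile definition (numpy default);
    ``quantile=0`` gives the minimum observed depth.
    """
    if not summaries:
        raise ValueError("cannot compute depth thresholds from an empty summary list")
    if not 0 <= quantile < 0.5:
        raise ValueError(f"quantile must be in [0, 0.5), got {quantile}")
    n_ci = np.array([s.combined_counts.n_ci for s in summaries], dtype=float)
    hifi = np.array([s.hifi_depth for s in summaries], dtype=float)
    return DepthThresholds(
        min_combined_reads=float(np.quantile(n_ci, quantile)),
        min_hifi_reads=float(np.quantile(hifi, quantile)),
        quantile=quantile,
    )
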