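"""Region-aware SNV comparison of a query callset against the benchmark.

A deliberately simple squash-ploidy matcher: two calls match when they agree
on (chrom, pos, ref, alt); genotype/zygosity and local haplotype
representation are ignored.  That is sound here because benchmark variants
are isolated SNVs by construction (complex/nearby variants were excluded),
but it is a documented divergence from hap.py / vcfeval, which perform
haplotype-aware matching.

Query calls outside the benchmark regions are ignored entirely; query calls
matching a supplied germline set are not counted as callset-only (they are
germline benchmark variants, not putative false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SnvRecord, VariantKey
from .regions import IntervalSet


@dataclass
class ComparisonResult:
    """Partition of query and truth SNVs within benchmark regions."""

    both: list[VariantKey] = field(default_factory=list)
    callset_only: list[VariantKey] = field(default_factory=list)
    truth_only: list[VariantKey] = field(default_factory=list)

    @property
    def n_both(self) -> int:
        return len(self.both)

    @property
    def n_callset_only(self) -> int:
        return len(self.callset_only)

    @property
    def n_truth_only(self) -> int:
        return len(self.truth_only)

    @property
    def recall(self) -> float:
        denom = self.n_both + self.n_truth_only
        return self.n_both / denom if denom else float("nan")


def _keys(records: Sequence) -> list[VariantKey]:
    return [r.key if isinstance(r, SnvRecord) else r for r in records]


def _check_chrom_consistency(query: Sequence[VariantKey], truth: Sequence[VariantKey]) -> None:
    def styles(keys):
        return {k.chrom.startswith("chr") for k in keys}

    sq, st = styles(query), styles(truth)
    if sq and st and sq != st:
        raise ValueError(
            "inconsistent chromosome naming between query and truth "
            "(one uses 'chr' prefixes, the other does not); remap one side"
        )


def compare(
    query: Sequence[SnvRecord | VariantKey],
    truth: Sequence[SnvRecord | VariantKey],
    regions: IntervalSet,
    germline: Sequence[SnvRecord | VariantKey] = (),
    vaf_range: tuple[float, float] | None = None,
) -> ComparisonResult:
    """Compare a query SNV callset with the benchmark truth set.

    ``vaf_range``, when given, keeps only query records whose reported VAF
    lies inside the closed range (records without a VAF pass unfiltered);
    the region restriction is applied before the VAF filter.  ``both`` and
    ``truth_only`` always partition the truth set restricted to regions.
    """
    truth_keys = _keys(truth)
    query_records = [r if isinstance(r, SnvRecord) else SnvRecord(key=r) for r in query]
    _check_chrom_consistency([r.key for r in query_records], truth_keys)

    in_regions = [r for r in query_records if regions.contains_key(r.key)]
    if vaf_range is not None:
        lo, hi = vaf_range
        in_regions = [r for r in in_regions if r.vaf is None or lo <= r.vaf <= hi]

    truth_in_regions = {k for k in truth_keys if regions.contains_key(k)}
    germline_set = set(_keys(germline))
    query_set = {r.key for r in in_regions}

    both = sorted(query_set & truth_in_regions)
    callset_only = sorted(query_set - truth_in_regions - germline_set)
    truth_only = sorted(truth_in_regions - query_set)
    return ComparisonResult(both=both, callset_only=callset_only, truth_only=truth_only)


def curation_sample(
    callset_only: Sequence[VariantKey], k: int, seed: int
) -> list[VariantKey]:
    """Reproducible uniform sample (without replacement) for manual review."""
    if k < 0:
        raise ValueError("sample size must be non-negative")
    if k > len(callset_only):
        raise ValueError(f"cannot sample {k} from {len(callset_only)} variants")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(callset_only), size=k, replace=False)
    return [callset_only[i] for i in sorted(idx)]
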