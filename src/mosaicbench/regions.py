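"""Genomic interval algebra and benchmark-region construction.

Benchmark regions are the genomic intervals within which every base is
confidently either a benchmark mosaic SNV or homozygous reference.  They are
built by subtracting difficult context (tandem repeats, homopolymers),
regions around variants whose VAF could not be confidently resolved, and
finally dropping fragments shorter than a minimum length, from a
characterizable base region set.

All intervals are 0-based half-open.  :class:`IntervalSet` keeps, per
chromosome, a sorted merged array of intervals, so set operations are linear
sweeps over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantKey


@dataclass(frozen=True)
class RegionStats:
    n_regions: int
    total_bases: int
    min_len: int
    max_len: int


class IntervalSet:
    """Per-chromosome sorted, merged, non-overlapping half-open intervals."""

    def __init__(self, intervals: Mapping[str, np.ndarray] | None = None):
        self._ivs: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size and arr.min() < 0:
                    raise ValueError(f"negative coordinate on {chrom}")
                if arr.size and (arr[:, 1] <= arr[:, 0]).any():
                    raise ValueError(f"empty or inverted interval on {chrom}")
                merged = _merge(arr)
                if merged.size:
                    self._ivs[chrom] = merged

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        """Normalize a raw BED DataFrame (chrom/start/end) into a set."""
        if df.empty:
            return cls()
        return cls.from_tuples(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))

    # -- exports ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(c, int(s), int(e)) for c in sorted(self._ivs) for s, e in self._ivs[c]]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def to_tuples(self) -> list[tuple[str, int, int]]:
        return [(c, int(s), int(e)) for c in sorted(self._ivs) for s, e in self._ivs[c]]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._ivs)

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivs.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.to_tuples() == other.to_tuples()

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bases} bases)"

    @property
    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivs.values()))

    # -- membership ---------------------------------------------------------

    def contains(self, chrom: str, pos0: int) -> bool:
        """Is base ``pos0`` (0-based) inside the set?"""
        arr = self._ivs.get(chrom)
        if arr is None:
            return False
        i = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < arr[i, 1]

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        arr = self._ivs.get(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        if arr is None:
            return np.zeros(pos0.shape, dtype=bool)
        i = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = i >= 0
        res = np.zeros(pos0.shape, dtype=bool)
        res[ok] = pos0[ok] < arr[i[ok], 1]
        return res

    def contains_key(self, key: VariantKey) -> bool:
        return self.contains(key.chrom, key.pos0)

    # -- set algebra --------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Already-normalized sets are fixed points; returns self (idempotent)."""
        return self

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self._ivs) | set(other._ivs):
            parts = [a for a in (self._ivs.get(chrom), other._ivs.get(chrom)) if a is not None]
            out[chrom] = np.concatenate(parts)
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self._ivs) & set(other._ivs):
            res = _intersect(self._ivs[chrom], other._ivs[chrom])
            if res.size:
                out[chrom] = res
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom, arr in self._ivs.items():
            b = other._ivs.get(chrom)
            res = arr if b is None else _subtract(arr, b)
            if res.size:
                out[chrom] = res
        return IntervalSet(out)

    def filter_min_length(self, min_len: int) -> "IntervalSet":
        out = {}
        for chrom, arr in self._ivs.items():
            keep = arr[:, 1] - arr[:, 0] >= min_len
            if keep.any():
                out[chrom] = arr[keep]
        return IntervalSet(out)


def _merge(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    starts, ends = arr[:, 0], arr[:, 1]
    # an interval starts a new block when it begins after the running max end
    run_max = np.maximum.accumulate(ends)
    new_block = np.ones(len(arr), dtype=bool)
    new_block[1:] = starts[1:] > run_max[:-1]
    idx = np.flatnonzero(new_block)
    out = np.empty((len(idx), 2), dtype=np.int64)
    out[:, 0] = starts[idx]
    block_end = np.append(idx[1:], len(arr))
    out[:, 1] = [run_max[e - 1] for e in block_end]
    return out


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            res.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(res, dtype=np.int64).reshape(-1, 2)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < end:
            if b[k, 0] > cur:
                res.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            if cur >= end:
                break
            k += 1
        if cur < end:
            res.append((cur, end))
    return np.array(res, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# benchmark BED construction
# ---------------------------------------------------------------------------

def exclusion_windows(positions: Sequence, flank: int = 50) -> IntervalSet:
    """±flank windows around variant bases (the base plus ``flank`` per side).

    ``positions`` holds :class:`~mosaicbench.io.VariantKey` objects or
    (chrom, pos) pairs with a 1-based position.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    tuples = []
    for p in positions:
        chrom, pos0 = (p.chrom, p.pos0) if hasattr(p, "pos0") else (p[0], int(p[1]) - 1)
        tuples.append((chrom, max(0, pos0 - flank), pos0 + flank + 1))
    return IntervalSet.from_tuples(tuples)


def build_benchmark_bed(
    base: IntervalSet,
    exclusions: Sequence[IntervalSet] = (),
    uncertain_positions: Sequence[VariantKey] = (),
    flank: int = 50,
    min_len: int = 50,
) -> IntervalSet:
    """Construct benchmark regions from a characterizable base set.

    Subtracts every exclusion set, then a (2*flank + 1)-bp window around each
    unresolved-VAF variant, and finally drops intervals shorter than
    ``min_len`` (run once, after all subtractions, so fragments created by
    any subtraction are caught).
    """
    result = base
    for excl in exclusions:
        result = result.subtract(excl)
    if uncertain_positions:
        result = result.subtract(exclusion_windows(uncertain_positions, flank=flank))
    return result.filter_min_length(min_len)


def region_stats(intervals: IntervalSet) -> RegionStats:
    """Count, total bases, and min/max interval length of a region set."""
    lengths = np.concatenate(
        [a[:, 1] - a[:, 0] for a in intervals._ivs.values()] or [np.array([], dtype=np.int64)]
    )
    if lengths.size == 0:
        return RegionStats(n_regions=0, total_bases=0, min_len=0, max_len=0)
    return RegionStats(
        n_regions=int(lengths.size),
        total_bases=int(lengths.sum()),
        min_len=int(lengths.min()),
        max_len=int(lengths.max()),
    )


def gene_coverage(
    intervals: IntervalSet,
    genes: pd.DataFrame,
    threshold: float = 0.9,
) -> tuple[pd.DataFrame, int, int]:
    """Fraction of each gene's bases covered by a region set.

    ``genes`` needs columns chrom/start/end/name; a gene may span several rows
    (bases are unioned per name).  Returns (per-gene table with columns
    name/length/covered/fraction, number of genes with fraction > threshold,
    total covered bases over the union of all gene intervals).
    """
    if genes.empty:
        return pd.DataFrame(columns=["name", "length", "covered", "fraction"]), 0, 0
    if (genes["end"].astype(int) <= genes["start"].astype(int)).any():
        raise ValueError("zero- or negative-length gene interval")
    rows = []
    for name, sub in genes.groupby("name", sort=True):
        gene_set = IntervalSet.from_dataframe(sub)
        length = gene_set.total_bases
        covered = gene_set.intersect(intervals).total_bases
        rows.append((name, length, covered, covered / length))
    table = pd.DataFrame(rows, columns=["name", "length", "covered", "fraction"])
    n_above = int((table["fraction"] > threshold).sum())
    union_covered = IntervalSet.from_dataframe(genes).intersect(intervals).total_bases
    return table, n_above, union_covered
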