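"""One-sided binomial confidence bounds on variant allele fractions.

Candidate mosaic variants are screened on read-count evidence: the observed
alt-read fraction x/n is an estimate of the variant allele fraction (VAF),
and decisions ("confidently below 3%", "confidently at or above 5%") are made
on one-sided score (Wilson) bounds rather than the raw fraction.

A one-sided confidence coefficient ``c`` is implemented as the Wilson score
interval computed with z = Phi^-1(c), which is the same interval a two-sided
procedure produces at alpha = 2(1 - c); callers consume only the relevant
side.  Per-technology screens use c = 0.95 and the combined-evidence screen
uses c = 0.99 by convention of the benchmark construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint


class CIMethod(enum.Enum):
    """Interval family used for the score bounds."""

    WILSON = "wilson"
    AGRESTI_COULL = "agresti_coull"


@dataclass(frozen=True)
class ConfidenceBound:
    """Point estimate and one-sided lower/upper bounds for a proportion.

    ``level`` is the one-sided confidence coefficient; both bounds are
    reported, each valid one-sided at that coefficient.
    """

    point: float
    lower: float
    upper: float
    level: float
    method: CIMethod = CIMethod.WILSON

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point + 1e-12 and self.point <= self.upper + 1e-12 and self.upper <= 1.0):
            raise ValueError(
                f"bounds must satisfy 0 <= lower <= point <= upper <= 1, "
                f"got lower={self.lower}, point={self.point}, upper={self.upper}"
            )


@dataclass(frozen=True)
class CombinedCounts:
    """Alt-supporting reads and total reads pooled across technologies."""

    x_ci: int
    n_ci: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_ci <= self.n_ci):
            raise ValueError(f"need 0 <= x_ci <= n_ci, got x_ci={self.x_ci}, n_ci={self.n_ci}")

    @property
    def point(self) -> float:
        return self.x_ci / self.n_ci if self.n_ci else float("nan")


def _validate_level(level: float) -> None:
    if not 0.5 < level < 1.0:
        raise ValueError(f"one-sided confidence coefficient must be in (0.5, 1), got {level}")


def wilson_bound(
    x: int,
    n: int,
    level: float = 0.95,
    method: CIMethod = CIMethod.WILSON,
) -> ConfidenceBound:
    """Score bounds on a binomial proportion at a one-sided coefficient.

    Parameters
    ----------
    x, n
        Successes (alt reads) and trials (total reads); ``n`` must be >= 1.
    level
        One-sided confidence coefficient in (0.5, 1).
    method
        ``WILSON`` (score interval, the default) or ``AGRESTI_COULL``
        (adjusted-Wald variant of the score interval).

    Returns
    -------
    ConfidenceBound
        point = x/n with lower/upper bounds, each one-sided at ``level``.
    """
    if n < 1:
        raise ValueError("n must be >= 1: proportion undefined for zero trials")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    _validate_level(level)
    alpha = 2.0 * (1.0 - level)
    lo, hi = proportion_confint(x, n, alpha=alpha, method=method.value)
    lo = float(min(max(lo, 0.0), 1.0))
    hi = float(min(max(hi, 0.0), 1.0))
    return ConfidenceBound(point=x / n, lower=lo, upper=hi, level=level, method=method)


def wilson_bounds_vector(
    x: np.ndarray, n: np.ndarray, level: float, method: CIMethod = CIMethod.WILSON
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lower/upper score bounds; zero-depth entries yield NaN."""
    _validate_level(level)
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    ok = n > 0
    lo = np.full(x.shape, np.nan)
    hi = np.full(x.shape, np.nan)
    if ok.any():
        l, h = proportion_confint(x[ok], n[ok], alpha=2.0 * (1.0 - level), method=method.value)
        lo[ok] = np.clip(l, 0.0, 1.0)
        hi[ok] = np.clip(h, 0.0, 1.0)
    return lo, hi


def combine_counts(supports: Iterable, include: Sequence | None = None) -> CombinedCounts:
    """Pool alt and total read counts across the included technologies.

    ``supports`` is an iterable of objects with ``technology``, ``alt_count``
    and ``depth`` attributes (see :class:`mosaicbench.io.TechReadSupport`).
    ``include`` restricts pooling to a technology subset; ``None`` pools all.
    """
    supports = list(supports)
    if include is not None:
        include_set = set(include)
        if not include_set:
            raise ValueError("empty technology subset: nothing to combine")
        supports = [s for s in supports if s.technology in include_set]
    if not supports:
        raise ValueError("no read support left after technology subsetting")
    x = int(sum(s.alt_count for s in supports))
    n = int(sum(s.depth for s in supports))
    return CombinedCounts(x_ci=x, n_ci=n)
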