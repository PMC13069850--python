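"""In-silico two-sample mixtures and limit-of-detection analysis.

Mixing a variant-carrier sample A into a background sample B at fraction f
dilutes a heterozygous A-specific variant to an expected allele fraction
f/2 (f for a homozygous one).  The canonical design ladder mixes the carrier
at fractions 1.0, 0.5, 0.2, 0.1, 0.02 and 0, giving expected AFs of 50%,
25%, 10%, 5%, 1% and 0%.

The original experiment built such mixtures from real reads and ran a
somatic caller; here the experiment is reproduced at the read-count level: a
per-variant depth is drawn, alt reads are sampled binomially at the expected
AF under a uniform sequencing-error model, and a pluggable detector stands
in for the caller.  Recall per design point gives the LOD curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ci import CIMethod, wilson_bounds_vector

#: carrier fractions of the standard mixture ladder
DEFAULT_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.02, 0.0)


def expected_af(fraction_a: float, genotype: str = "het") -> float:
    """Expected allele fraction of an A-specific variant at carrier fraction f.

    ``genotype`` is "het" (AF = f/2) or "hom" (AF = f).
    """
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError(f"carrier fraction must be in [0, 1], got {fraction_a}")
    if genotype == "het":
        return fraction_a / 2.0
    if genotype == "hom":
        return fraction_a
    raise ValueError(f"genotype must be 'het' or 'hom', got {genotype!r}")


@dataclass(frozen=True)
class MixtureDesign:
    """One mixture point: carrier fraction and its expected het AF."""

    fraction_a: float
    genotype: str = "het"

    def __post_init__(self) -> None:
        expected_af(self.fraction_a, self.genotype)  # validates

    @property
    def fraction_b(self) -> float:
        return 1.0 - self.fraction_a

    @property
    def af(self) -> float:
        return expected_af(self.fraction_a, self.genotype)


def default_designs() -> list[MixtureDesign]:
    return [MixtureDesign(f) for f in DEFAULT_FRACTIONS]


def simulate_mixture_counts(
    n_variants: int,
    mean_depth: float,
    fraction_a: float,
    error_rate: float = 1e-3,
    seed: int | None = None,
    genotype: str = "het",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-variant (alt, depth) counts for one mixture point.

    Depth ~ Poisson(mean_depth); alt ~ Binomial(depth, p) with
    p = af * (1 - e) + (1 - af) * e/3: a true alt read is miscalled with
    probability e, and a ref read is miscalled to the specific alt base with
    probability e/3 (uniform error channel).
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    af = expected_af(fraction_a, genotype)
    p = af * (1.0 - error_rate) + (1.0 - af) * error_rate / 3.0
    depth = rng.poisson(mean_depth, size=n_variants)
    alt = rng.binomial(depth, p)
    return alt, depth


def threshold_detector(
    alt: np.ndarray,
    depth: np.ndarray,
    min_alt: int = 5,
    lower_bound_min: float = 0.01,
    level: float = 0.95,
) -> np.ndarray:
    """Generic caller stand-in: detect when alt >= min_alt and the one-sided
    Wilson lower bound on the VAF exceeds ``lower_bound_min``."""
    lo, _ = wilson_bounds_vector(np.asarray(alt), np.asarray(depth), level, CIMethod.WILSON)
    with np.errstate(invalid="ignore"):
        return (np.asarray(alt) >= min_alt) & (lo > lower_bound_min)


def detection_power(
    mean_depth: float,
    af: float,
    min_alt: int = 5,
    lower_bound_min: float = 0.01,
    level: float = 0.95,
    error_rate: float = 1e-3,
    max_depth_sd: float = 8.0,
) -> float:
    """Analytic detection probability of :func:`threshold_detector`.

    Marginalizes the Poisson depth over +-``max_depth_sd`` standard
    deviations and, for each depth, finds the smallest alt count the detector
    accepts (the rule is monotone in alt at fixed depth), accumulating
    binomial tail mass.  Serves as the independent oracle for simulated
    recall.
    """
    p = af * (1.0 - error_rate) + (1.0 - af) * error_rate / 3.0
    sd = np.sqrt(mean_depth)
    depths = np.arange(
        max(1, int(mean_depth - max_depth_sd * sd)), int(mean_depth + max_depth_sd * sd) + 1
    )
    d_weights = stats.poisson.pmf(depths, mean_depth)
    power = 0.0
    for d, w in zip(depths, d_weights):
        alts = np.arange(min_alt, d + 1)
        if alts.size == 0:
            continue
        det = threshold_detector(alts, np.full(alts.shape, d), min_alt, lower_bound_min, level)
        if not det.any():
            continue
        x_min = alts[det.argmax()]  # smallest accepted alt count
        power += w * stats.binom.sf(x_min - 1, d, p)
    return float(power)


@dataclass
class LODCurve:
    """Recall per expected allele fraction."""

    table: pd.DataFrame  # columns: expected_af, n_truth, n_detected, recall

    def recall_at(self, af: float) -> float:
        row = self.table.loc[np.isclose(self.table["expected_af"], af)]
        if row.empty:
            raise KeyError(f"no design point at AF {af}")
        return float(row["recall"].iloc[0])


def recall_by_af(detections: Sequence[tuple[MixtureDesign, int, int]]) -> LODCurve:
    """Assemble an LOD curve from (design, n_truth, n_detected) rows.

    Recall is n_detected / n_truth; rows with zero truth variants get NaN
    recall and are flagged in the ``defined`` column.  Monotonicity in AF is
    reported, never enforced.
    """
    rows = []
    for design, n_truth, n_detected in detections:
        if n_truth == 0:
            rows.append((design.af, 0, 0, float("nan"), False))
        else:
            rows.append((design.af, n_truth, n_detected, n_detected / n_truth, True))
    table = pd.DataFrame(rows, columns=["expected_af", "n_truth", "n_detected", "recall", "defined"])
    return LODCurve(table=table.sort_values("expected_af", ascending=False, ignore_index=True))


def run_lod(
    designs: Sequence[MixtureDesign] | None = None,
    n_variants: int = 2000,
    mean_depth: float = 300.0,
    error_rate: float = 1e-3,
    seed: int = 0,
    detector: Callable[[np.ndarray, np.ndarray], np.ndarray] = threshold_detector,
) -> LODCurve:
    """Simulate every design point and return the LOD curve.

    Each design gets an independent substream of ``seed`` so adding or
    reordering design points does not perturb the others.
    """
    designs = list(designs) if designs is not None else default_designs()
    rows = []
    for i, design in enumerate(designs):
        alt, depth = simulate_mixture_counts(
            n_variants, mean_depth, design.fraction_a, error_rate,
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31),
            genotype=design.genotype,
        )
        detected = int(detector(alt, depth).sum())
        rows.append((design, n_variants, detected))
    return recall_by_af(rows)
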