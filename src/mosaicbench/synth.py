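"""Synthetic evidence databases with known ground truth.

Emulates the study conditions of the benchmark construction on a toy genome
so every pipeline stage can be exercised without any sequencing data:

* three variant classes — true mosaics (VAF 5-30%), low-fraction variants
  (VAF < 2%, which the pipeline must confidently ignore), and mapping
  artifacts (alt support inflated in exactly one short-read technology and
  absent from long reads, the signature of segmental-duplication mapping
  errors; placed in low-mappability regions);
* per-technology mean depths matching the sequencing datasets used:
  Illumina 300x, BGI 100x, Element 136x (both insert libraries pooled),
  PacBio HiFi 106x (Sequel + Revio pooled); depth is Poisson per variant
  and alt reads are binomial at the true VAF;
* random stratification BEDs (low-mappability, homopolymer, tandem repeat,
  germline indel) with controlled genome densities;
* RM vs non-RM batch count tables with a configurable log-odds VAF shift.

True mosaic VAFs are drawn from a Beta(2, 2) scaled onto [0.05, 0.30]: the
density vanishes at the range edges because variants with true VAFs exactly
at the inclusion boundaries are rare in a curated benchmark whose inclusion
rule demands confident separation from the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Technology, TechReadSupport, VariantEvidence, VariantKey
from .regions import IntervalSet

_ALT_OF = {"A": "C", "C": "T", "G": "A", "T": "G"}
_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the generator."""

    n_mosaic: int = 200
    n_low: int = 200
    n_artifact: int = 50
    mosaic_vaf_range: tuple[float, float] = (0.05, 0.30)
    low_vaf_max: float = 0.02
    tech_depths: dict[str, float] = field(
        default_factory=lambda: {"ILLUMINA": 300.0, "BGI": 100.0, "ELEMENT": 136.0, "HIFI": 106.0}
    )
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000, "chr3": 300_000}
    )
    strat_densities: dict[str, float] = field(
        default_factory=lambda: {
            "low_mappability": 0.10,
            "homopolymer": 0.04,
            "tandem_repeat": 0.04,
            "germline_indel": 0.01,
        }
    )
    batch_shift: float = 0.5  # log-odds drop of non-RM VAFs
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.tech_depths.values()):
            raise ValueError("technology depths must be positive")
        if self.low_vaf_max >= self.mosaic_vaf_range[0]:
            raise ValueError("variant classes must not overlap in VAF")


def generate_strats(
    genome: dict[str, int],
    densities: dict[str, float],
    seed: int,
    mean_len: int = 2_000,
) -> dict[str, IntervalSet]:
    """Random stratification BEDs covering a requested fraction per genome.

    Intervals within one stratification are disjoint by construction: per
    chromosome the covered bases are split into roughly equal intervals whose
    gaps are drawn from a flat Dirichlet, so realized coverage equals the
    requested density up to rounding.
    """
    rng = np.random.default_rng(seed)
    strats: dict[str, IntervalSet] = {}
    for name, density in densities.items():
        if not 0.0 <= density <= 1.0:
            raise ValueError(f"density for {name} must be in [0, 1]")
        tuples = []
        for chrom, length in genome.items():
            covered = int(round(density * length))
            if covered == 0:
                continue
            n_iv = max(1, covered // mean_len)
            iv_len = covered // n_iv
            total_gap = length - iv_len * n_iv
            gaps = rng.dirichlet(np.ones(n_iv + 1)) * total_gap
            pos = 0
            for i in range(n_iv):
                pos += int(gaps[i])
                tuples.append((chrom, pos, pos + iv_len))
                pos += iv_len
        strats[name] = IntervalSet.from_tuples(tuples)
    return strats


def _sample_positions(rng, genome, n, taken, inside: IntervalSet | None = None):
    """Distinct positions, optionally restricted to a region set."""
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    while len(out) < n:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos0 = int(rng.integers(0, genome[chrom]))
        if (chrom, pos0) in taken:
            continue
        if inside is not None and not inside.contains(chrom, pos0):
            continue
        taken.add((chrom, pos0))
        out.append((chrom, pos0))
    return out


def generate_db(
    config: SyntheticConfig, seed: int
) -> tuple[list[VariantEvidence], pd.DataFrame, dict[str, IntervalSet]]:
    """Generate an evidence database with ground truth.

    Returns (evidence records, truth table, stratification sets).  The truth
    table has one row per variant: chrom, pos (1-based), ref, alt, class
    (mosaic/low/artifact), true_vaf, artifact_tech, and stratification
    membership columns.
    """
    rng = np.random.default_rng(seed)
    strats = generate_strats(
        config.genome, config.strat_densities, seed=int(rng.integers(2**31))
    )
    lowmap = strats["low_mappability"]

    classes = (
        ["mosaic"] * config.n_mosaic + ["low"] * config.n_low + ["artifact"] * config.n_artifact
    )
    taken: set[tuple[str, int]] = set()
    positions = (
        _sample_positions(rng, config.genome, config.n_mosaic + config.n_low, taken)
        + _sample_positions(rng, config.genome, config.n_artifact, taken, inside=lowmap)
    )

    lo, hi = config.mosaic_vaf_range
    vafs = np.concatenate([
        lo + (hi - lo) * rng.beta(2.0, 2.0, size=config.n_mosaic),
        rng.uniform(0.0, config.low_vaf_max, size=config.n_low),
        np.zeros(config.n_artifact),
    ])
    short_reads = [t for t in config.tech_depths if t != "HIFI"]
    artifact_techs = rng.choice(short_reads, size=config.n_artifact)
    artifact_fake_vaf = rng.uniform(lo, hi, size=config.n_artifact)

    evidences: list[VariantEvidence] = []
    truth_rows = []
    for i, ((chrom, pos0), cls, vaf) in enumerate(zip(positions, classes, vafs)):
        ref = str(_BASES[rng.integers(4)])
        alt = _ALT_OF[ref]
        key = VariantKey(chrom, pos0 + 1, ref, alt)
        art_tech = artifact_techs[i - config.n_mosaic - config.n_low] if cls == "artifact" else ""
        supports = []
        for tech_name, mean_depth in config.tech_depths.items():
            depth = int(rng.poisson(mean_depth))
            if cls == "artifact":
                p = artifact_fake_vaf[i - config.n_mosaic - config.n_low] if tech_name == art_tech else (
                    0.0 if tech_name == "HIFI" else config.error_rate / 3.0
                )
            else:
                p = vaf * (1 - config.error_rate) + (1 - vaf) * config.error_rate / 3.0
            alt_n = int(rng.binomial(depth, p)) if depth > 0 else 0
            supports.append(
                TechReadSupport(
                    technology=Technology(tech_name),
                    ref_count=depth - alt_n, alt_count=alt_n, depth=depth,
                )
            )
        ill = next(s for s in supports if s.technology is Technology.ILLUMINA)
        evidences.append(
            VariantEvidence(key=key, supports=supports, caller_filter="PASS", tar_depth=ill.alt_count)
        )
        truth_rows.append(
            dict(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, var_class=cls,
                true_vaf=float(vaf), artifact_tech=art_tech,
                in_low_mappability=lowmap.contains(chrom, pos0),
                in_homopolymer=strats["homopolymer"].contains(chrom, pos0),
                in_tandem_repeat=strats["tandem_repeat"].contains(chrom, pos0),
                in_germline_indel=strats["germline_indel"].contains(chrom, pos0),
            )
        )
    return evidences, pd.DataFrame(truth_rows), strats


def generate_batch_counts(
    truth: pd.DataFrame,
    batch_shift: float,
    seed: int,
    platform_depths: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """RM vs non-RM read-count tables for the benchmark (mosaic) variants.

    RM counts are binomial at the variant's true VAF; non-RM counts at the
    VAF shifted down by ``batch_shift`` on the log-odds scale.
    ``platform_depths`` maps platform name to (RM depth, non-RM depth);
    defaults mirror the Element / PacBio Revio coverages used for the
    comparison (81x/100x and 48x/120x).
    """
    if platform_depths is None:
        platform_depths = {"ELEMENT": (81.0, 100.0), "REVIO": (48.0, 120.0)}
    rng = np.random.default_rng(seed)
    mosaic = truth.loc[truth["var_class"] == "mosaic"]
    rows = []
    for _, v in mosaic.iterrows():
        variant_id = f"{v['chrom']}:{v['pos']}{v['ref']}>{v['alt']}"
        logit_vaf = np.log(v["true_vaf"] / (1.0 - v["true_vaf"]))
        for platform, (depth_rm, depth_nonrm) in platform_depths.items():
            for source, depth, shift in (
                ("RM", depth_rm, 0.0), ("NONRM", depth_nonrm, batch_shift)
            ):
                p = 1.0 / (1.0 + np.exp(-(logit_vaf - shift)))
                n = int(rng.poisson(depth))
                alt = int(rng.binomial(n, p)) if n > 0 else 0
                rows.append(
                    dict(variant_id=variant_id, dna_source=source, platform=platform,
                         alt_count=alt, ref_count=n - alt)
                )
    return pd.DataFrame(rows)
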