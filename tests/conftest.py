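import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosaicbench import (
    SyntheticConfig,
    Technology,
    TechReadSupport,
    VariantEvidence,
    VariantKey,
    generate_db,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_evidence(
    counts: dict[Technology, tuple[int, int]],
    chrom: str = "chr1",
    pos: int = 1000,
    **kwargs,
) -> VariantEvidence:
    """Evidence from {technology: (alt, depth)} shorthand."""
    supports = [
        TechReadSupport(technology=t, ref_count=d - a, alt_count=a, depth=d)
        for t, (a, d) in counts.items()
    ]
    return VariantEvidence(key=VariantKey(chrom, pos, "A", "T"), supports=supports, **kwargs)


def random_interval_tuples(rng, n, genome_len=100_000, max_len=2_000, chrom="chr1"):
    starts = rng.integers(0, genome_len - 1, size=n)
    lengths = rng.integers(1, max_len, size=n)
    ends = np.minimum(starts + lengths, genome_len)
    return [(chrom, int(s), int(e)) for s, e in zip(starts, ends) if e > s]


def bool_mask(tuples, genome_len=100_000):
    mask = np.zeros(genome_len, dtype=bool)
    for _, s, e in tuples:
        mask[s:e] = True
    return mask


@pytest.fixture(scope="session")
def small_db():
    """A small synthetic evidence database shared across read-only tests."""
    cfg = SyntheticConfig(n_mosaic=60, n_low=60, n_artifact=20)
    db, truth, strats = generate_db(cfg, seed=42)
    return cfg, db, truth, strats
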