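import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cncc import GenomeBuild, StrandProfile, POSITIVE, NEGATIVE

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def genome() -> GenomeBuild:
    return GenomeBuild({"chr1": 1000, "chr2": 500})


def make_profile(genome: GenomeBuild, strand: str, entries: dict) -> StrandProfile:
    """entries: {chrom: {pos: count}}"""
    p = StrandProfile(strand, genome)
    for chrom, d in entries.items():
        for pos, cnt in d.items():
            p.add(chrom, pos, cnt)
    return p


@pytest.fixture
def profile_factory(genome):
    def factory(strand=POSITIVE, entries=None):
        return make_profile(genome, strand, entries or {})

    return factory


def brute_force_cncc(pos: StrandProfile, neg: StrandProfile, shifts) -> np.ndarray:
    """Independent nested-loop oracle for the cross-correlation statistic."""
    sum_x2 = sum(c * c for d in pos.data.values() for c in d.values())
    sum_y2 = sum(c * c for d in neg.data.values() for c in d.values())
    values = []
    for t in shifts:
        num = 0.0
        for chrom, yd in neg.data.items():
            xd = pos.data.get(chrom, {})
            for i, y in yd.items():
                num += y * xd.get(i - t, 0)
        values.append(num / np.sqrt(sum_x2 * sum_y2))
    return np.array(values)


def free_shuffle(profile: StrandProfile, seed: int) -> StrandProfile:
    """Naive genome-wide free position shuffle (test fixture only: the
    rejected, overly permissive null)."""
    rng = np.random.default_rng(seed)
    out = StrandProfile(profile.strand, profile.genome)
    for chrom in profile.chroms():
        _, cnt = profile.arrays(chrom)
        length = profile.genome.length(chrom)
        new_pos = rng.choice(length, size=len(cnt), replace=False)
        for p, c in zip(new_pos.tolist(), cnt.tolist()):
            out.add(chrom, p, c)
    return out
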