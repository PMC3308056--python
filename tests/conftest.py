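import numpy as np
import pytest

from servic4e.regions import TargetRegion
from servic4e.tally import RegionTallies, TallySet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_position_tally(rng, L=47, density=0.3, max_count=6):
    """A random (counts, qual_sums) pair of shape (4, L, 2).

    Sparse by default; qualities are zero exactly where counts are zero.
    """
    counts = rng.integers(0, max_count + 1, size=(4, L, 2))
    counts[rng.random((4, L, 2)) > density] = 0
    counts = counts.astype(np.uint32)
    per_call_q = rng.uniform(5.0, 40.0, size=(4, L, 2))
    qual_sums = counts * per_call_q
    return counts, qual_sums


def make_region_tallies(
    ref_seq="ACGT" * 10,
    pool_ids=(1, 2, 3),
    read_length=8,
    contig="chrT",
    start=0,
    label="toyregion",
):
    region = TargetRegion(contig, start, start + len(ref_seq), label)
    return RegionTallies(region, list(pool_ids), read_length, ref_seq)


def add_calls(rt, pool_id, position, base, n, qual, cycle=1, strand="+"):
    """Deposit n identical calls into one tally cell."""
    from servic4e.tally import BASE_INDEX, STRAND_INDEX

    p = rt.pool_index[pool_id]
    i = position - rt.region.start
    b = BASE_INDEX[base]
    s = STRAND_INDEX[strand]
    rt.counts[p, i, b, cycle - 1, s] += n
    rt.qual_sums[p, i, b, cycle - 1, s] += n * qual
    rt.invalidate_cache()


def spread_calls(rt, pool_id, position, base, per_cycle, qual, cycles=None,
                 strands=("+", "-")):
    """Deposit per_cycle calls of one base at every (cycle, strand) given."""
    if cycles is None:
        cycles = range(1, rt.read_length + 1)
    for c in cycles:
        for s in strands:
            add_calls(rt, pool_id, position, base, per_cycle, qual, c, s)


@pytest.fixture
def toy_tallyset():
    rt = make_region_tallies()
    return TallySet([rt])
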