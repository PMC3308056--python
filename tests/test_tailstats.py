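"""The four per-candidate statistics against brute-force recomputation."""

import math

import numpy as np
import pytest

from servic4e import tailstats

from conftest import random_position_tally


def brute_continuity(counts, alt):
    L = counts.shape[1]
    return sum(
        1 for c in range(L) if counts[alt, c, 0] + counts[alt, c, 1] > 0
    )


def brute_waf(quals, alt):
    total = float(np.sum(quals))
    return float(np.sum(quals[alt])) / total


def brute_avg_quality(counts, quals, alt):
    return float(np.sum(quals[alt])) / int(np.sum(counts[alt]))


def brute_tailcurve(counts, alt, eps=1.0):
    L = counts.shape[1]
    h = math.ceil(L / 2)
    ratios = {}
    for s in range(2):
        n_alt = int(counts[alt, :, s].sum())
        if n_alt == 0:
            continue
        pe = (counts[alt, :h, s].sum() + eps) / (counts[:, :h, s].sum() + eps)
        pl = (counts[alt, h:, s].sum() + eps) / (counts[:, h:, s].sum() + eps)
        ratios["+-"[s]] = max(pe / pl, pl / pe)
    return ratios


class TestContinuity:
    def test_every_cycle_gives_read_length(self):
        L = 47
        counts = np.zeros((4, L, 2), dtype=np.uint32)
        counts[1, :, 0] = 3
        assert tailstats.continuity(counts, 1) == L

    def test_single_cycle_both_strands_gives_one(self):
        counts = np.zeros((4, 47, 2), dtype=np.uint32)
        counts[2, 11, :] = 5
        assert tailstats.continuity(counts, 2) == 1

    def test_absent_base_warns_and_returns_zero(self):
        counts = np.zeros((4, 47, 2), dtype=np.uint32)
        counts[0, 0, 0] = 1
        with pytest.warns(UserWarning):
            assert tailstats.continuity(counts, 3) == 0


class TestWeightedAlleleFrequency:
    def test_pure_alt_is_one(self):
        quals = np.zeros((4, 10, 2))
        quals[0, 3, 0] = 120.0
        assert tailstats.weighted_allele_frequency(quals, 0) == 1.0

    def test_hand_summation(self):
        quals = np.zeros((4, 10, 2))
        quals[1, 0, 0] = 60.0  # alt
        quals[0, 0, 0] = 540.0
        assert tailstats.weighted_allele_frequency(quals, 1) == pytest.approx(0.1)

    def test_symmetric_two_allele_split(self):
        quals = np.zeros((4, 10, 2))
        quals[0, 2, 0] = 90.0
        quals[2, 5, 1] = 90.0
        assert tailstats.weighted_allele_frequency(quals, 2) == pytest.approx(0.5)

    def test_zero_total_quality_raises(self):
        with pytest.raises(ValueError):
            tailstats.weighted_allele_frequency(np.zeros((4, 10, 2)), 0)


class TestAverageQuality:
    def test_constant_and_singleton_cases(self):
        counts = np.zeros((4, 12, 2), dtype=np.uint32)
        quals = np.zeros((4, 12, 2))
        counts[3, 2, 0] = 3
        quals[3, 2, 0] = 90.0
        assert tailstats.average_quality(counts, quals, 3) == pytest.approx(30.0)
        counts2 = np.zeros((4, 12, 2), dtype=np.uint32)
        quals2 = np.zeros((4, 12, 2))
        counts2[1, 7, 1] = 1
        quals2[1, 7, 1] = 37.0
        assert tailstats.average_quality(counts2, quals2, 1) == pytest.approx(37.0)

    def test_arithmetic_mean_of_mixed_qualities(self):
        counts = np.zeros((4, 12, 2), dtype=np.uint32)
        quals = np.zeros((4, 12, 2))
        for cycle, q in enumerate((10.0, 20.0, 30.0, 40.0)):
            counts[0, cycle, 0] = 1
            quals[0, cycle, 0] = q
        assert tailstats.average_quality(counts, quals, 0) == pytest.approx(25.0)

    def test_zero_calls_raises(self):
        with pytest.raises(ValueError):
            tailstats.average_quality(
                np.zeros((4, 5, 2), dtype=np.uint32), np.zeros((4, 5, 2)), 0
            )


class TestTailcurveRatio:
    def test_uniform_profile_is_one(self):
        counts = np.zeros((4, 46, 2), dtype=np.uint32)
        counts[0] = 20  # reference, everywhere
        counts[1] = 2  # variant, same proportion at every cycle/strand
        assert tailstats.tailcurve_ratio(counts, 1) == pytest.approx(1.0)

    def test_late_cycle_errors_exceed_tenfold(self):
        # variant present only at cycles 30..47 of a 47-cycle run
        counts = np.zeros((4, 47, 2), dtype=np.uint32)
        counts[0] = 50
        counts[1, 29:, 0] = 10
        ratio = tailstats.tailcurve_ratio(counts, 1)
        assert ratio > 10
        assert tailstats.tailcurve_fails(counts, 1, max_ratio=10.0)

    def test_fourfold_proportion_difference(self):
        # large counts so the pseudocount is negligible: p_early 0.04, p_late 0.01
        counts = np.zeros((4, 40, 2), dtype=np.uint32)
        counts[0, :20, :] = 960
        counts[1, :20, :] = 40
        counts[0, 20:, :] = 990
        counts[1, 20:, :] = 10
        assert tailstats.tailcurve_ratio(counts, 1) == pytest.approx(4.0, rel=0.02)

    def test_minimum_strand_calls_gate(self):
        counts = np.zeros((4, 47, 2), dtype=np.uint32)
        counts[0] = 50
        counts[1, 45:, 0] = 2  # 4 late calls on plus: too few to judge alone
        ratio = tailstats.tailcurve_ratio(counts, 1)
        assert ratio > 4
        assert not tailstats.tailcurve_fails(counts, 1, max_ratio=4.0,
                                             min_strand_calls=10)
        assert tailstats.tailcurve_fails(counts, 1, max_ratio=4.0,
                                         min_strand_calls=1)


@pytest.mark.parametrize("trial", range(4))
def test_statistics_match_brute_force_on_random_tallies(trial):
    """All four statistics agree with definitional loops on random tallies."""
    rng = np.random.default_rng(1000 + trial)
    for _ in range(250):
        L = int(rng.integers(4, 60))
        counts, quals = random_position_tally(rng, L=L)
        present = [b for b in range(4) if counts[b].sum() > 0]
        if not present:
            continue
        alt = present[int(rng.integers(len(present)))]
        assert tailstats.continuity(counts, alt) == brute_continuity(counts, alt)
        assert tailstats.weighted_allele_frequency(quals, alt) == pytest.approx(
            brute_waf(quals, alt)
        )
        assert tailstats.average_quality(counts, quals, alt) == pytest.approx(
            brute_avg_quality(counts, quals, alt)
        )
        expected = brute_tailcurve(counts, alt)
        got = tailstats.strand_tailcurve_ratios(counts, alt)
        assert set(got) == set(expected)
        for s in expected:
            assert got[s][0] == pytest.approx(expected[s])
        assert tailstats.tailcurve_ratio(counts, alt) == pytest.approx(
            max(expected.values())
        )


def test_invariants_on_random_tallies(rng):
    """Bounds and symmetries: 0<w<=1, 1<=C<=L, T>=1, quality scaling,
    strand-swap invariance, continuity monotone in added calls."""
    for _ in range(200):
        counts, quals = random_position_tally(rng, L=20)
        present = [b for b in range(4) if counts[b].sum() > 0]
        if not present:
            continue
        alt = present[0]
        w = tailstats.weighted_allele_frequency(quals, alt)
        c = tailstats.continuity(counts, alt)
        t = tailstats.tailcurve_ratio(counts, alt)
        assert 0 < w <= 1
        assert 1 <= c <= 20
        assert t >= 1
        # scaling all qualities leaves w unchanged, scales avg quality
        q = tailstats.average_quality(counts, quals, alt)
        assert tailstats.weighted_allele_frequency(quals * 3.0, alt) == pytest.approx(w)
        assert tailstats.average_quality(counts, quals * 3.0, alt) == pytest.approx(3 * q)
        # swapping strand labels leaves the max-over-strands ratio unchanged
        swapped = counts[:, :, ::-1]
        assert tailstats.tailcurve_ratio(swapped, alt) == pytest.approx(t)
        # adding variant calls never lowers continuity
        more = counts.copy()
        more[alt, int(np.argmin(more[alt].sum(axis=1))), 0] += 1
        assert tailstats.continuity(more, alt) >= c
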