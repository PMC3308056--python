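"""Local error-pattern model: cross-pool filtering by recurring mismatch
combinations in the sequence surrounding a candidate site.

Systematic errors (library preparation, chemistry, sequence context) tend to
recur at adjacent positions and in the same subset of pools.  For a candidate
site, the +/- ``flank`` positions around it (the site itself excluded) are
scanned for the combination of pools showing high mismatch rates; the modal
combination, if it occurs at two or more positions, is the local error
pattern.  A candidate whose positive-pool set is too similar to that pattern
(Jaccard index at or above ``j_min``) is eliminated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .tally import RegionTallies


@dataclass
class LocalWindowProfile:
    """Mismatch-rate window around one candidate position.

    ``rates[p, j]`` is the WAF of the most prominent non-reference allele in
    pool ``pool_ids[p]`` at ``positions[j]`` (NaN where no coverage).
    """

    contig: str
    center: int
    positions: np.ndarray  # absolute 0-based positions, center included
    pool_ids: list[int]
    rates: np.ndarray  # (n_pools, n_positions)

    @property
    def center_index(self) -> int:
        return int(np.flatnonzero(self.positions == self.center)[0])


@dataclass(frozen=True)
class PoolPattern:
    """The modal combination of high-mismatch pools near a site."""

    pools: frozenset[int]
    support: int  # number of window positions exhibiting the combination


def local_profile(
    region_tallies: RegionTallies, position: int, flank: int = 15
) -> LocalWindowProfile:
    """Mismatch rates for every pool at ``position +/- flank``, truncated at
    region edges."""
    region = region_tallies.region
    if not region.contains(position):
        raise ValueError(f"{position} outside region {region.label}")
    lo = max(region.start, position - flank)
    hi = min(region.end, position + flank + 1)
    w, _ = region_tallies.mismatch_rates()
    sl = slice(lo - region.start, hi - region.start)
    return LocalWindowProfile(
        contig=region.contig,
        center=position,
        positions=np.arange(lo, hi),
        pool_ids=list(region_tallies.pool_ids),
        rates=w[:, sl],
    )


def dominant_pattern(
    profile: LocalWindowProfile, high_threshold: float
) -> PoolPattern | None:
    """Most frequent non-empty combination of pools with mismatch rate at or
    above ``high_threshold`` across the window (center excluded).

    Requires support at a minimum of two positions; ties are broken towards
    the combination with the smallest sorted pool tuple, for determinism.
    """
    combos: Counter[frozenset[int]] = Counter()
    ci = profile.center_index
    for j in range(profile.rates.shape[1]):
        if j == ci:
            continue
        col = profile.rates[:, j]
        pools = frozenset(
            profile.pool_ids[p]
            for p in np.flatnonzero(~np.isnan(col) & (col >= high_threshold))
        )
        if pools:
            combos[pools] += 1
    if not combos:
        return None
    best = min(combos.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    pools, support = best
    if support < 2:  # a pattern must recur at multiple positions
        return None
    return PoolPattern(pools=pools, support=support)


def jaccard(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    if not a and not b:
        return 0.0
    return len(set(a) & set(b)) / len(set(a) | set(b))


def pattern_filter(
    candidate_pools: set[int],
    pattern: PoolPattern | None,
    j_min: float = 0.5,
) -> bool:
    """True = keep the candidate, False = drop it.

    Drops only when a local pattern exists and the candidate's positive-pool
    combination matches it with Jaccard index >= ``j_min``; with no pattern
    (or flank 0) everything is kept, so the cascade degrades gracefully.
    """
    if pattern is None or not candidate_pools:
        return True
    return jaccard(candidate_pools, pattern.pools) < j_min
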