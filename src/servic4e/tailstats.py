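"""The four per-candidate statistics computed from cycle/strand tallies.

Every statistic is a pure function of one position's tally in one pool: two
arrays of shape ``(4, L, 2)`` (base x sequencing cycle x strand) holding call
counts and summed Phred qualities, plus the index of the variant (alternate)
base.  Strand index 0 is '+', 1 is '-'.

* continuity        - number of cycles (out of L) at which the variant base
                      is observed on either strand; true alleles sampled by
                      random fragmentation appear at many cycles, artifacts
                      cluster at few.
* weighted allele frequency (WAF)
                    - Phred-weighted fraction of calls supporting the variant:
                      sum of variant-call qualities over sum of all qualities.
* average quality   - mean Phred score of the variant-supporting calls.
* tailcurve ratio   - strand-specific fold-change of the variant proportion
                      between the first and second half of sequencing cycles;
                      cycle-dependent errors concentrate in late cycles and
                      produce large ratios.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

#: strand axis labels, index 0 / 1
STRANDS = ("+", "-")


def continuity(counts: np.ndarray, alt: int) -> int:
    """Number of cycles at which the variant base is called (either strand).

    Returns 0 with a warning when the variant base has no calls at all (such
    a candidate should not have been enumerated).
    """
    per_cycle = counts[alt].sum(axis=1)
    c = int(np.count_nonzero(per_cycle))
    if c == 0:
        warnings.warn("continuity of an absent variant base is 0", stacklevel=2)
    return c


def weighted_allele_frequency(qual_sums: np.ndarray, alt: int) -> float:
    """Phred-weighted allele frequency: sum(Q_variant) / sum(Q_all)."""
    total = float(qual_sums.sum())
    if total <= 0:
        raise ValueError("no usable coverage: total quality sum is zero")
    return float(qual_sums[alt].sum()) / total


def average_quality(counts: np.ndarray, qual_sums: np.ndarray, alt: int) -> float:
    """Mean Phred quality of the variant-supporting calls."""
    n = int(counts[alt].sum())
    if n == 0:
        raise ValueError("average quality undefined: variant base has no calls")
    return float(qual_sums[alt].sum()) / n


def tailcurve_profile(counts: np.ndarray, alt: int) -> np.ndarray:
    """Per-strand, per-cycle proportion of calls equal to the variant base.

    Returns an array of shape ``(2, L)`` (strand x cycle); cycles with zero
    coverage on a strand are NaN.
    """
    cov = counts.sum(axis=0).astype(float).T  # (2, L)
    var = counts[alt].astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(cov > 0, var / np.where(cov > 0, cov, 1.0), np.nan)
    return prop


def _half_split(L: int) -> int:
    # first half = cycles 1..ceil(L/2)
    return math.ceil(L / 2)


def strand_tailcurve_ratios(
    counts: np.ndarray, alt: int, pseudocount: float = 1.0
) -> dict[str, tuple[float, int]]:
    """Tailcurve ratio and variant-call count for each strand with >= 1 call.

    For strand s, with h = ceil(L/2):
      p_early = (variant calls in cycles 1..h   + eps) / (all calls 1..h   + eps)
      p_late  = (variant calls in cycles h+1..L + eps) / (all calls h+1..L + eps)
      ratio   = max(p_early / p_late, p_late / p_early)   >= 1

    The pseudocount keeps the ratio defined when one half has no coverage.
    Returns ``{strand: (ratio, n_variant_calls_on_strand)}``.
    """
    L = counts.shape[1]
    h = _half_split(L)
    out: dict[str, tuple[float, int]] = {}
    for s, name in enumerate(STRANDS):
        n_alt = int(counts[alt, :, s].sum())
        if n_alt == 0:
            continue
        ne = float(counts[alt, :h, s].sum())
        nl = float(counts[alt, h:, s].sum())
        de = float(counts[:, :h, s].sum())
        dl = float(counts[:, h:, s].sum())
        pe = (ne + pseudocount) / (de + pseudocount)
        pl = (nl + pseudocount) / (dl + pseudocount)
        out[name] = (max(pe / pl, pl / pe), n_alt)
    return out


def tailcurve_ratio(counts: np.ndarray, alt: int, pseudocount: float = 1.0) -> float:
    """Maximum tailcurve ratio over strands carrying >= 1 variant call.

    Returns 1.0 (neutral) when the variant base has no calls on either strand.
    """
    ratios = strand_tailcurve_ratios(counts, alt, pseudocount)
    if not ratios:
        return 1.0
    return max(r for r, _ in ratios.values())


def tailcurve_fails(
    counts: np.ndarray,
    alt: int,
    max_ratio: float = 10.0,
    min_strand_calls: int = 10,
    pseudocount: float = 1.0,
) -> bool:
    """Ten-fold rule: does any adequately covered strand exceed ``max_ratio``?

    The test is applied per strand; a strand contributes only when it carries
    at least ``min_strand_calls`` variant calls (fewer calls give too noisy a
    proportion to judge alone).
    """
    for ratio, n_alt in strand_tailcurve_ratios(counts, alt, pseudocount).values():
        if n_alt >= min_strand_calls and ratio > max_ratio:
            return True
    return False
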