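"""Diagnostic plots: tailcurve profiles and the filtering funnel.

matplotlib is imported lazily so the core pipeline has no plotting
dependency at run time.
"""

from __future__ import annotations

import numpy as np

from . import tailstats
from .cascade import FilterReport
from .tally import BASE_INDEX, PositionTally


def plot_tailcurve(pt: PositionTally, alt_base: str, ax=None):
    """Per-cycle variant proportion for each strand at one position/pool."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    prop = tailstats.tailcurve_profile(pt.counts, BASE_INDEX[alt_base])
    cycles = np.arange(1, prop.shape[1] + 1)
    for s, (row, style) in enumerate(zip(prop, ("-", "--"))):
        ax.plot(cycles, row, style, label=f"strand {tailstats.STRANDS[s]}")
    ax.axvline(prop.shape[1] / 2, color="grey", lw=0.5)
    ax.set_xlabel("sequencing cycle")
    ax.set_ylabel(f"proportion of {alt_base} calls")
    ax.set_title(f"{pt.contig}:{pt.position + 1} pool {pt.pool_id}")
    ax.legend()
    return ax


def plot_funnel(report: FilterReport, ax=None):
    """Retained variant-pool counts across the cascade stages."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts = report.counts()
    ax.bar(range(len(counts)), list(counts.values()))
    ax.set_xticks(range(len(counts)))
    ax.set_xticklabels(list(counts), rotation=30, ha="right")
    ax.set_ylabel("retained variant-pools")
    return ax
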