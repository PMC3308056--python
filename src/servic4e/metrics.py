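"""Validation arithmetic on a variant-pool basis.

The unit of detection is the variant-pool: one (site, pool) hypothesis.  A
truth set enumerates the evaluable universe - variant-pools confirmed
positive and those assayed and confirmed negative.  Calls are compared
against that universe; calls at variant-pools never assayed are reported
separately as *unevaluable* rather than counted as false positives, since
nothing is known about them.

Eight derived statistics are reported as percentages: sensitivity,
specificity, PPV, NPV, accuracy, FPR, FDR and the Matthews correlation
coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which balances all four confusion counts and is the headline comparison
statistic between calling methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

VariantPool = tuple[str, int, str, int]  # contig, 0-based pos, alt, pool


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


def confusion(
    calls: Iterable[VariantPool],
    truth_positive: Iterable[VariantPool],
    truth_negative: Iterable[VariantPool],
) -> tuple[ConfusionCounts, set[VariantPool]]:
    """Compare calls against the evaluable truth universe.

    Returns the confusion counts and the set of unevaluable calls (outside
    the universe).
    """
    calls = set(calls)
    pos = set(truth_positive)
    neg = set(truth_negative)
    overlap = pos & neg
    if overlap:
        raise ValueError(f"{len(overlap)} variant-pools are both + and - in truth")
    return (
        ConfusionCounts(
            tp=len(calls & pos),
            tn=len(neg - calls),
            fp=len(calls & neg),
            fn=len(pos - calls),
        ),
        calls - pos - neg,
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the eight derived rates, in percent.

    A statistic whose denominator is zero is reported as 0.0 and listed in
    ``undefined`` (the MCC zero-denominator convention).
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    fpr: float
    fdr: float
    mcc: float
    undefined: frozenset[str] = frozenset()

    _PERCENT_FIELDS = (
        "sensitivity", "specificity", "ppv", "npv",
        "accuracy", "fpr", "fdr", "mcc",
    )

    def rounded(self, places: int = 2) -> dict[str, float]:
        """Percentages rounded half-up to ``places`` decimals (as printed)."""
        return {
            name: round_half_up(getattr(self, name), places)
            for name in self._PERCENT_FIELDS
        }


def round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def derive(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """All eight statistics from the four confusion counts."""
    counts = ConfusionCounts(tp, tn, fp, fn)
    undefined: set[str] = set()

    def rate(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return 100.0 * num / den

    sensitivity = rate(tp, tp + fn, "sensitivity")
    specificity = rate(tn, fp + tn, "specificity")
    ppv = rate(tp, tp + fp, "ppv")
    npv = rate(tn, tn + fn, "npv")
    accuracy = rate(tp + tn, tp + tn + fp + fn, "accuracy")
    fpr = rate(fp, fp + tn, "fpr")
    fdr = rate(fp, fp + tp, "fdr")

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.add("mcc")
        mcc = 0.0
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(denom)

    return ConfusionMetrics(
        counts=counts,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        fpr=fpr,
        fdr=fdr,
        mcc=mcc,
        undefined=frozenset(undefined),
    )


# ---------------------------------------------------------------------------
# Truth TSV and report output
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["contig", "pos", "ref", "alt", "pool", "status"]


def read_truth_tsv(
    path: str | Path,
) -> tuple[set[VariantPool], set[VariantPool]]:
    """Read an assayed-truth TSV: contig, pos (0-based), ref, alt, pool,
    status ('+' positive / '-' negative).  Returns (positives, negatives)."""
    df = pd.read_csv(path, sep="\t", dtype={"status": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth TSV missing columns: {sorted(missing)}")
    pos: set[VariantPool] = set()
    neg: set[VariantPool] = set()
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.pos), row.alt, int(row.pool))
        if row.status == "+":
            pos.add(key)
        elif row.status == "-":
            neg.add(key)
        else:
            raise ValueError(f"truth status must be + or -, got {row.status!r}")
    return pos, neg


def metrics_to_tsv(
    m: ConfusionMetrics, path: str | Path, unevaluable: int = 0
) -> None:
    rows = [
        ("TP", m.counts.tp), ("TN", m.counts.tn),
        ("FP", m.counts.fp), ("FN", m.counts.fn),
        ("unevaluable", unevaluable),
    ] + [(k, v) for k, v in m.rounded().items()]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        path, sep="\t", index=False
    )
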