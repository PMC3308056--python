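"""Target regions for amplicon resequencing.

Regions are 0-based half-open intervals on a reference contig, typically one
interval per PCR amplicon (a few hundred bp each).  They are consumed as BED
and merged per contig so that downstream tallies never double-count a base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True, order=True)
class TargetRegion:
    """A 0-based half-open target interval (one amplicon)."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read target regions from a BED3/BED4+ file.

    Only the first four columns are used (contig, start, end, name).  Track
    and comment lines are skipped.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else f"{contig}:{start}-{end}"
            regions.append(TargetRegion(contig, start, end, label))
    return regions


def write_bed(regions: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\n")


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping/adjacent regions within each contig.

    Labels of merged intervals are joined with '+'.  The result is sorted and
    pairwise non-overlapping, the invariant the tally builder relies on.
    """
    merged: list[TargetRegion] = []
    for r in sorted(regions):
        if merged and r.contig == merged[-1].contig and r.start <= merged[-1].end:
            last = merged[-1]
            label = last.label if r.label == last.label else f"{last.label}+{r.label}"
            merged[-1] = replace(last, end=max(last.end, r.end), label=label)
        else:
            merged.append(r)
    return merged
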