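"""Per-position cycle/strand tallies and candidate variant-pool enumeration.

A :class:`RegionTallies` holds, for one target region, dense arrays of base
call counts and Phred-quality sums indexed by
``(pool, position, base, cycle, strand)``.  The cycle of a call is its 1-based
index in the read *as sequenced*: for a minus-strand alignment the aligned
query offset is reflected (``cycle = L - offset``) so that "late cycles"
always means late in sequencing chemistry, where cycle-dependent errors live.

Tallies are built from sorted, indexed BAM files (one per pool, listed in a
two-column manifest), or injected directly by the simulator, or exchanged as
a plain TSV dump for debugging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .regions import TargetRegion, merge_regions
from . import tailstats

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STRAND_INDEX = {"+": 0, "-": 1}


@dataclass
class PositionTally:
    """One position in one pool: counts/qual_sums of shape (4, L, 2)."""

    contig: str
    position: int
    pool_id: int
    ref_base: str
    counts: np.ndarray
    qual_sums: np.ndarray

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())

    @property
    def read_length(self) -> int:
        return self.counts.shape[1]


class RegionTallies:
    """Dense cycle/strand tallies for every pool over one target region."""

    def __init__(
        self,
        region: TargetRegion,
        pool_ids: Sequence[int],
        read_length: int,
        ref_seq: str,
    ) -> None:
        if len(ref_seq) != len(region):
            raise ValueError(
                f"reference for {region.label} has length {len(ref_seq)}, "
                f"region spans {len(region)}"
            )
        self.region = region
        self.pool_ids = list(pool_ids)
        self.pool_index = {p: i for i, p in enumerate(self.pool_ids)}
        self.read_length = int(read_length)
        self.ref_seq = ref_seq.upper()
        self.ref_idx = np.array(
            [BASE_INDEX.get(b, 0) for b in self.ref_seq], dtype=np.int8
        )
        shape = (len(self.pool_ids), len(region), 4, self.read_length, 2)
        self.counts = np.zeros(shape, dtype=np.uint32)
        self.qual_sums = np.zeros(shape, dtype=np.float32)
        self._mismatch_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- accessors ---------------------------------------------------------

    def position_tally(self, pool_id: int, position: int) -> PositionTally:
        i = position - self.region.start
        if not 0 <= i < len(self.region):
            raise IndexError(f"position {position} outside {self.region.label}")
        p = self.pool_index[pool_id]
        return PositionTally(
            contig=self.region.contig,
            position=position,
            pool_id=pool_id,
            ref_base=self.ref_seq[i],
            counts=self.counts[p, i],
            qual_sums=self.qual_sums[p, i],
        )

    def base_qual_sums(self) -> np.ndarray:
        """Quality sums per (pool, position, base), summed over cycle/strand."""
        return self.qual_sums.sum(axis=(3, 4), dtype=np.float64)

    def invalidate_cache(self) -> None:
        self._mismatch_cache = None

    def mismatch_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Weighted allele frequency of the most prominent non-reference
        allele at every (pool, position), and that allele's base index.

        Positions with zero quality are NaN.  This is the "mismatch rate"
        profile the local error-pattern model inspects.
        """
        if self._mismatch_cache is None:
            qs = self.base_qual_sums()  # (P, n, 4)
            total = qs.sum(axis=2)
            masked = qs.copy()
            idx = np.arange(len(self.region))
            masked[:, idx, self.ref_idx] = -1.0  # exclude reference base
            alt = masked.argmax(axis=2)
            alt_qs = np.take_along_axis(qs, alt[:, :, None], axis=2)[:, :, 0]
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(total > 0, alt_qs / np.where(total > 0, total, 1.0), np.nan)
            self._mismatch_cache = (w, alt)
        return self._mismatch_cache


class TallySet:
    """All region tallies for one dataset (one cohort of pools)."""

    def __init__(self, regions: Iterable[RegionTallies]) -> None:
        self.regions = {rt.region.label: rt for rt in regions}
        if not self.regions:
            raise ValueError("TallySet requires at least one region")
        first = next(iter(self.regions.values()))
        self.pool_ids = first.pool_ids
        self.read_length = first.read_length
        for rt in self.regions.values():
            if rt.pool_ids != self.pool_ids or rt.read_length != self.read_length:
                raise ValueError("all regions must share pool ids and read length")

    def __iter__(self) -> Iterator[RegionTallies]:
        return iter(self.regions.values())

    def region_for(self, contig: str, position: int) -> RegionTallies:
        for rt in self.regions.values():
            if rt.region.contig == contig and rt.region.contains(position):
                return rt
        raise KeyError(f"{contig}:{position} is not inside any target region")


@dataclass
class CandidateVariantPool:
    """A (position, pool, alternate allele) hypothesis with its statistics."""

    contig: str
    position: int  # 0-based
    region_label: str
    pool_id: int
    ref_base: str
    alt_base: str
    continuity: int
    waf: float
    avg_quality: float
    tailcurve: float
    strand_tailcurves: dict[str, tuple[float, int]] = field(default_factory=dict)
    coverage: int = 0
    alt_count: int = 0

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.alt_base)

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.contig, self.position, self.alt_base, self.pool_id)


# ---------------------------------------------------------------------------
# BAM ingestion
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[tuple[int, str]]:
    """Read a pool manifest: two tab-separated columns, pool_id and BAM path."""
    out: list[tuple[int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pool, bam = line.split("\t")[:2]
            out.append((int(pool), bam))
    if not out:
        raise ValueError(f"manifest {path} lists no pools")
    return out


def build_tallies(
    alignments_per_pool: Sequence[tuple[int, str]],
    regions: Sequence[TargetRegion],
    read_length: int,
    reference: str | Path,
) -> TallySet:
    """Ingest per-pool sorted BAMs over target regions into cycle/strand tallies.

    Soft-clipped bases, deletions and reference skips contribute nothing;
    ambiguous (N) calls are dropped.  A read longer than ``read_length`` is an
    error because its cycle axis would be undefined.
    """
    import pysam

    regions = merge_regions(regions)
    pool_ids = [p for p, _ in alignments_per_pool]
    with pysam.FastaFile(str(reference)) as fa:
        tallies = [
            RegionTallies(
                r, pool_ids, read_length, fa.fetch(r.contig, r.start, r.end)
            )
            for r in regions
        ]

    for pool_id, bam_path in alignments_per_pool:
        if not Path(bam_path).exists():
            raise FileNotFoundError(f"pool {pool_id}: missing BAM {bam_path}")
        try:
            af = pysam.AlignmentFile(str(bam_path))
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"pool {pool_id}: cannot open {bam_path}: {exc}")
        with af:
            if not af.has_index():
                raise FileNotFoundError(
                    f"pool {pool_id}: {bam_path} has no index (.bai)"
                )
            for rt in tallies:
                p = rt.pool_index[pool_id]
                for read in af.fetch(
                    rt.region.contig, rt.region.start, rt.region.end
                ):
                    _tally_read(rt, p, read, bam_path)
    for rt in tallies:
        rt.invalidate_cache()
    return TallySet(tallies)


def _tally_read(rt: RegionTallies, p: int, read, bam_path: str) -> None:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return
    L = rt.read_length
    qlen = read.query_length or len(read.query_sequence or "")
    if qlen > L:
        raise ValueError(
            f"{bam_path}: read {read.query_name} has {qlen} bases but the "
            f"declared read length is {L}; cycle axis undefined"
        )
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        raise ValueError(f"{bam_path}: read {read.query_name} lacks bases/qualities")
    start, end = rt.region.start, rt.region.end
    strand = 1 if read.is_reverse else 0
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos is None or not start <= rpos < end:
            continue
        base = seq[qpos]
        bi = BASE_INDEX.get(base)
        if bi is None:  # ambiguous call carries no allele identity
            continue
        cycle = (qpos + 1) if strand == 0 else (L - qpos)
        i = rpos - start
        rt.counts[p, i, bi, cycle - 1, strand] += 1
        rt.qual_sums[p, i, bi, cycle - 1, strand] += quals[qpos]


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


def enumerate_candidates(
    tallyset: TallySet,
    alleles_per_pool: int,
    waf_floor: float | None = None,
    trim: int = 0,
) -> list[CandidateVariantPool]:
    """Enumerate candidate variant-pools above the weighted-frequency floor.

    For every (position, pool) the single most prominent non-reference allele
    (highest WAF) is considered; it becomes a candidate when its WAF reaches
    ``waf_floor``.  The default floor is a quarter of one allele's expected
    frequency, 0.25/N, so true singletons survive modest coverage imbalance.
    ``trim`` masks that many bases from each end of every region (primer
    sequence) from enumeration.
    """
    if alleles_per_pool <= 1:
        raise ValueError("alleles_per_pool must be >= 2")
    if waf_floor is None:
        waf_floor = 0.25 / alleles_per_pool

    candidates: list[CandidateVariantPool] = []
    any_coverage = False
    for rt in tallyset:
        n = len(rt.region)
        if trim < 0 or 2 * trim >= n:
            raise ValueError(
                f"trim {trim} leaves no callable sequence in region "
                f"{rt.region.label} (length {n})"
            )
        w, alt = rt.mismatch_rates()
        any_coverage = any_coverage or bool(np.any(~np.isnan(w)))
        callable_mask = np.zeros(n, dtype=bool)
        callable_mask[trim : n - trim] = True
        hits = np.argwhere(
            (~np.isnan(w)) & (w >= waf_floor) & callable_mask[None, :]
        )
        for p, i in hits:
            bi = int(alt[p, i])
            if bi == rt.ref_idx[i]:  # position is all-reference
                continue
            counts = rt.counts[p, i]
            quals = rt.qual_sums[p, i]
            if counts[bi].sum() == 0:
                continue
            candidates.append(
                _make_candidate(rt, int(p), int(i), bi, counts, quals)
            )
    if not any_coverage:
        warnings.warn("empty tallies: no coverage anywhere", stacklevel=2)
    candidates.sort(key=lambda c: c.key)
    return candidates


def _make_candidate(
    rt: RegionTallies, p: int, i: int, bi: int, counts, quals
) -> CandidateVariantPool:
    return CandidateVariantPool(
        contig=rt.region.contig,
        position=rt.region.start + i,
        region_label=rt.region.label,
        pool_id=rt.pool_ids[p],
        ref_base=rt.ref_seq[i],
        alt_base=BASES[bi],
        continuity=tailstats.continuity(counts, bi),
        waf=tailstats.weighted_allele_frequency(quals, bi),
        avg_quality=tailstats.average_quality(counts, quals, bi),
        tailcurve=tailstats.tailcurve_ratio(counts, bi),
        strand_tailcurves=tailstats.strand_tailcurve_ratios(counts, bi),
        coverage=int(counts.sum()),
        alt_count=int(counts[bi].sum()),
    )


# ---------------------------------------------------------------------------
# TSV dialect (debugging / simulator direct injection)
# ---------------------------------------------------------------------------

TALLY_TSV_COLUMNS = [
    "contig", "pos", "pool", "base", "cycle", "strand", "count", "qualsum",
]


def tallies_to_tsv(tallyset: TallySet, path: str | Path) -> None:
    """Dump non-zero tally cells as TSV (one row per cell)."""
    rows = []
    for rt in tallyset:
        nz = np.argwhere(rt.counts > 0)
        for p, i, b, c, s in nz:
            rows.append(
                (
                    rt.region.contig,
                    rt.region.start + int(i),
                    rt.pool_ids[p],
                    BASES[b],
                    int(c) + 1,
                    "+-"[s],
                    int(rt.counts[p, i, b, c, s]),
                    float(rt.qual_sums[p, i, b, c, s]),
                )
            )
    pd.DataFrame(rows, columns=TALLY_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def tallies_from_tsv(
    path: str | Path,
    regions: Sequence[TargetRegion],
    pool_ids: Sequence[int],
    read_length: int,
    ref_seqs: dict[str, str],
) -> TallySet:
    """Load a tally TSV dump (inverse of :func:`tallies_to_tsv`).

    ``ref_seqs`` maps region label to its reference sequence.
    """
    tallies = {
        r.label: RegionTallies(r, pool_ids, read_length, ref_seqs[r.label])
        for r in merge_regions(regions)
    }
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        for rt in tallies.values():
            if rt.region.contig == row.contig and rt.region.contains(row.pos):
                p = rt.pool_index[row.pool]
                i = row.pos - rt.region.start
                b = BASE_INDEX[row.base]
                s = STRAND_INDEX[row.strand]
                rt.counts[p, i, b, row.cycle - 1, s] += row.count
                rt.qual_sums[p, i, b, row.cycle - 1, s] += row.qualsum
                break
    return TallySet(tallies.values())
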