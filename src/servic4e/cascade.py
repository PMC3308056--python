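"""The full filtering cascade, in order, with a per-stage report.

Stage order (the funnel a run reports):

  0. trim-mask the extremes of every target region (primer sequence);
  1. enumerate candidate variant-pools above the WAF floor;
  2. cross-pool cluster analysis per site in (continuity, WAF) space;
  3. global average-quality cutoff (clustered, or a manual override);
  4. strand-specific tailcurve ten-fold filter;
  5. local error-pattern filter (+/- flank window, modal pool combination).

Retained counts are non-increasing across stages by construction.  Given the
same inputs and seed the run is fully deterministic, down to the bytes of
the VCF and report it writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import clustering, error_model, tailstats
from .tally import (
    BASE_INDEX,
    CandidateVariantPool,
    TallySet,
    enumerate_candidates,
)

STAGES = (
    "candidates",
    "after_cluster",
    "after_quality",
    "after_tailcurve",
    "after_error_model",
)


@dataclass(frozen=True)
class CascadeParams:
    """All tunable parameters of a cascade run."""

    alleles_per_pool: int = 80
    waf_floor: float | None = None  # default 0.25 / N
    trim: int = 0
    tailcurve_max: float = 10.0
    tailcurve_min_strand_calls: int = 10
    flank: int = 15
    avg_quality_cutoff: float | None = None  # None = automatic clustering
    high_threshold_floor: float = 0.005
    high_threshold_scale: float = 0.5
    j_min: float = 0.5
    s_min: float = 0.25
    k_max: int = 6
    seed: int = 1
    enable_cluster: bool = True
    enable_quality: bool = True
    enable_tailcurve: bool = True
    enable_error_model: bool = True

    def __post_init__(self) -> None:
        if self.alleles_per_pool < 2:
            raise ValueError("alleles_per_pool must be >= 2")
        if self.trim < 0:
            raise ValueError("trim must be >= 0")

    @property
    def effective_waf_floor(self) -> float:
        return (
            self.waf_floor
            if self.waf_floor is not None
            else 0.25 / self.alleles_per_pool
        )


@dataclass
class StageRecord:
    stage: str
    retained: int
    dropped: list[tuple[tuple, str]] = field(default_factory=list)


@dataclass
class FilterReport:
    stages: list[StageRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {s.stage: s.retained for s in self.stages}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tretained\tdropped\n")
            for s in self.stages:
                fh.write(f"{s.stage}\t{s.retained}\t{len(s.dropped)}\n")


@dataclass
class SiteCall:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    pools: list[int]
    per_pool: dict[int, CandidateVariantPool]
    carriers: dict[int, int]  # estimated carrier chromosomes per pool


@dataclass
class CallSet:
    sites: list[SiteCall]
    pool_ids: list[int]
    alleles_per_pool: int

    def variant_pools(self) -> set[tuple[str, int, str, int]]:
        return {
            (s.contig, s.position, s.alt, p) for s in self.sites for p in s.pools
        }

    def __len__(self) -> int:
        return len(self.sites)


def run(
    tallyset: TallySet,
    params: CascadeParams,
    candidates: list[CandidateVariantPool] | None = None,
) -> tuple[CallSet, FilterReport]:
    """Run every filter stage in order; returns the calls and the funnel.

    Candidates are enumerated from the tallies by default; an externally
    seeded candidate list (e.g. from another caller's per-pool output) can
    be passed instead and flows through the same filters.
    """
    report = FilterReport()
    floor = params.effective_waf_floor

    if candidates is None:
        candidates = enumerate_candidates(
            tallyset,
            alleles_per_pool=params.alleles_per_pool,
            waf_floor=floor,
            trim=params.trim,
        )
    else:
        candidates = sorted(candidates, key=lambda c: c.key)
    report.stages.append(StageRecord("candidates", len(candidates)))

    # stage 2: cross-pool cluster analysis, per site
    if params.enable_cluster:
        survivors, dropped = _cluster_stage(tallyset, candidates, params, floor)
    else:
        survivors, dropped = candidates, []
    report.stages.append(StageRecord("after_cluster", len(survivors), dropped))

    # stage 3: global average-quality cutoff
    if params.enable_quality and survivors:
        keep_idx = clustering.quality_cutoff(
            [c.avg_quality for c in survivors],
            [c.waf for c in survivors],
            manual_cutoff=params.avg_quality_cutoff,
            s_min=params.s_min,
            k_max=params.k_max,
            seed=params.seed,
        )
        keep = set(int(i) for i in keep_idx)
        dropped = [
            (c.key, "average_quality")
            for i, c in enumerate(survivors)
            if i not in keep
        ]
        survivors = [c for i, c in enumerate(survivors) if i in keep]
    else:
        dropped = []
    report.stages.append(StageRecord("after_quality", len(survivors), dropped))

    # stage 4: tailcurve ten-fold rule, per candidate and strand
    if params.enable_tailcurve:
        kept: list[CandidateVariantPool] = []
        dropped = []
        for c in survivors:
            pt = tallyset.region_for(c.contig, c.position).position_tally(
                c.pool_id, c.position
            )
            if tailstats.tailcurve_fails(
                pt.counts,
                BASE_INDEX[c.alt_base],
                max_ratio=params.tailcurve_max,
                min_strand_calls=params.tailcurve_min_strand_calls,
            ):
                dropped.append((c.key, "tailcurve_ratio"))
            else:
                kept.append(c)
        survivors = kept
    else:
        dropped = []
    report.stages.append(StageRecord("after_tailcurve", len(survivors), dropped))

    # stage 5: local error-pattern filter, per site
    if params.enable_error_model:
        survivors, dropped = _error_model_stage(tallyset, survivors, params)
    else:
        dropped = []
    report.stages.append(
        StageRecord("after_error_model", len(survivors), dropped)
    )

    return _build_callset(tallyset, survivors, params), report


def _cluster_stage(
    tallyset: TallySet,
    candidates: Sequence[CandidateVariantPool],
    params: CascadeParams,
    floor: float,
) -> tuple[list[CandidateVariantPool], list]:
    by_site: dict[tuple, list[CandidateVariantPool]] = {}
    for c in candidates:
        by_site.setdefault(c.site, []).append(c)
    survivors: list[CandidateVariantPool] = []
    dropped: list[tuple[tuple, str]] = []
    for site, cands in by_site.items():
        contig, position, alt = site
        rt = tallyset.region_for(contig, position)
        alt_idx = BASE_INDEX[alt]
        stats: dict[int, tuple[float, float]] = {}
        have = {c.pool_id: c for c in cands}
        for pool in tallyset.pool_ids:
            if pool in have:
                stats[pool] = (have[pool].continuity, have[pool].waf)
            else:
                pt = rt.position_tally(pool, position)
                total_q = float(pt.qual_sums.sum())
                w = float(pt.qual_sums[alt_idx].sum()) / total_q if total_q > 0 else 0.0
                c_cycles = int(np.count_nonzero(pt.counts[alt_idx].sum(axis=1)))
                stats[pool] = (c_cycles, w)
        keep = clustering.positive_pools(
            stats, waf_floor=floor, s_min=params.s_min,
            k_max=params.k_max, seed=params.seed,
        )
        for c in cands:
            if c.pool_id in keep:
                survivors.append(c)
            else:
                dropped.append((c.key, "cross_pool_cluster"))
    survivors.sort(key=lambda c: c.key)
    return survivors, dropped


def _error_model_stage(
    tallyset: TallySet,
    survivors: Sequence[CandidateVariantPool],
    params: CascadeParams,
) -> tuple[list[CandidateVariantPool], list]:
    by_site: dict[tuple, list[CandidateVariantPool]] = {}
    for c in survivors:
        by_site.setdefault(c.site, []).append(c)
    kept: list[CandidateVariantPool] = []
    dropped: list[tuple[tuple, str]] = []
    for site, cands in by_site.items():
        contig, position, _ = site
        pools = {c.pool_id for c in cands}
        if params.flank > 0:
            rt = tallyset.region_for(contig, position)
            profile = error_model.local_profile(rt, position, flank=params.flank)
            mean_w = float(np.mean([c.waf for c in cands]))
            thr = max(
                params.high_threshold_floor, params.high_threshold_scale * mean_w
            )
            pattern = error_model.dominant_pattern(profile, thr)
        else:
            pattern = None
        if error_model.pattern_filter(pools, pattern, j_min=params.j_min):
            kept.extend(cands)
        else:
            dropped.extend((c.key, "error_pattern") for c in cands)
    kept.sort(key=lambda c: c.key)
    return kept, dropped


def _build_callset(
    tallyset: TallySet,
    survivors: Sequence[CandidateVariantPool],
    params: CascadeParams,
) -> CallSet:
    by_site: dict[tuple, list[CandidateVariantPool]] = {}
    for c in survivors:
        by_site.setdefault(c.site, []).append(c)
    sites: list[SiteCall] = []
    N = params.alleles_per_pool
    for (contig, position, alt), cands in sorted(by_site.items()):
        cands.sort(key=lambda c: c.pool_id)
        sites.append(
            SiteCall(
                contig=contig,
                position=position,
                ref=cands[0].ref_base,
                alt=alt,
                pools=[c.pool_id for c in cands],
                per_pool={c.pool_id: c for c in cands},
                carriers={
                    c.pool_id: max(1, int(round(c.waf * N))) for c in cands
                },
            )
        )
    return CallSet(sites, list(tallyset.pool_ids), N)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=servic4e
##INFO=<ID=POOLS,Number=.,Type=Integer,Description="Positive pools">
##INFO=<ID=WAF,Number=.,Type=Float,Description="Phred-weighted allele frequency per positive pool">
##INFO=<ID=CONT,Number=.,Type=Integer,Description="Continuity (cycles with the variant call) per positive pool">
##INFO=<ID=AVGQ,Number=.,Type=Float,Description="Average Phred quality of variant calls per positive pool">
##INFO=<ID=TCR,Number=.,Type=Float,Description="Tailcurve ratio (max over strands) per positive pool">
##FORMAT=<ID=WAF,Number=1,Type=Float,Description="Phred-weighted allele frequency">
##FORMAT=<ID=CONT,Number=1,Type=Integer,Description="Continuity">
##FORMAT=<ID=AVGQ,Number=1,Type=Float,Description="Average variant-call quality">
##FORMAT=<ID=TCR,Number=1,Type=Float,Description="Tailcurve ratio">
##FORMAT=<ID=CAR,Number=1,Type=Integer,Description="Estimated carrier chromosomes, round(WAF*N)">
"""


def write_vcf(
    callset: CallSet,
    path: str | Path,
    contigs: Iterable[tuple[str, int]] | None = None,
) -> None:
    """Write one VCF 4.2 record per called site (1-based positions).

    Per-pool statistics go both in INFO (aligned with POOLS order) and in a
    FORMAT column per pool; pools without the variant show missing values.
    """
    lines = [_VCF_HEADER]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>\n")
    sample_names = [f"pool{p}" for p in callset.pool_ids]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
        + "\n"
    )
    for s in sorted(callset.sites, key=lambda s: (s.contig, s.position, s.alt)):
        info = ";".join(
            [
                "POOLS=" + ",".join(str(p) for p in s.pools),
                "WAF=" + ",".join(f"{s.per_pool[p].waf:.6g}" for p in s.pools),
                "CONT=" + ",".join(str(s.per_pool[p].continuity) for p in s.pools),
                "AVGQ=" + ",".join(f"{s.per_pool[p].avg_quality:.4g}" for p in s.pools),
                "TCR=" + ",".join(f"{s.per_pool[p].tailcurve:.4g}" for p in s.pools),
            ]
        )
        samples = []
        for p in callset.pool_ids:
            if p in s.per_pool:
                c = s.per_pool[p]
                samples.append(
                    f"{c.waf:.6g}:{c.continuity}:{c.avg_quality:.4g}:"
                    f"{c.tailcurve:.4g}:{s.carriers[p]}"
                )
            else:
                samples.append(".:.:.:.:.")
        lines.append(
            f"{s.contig}\t{s.position + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
            f"{info}\tWAF:CONT:AVGQ:TCR:CAR\t" + "\t".join(samples) + "\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
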