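"""Synthetic pooled amplicon sequencing with a machine-readable truth set.

The generator emulates the data regime of indexed pooled amplicon libraries
sequenced on a short-read instrument:

* P pools, each carrying N alleles per autosomal site, covered at roughly
  ``depth_per_allele`` x N calls per position, spread uniformly over
  sequencing cycles and strands (random fragmentation);
* rare spiked variants at frequency copies/N with true-call qualities;
* a background error floor, multiplied after an onset cycle to mimic
  cycle-dependent chemistry decay, with a strand asymmetry factor;
* tailcurve hotspots - loci where late-cycle, strand-biased miscalls are
  frequent enough to masquerade as variants while carrying ordinary reported
  qualities (the failure mode quality-based filters cannot see);
* low-quality error hotspots - loci with frequent low-Phred miscalls, the
  mode the average-quality filter removes;
* shared-error clusters - runs of adjacent positions with elevated mismatch
  rates recurring in the same subset of pools, the prey of the local
  error-pattern filter.

Output is tally-level by default (direct injection into the containers the
cascade consumes); a read-level mode emits FASTA/BAM for integration tests
of the alignment-ingestion path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .regions import TargetRegion
from .tally import BASES, BASE_INDEX, RegionTallies, TallySet


@dataclass(frozen=True)
class HotspotSpec:
    """Loci with locally elevated error rates (count across the dataset)."""

    count: int = 0
    rate: float = 0.0


@dataclass(frozen=True)
class SharedClusterSpec:
    """Clusters of adjacent error-prone positions recurring across pools."""

    count: int = 0
    span: int = 4
    pools_per_cluster: int = 3
    rate: float = 0.02


@dataclass(frozen=True)
class Spike:
    """A variant spiked into one pool at frequency copies/N."""

    region_label: str
    offset: int  # 0-based offset within the region
    pool_id: int
    copies: int = 1
    alt: str | None = None  # chosen by the generator when None


@dataclass(frozen=True)
class SimConfig:
    pools: int = 12
    alleles_per_pool: int = 80
    n_regions: int = 24
    region_length: int = 280
    depth_per_allele: float = 30.0
    read_length: int = 47
    base_error_rate: float = 0.001
    tailcurve_multiplier: float = 5.0
    tailcurve_onset_cycle: int = 30
    strand_asymmetry: float = 0.15  # minus/plus rate ratio for cycle errors
    tailcurve_hotspots: HotspotSpec = HotspotSpec(count=6, rate=0.12)
    lowq_hotspots: HotspotSpec = HotspotSpec(count=8, rate=0.02)
    shared_clusters: SharedClusterSpec = SharedClusterSpec(count=4)
    spikes: tuple[Spike, ...] = ()
    true_quality: tuple[float, float] = (35.0, 3.0)
    error_quality: tuple[float, float] = (15.0, 5.0)
    systematic_quality: tuple[float, float] = (34.0, 3.0)
    edge_margin: int = 25  # systematic loci / random spikes placed inside
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.base_error_rate, self.tailcurve_hotspots.rate,
                  self.lowq_hotspots.rate, self.shared_clusters.rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.depth_per_allele <= 0:
            raise ValueError("depth_per_allele must be > 0")
        if not 1 <= self.tailcurve_onset_cycle <= self.read_length:
            raise ValueError("tailcurve_onset_cycle must be within 1..read_length")
        if self.alleles_per_pool < 2:
            raise ValueError("alleles_per_pool must be >= 2")


def preset(name: str) -> SimConfig:
    """Named study designs.

    * ``cohort1`` - 12 pools x 80 alleles, 47-cycle single-end reads,
      24 regions of 280 bp;
    * ``cohort2`` - 24 pools x 40 alleles, 100-cycle reads;
    * ``toy``     - 4 pools x 8 alleles, 2 short regions; seconds to run.
    """
    if name == "cohort1":
        return SimConfig()
    if name == "cohort2":
        return SimConfig(
            pools=24, alleles_per_pool=40, read_length=100,
            tailcurve_onset_cycle=64,
        )
    if name == "toy":
        return SimConfig(
            pools=4, alleles_per_pool=8, n_regions=2, region_length=120,
            read_length=24, tailcurve_onset_cycle=16,
            tailcurve_hotspots=HotspotSpec(count=2, rate=0.12),
            lowq_hotspots=HotspotSpec(count=2, rate=0.02),
            shared_clusters=SharedClusterSpec(count=1),
            edge_margin=10,
        )
    raise ValueError(f"unknown preset {name!r}; choose cohort1, cohort2 or toy")


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    pool_id: int
    copies: int
    expected_waf: float


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def variant_pools(self) -> set[tuple[str, int, str, int]]:
        return {(r.contig, r.position, r.alt, r.pool_id) for r in self.records}

    def sites(self) -> set[tuple[str, int, str]]:
        return {(r.contig, r.position, r.alt) for r in self.records}

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t")
        return cls([TruthRecord(**row) for row in df.to_dict("records")])


@dataclass
class Layout:
    """Where the generator placed each channel (useful as a test oracle)."""

    tailcurve_hotspots: list[tuple[str, int]] = field(default_factory=list)
    lowq_hotspots: list[tuple[str, int, frozenset[int]]] = field(default_factory=list)
    shared_clusters: list[tuple[str, list[int], frozenset[int]]] = field(
        default_factory=list
    )

    def systematic_positions(self) -> set[tuple[str, int]]:
        out = {(c, p) for c, p in self.tailcurve_hotspots}
        out |= {(c, p) for c, p, _ in self.lowq_hotspots}
        for c, ps, _ in self.shared_clusters:
            out |= {(c, p) for p in ps}
        return out


@dataclass
class SimResult:
    tallyset: TallySet
    truth: TruthSet
    regions: list[TargetRegion]
    config: SimConfig
    layout: Layout


def with_random_singletons(
    cfg: SimConfig, n: int, seed: int | None = None
) -> SimConfig:
    """Spike ``n`` singleton heterozygotes (copies=1) at random distinct
    positions inside the trim-safe zone, one random pool each."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    margin = cfg.edge_margin
    lo, hi = margin, cfg.region_length - margin
    if hi <= lo:
        raise ValueError("edge_margin leaves no room for spikes")
    taken: set[tuple[int, int]] = set()
    spikes = list(cfg.spikes)
    while len(spikes) < len(cfg.spikes) + n:
        reg = int(rng.integers(cfg.n_regions))
        off = int(rng.integers(lo, hi))
        if (reg, off) in taken:
            continue
        taken.add((reg, off))
        pool = int(rng.integers(1, cfg.pools + 1))
        spikes.append(Spike(_region_label(reg), off, pool, copies=1))
    return replace(cfg, spikes=tuple(spikes))


def _region_label(i: int) -> str:
    return f"amplicon{i + 1:02d}"


def _make_regions(cfg: SimConfig) -> list[TargetRegion]:
    return [
        TargetRegion(_region_label(i), 0, cfg.region_length, _region_label(i))
        for i in range(cfg.n_regions)
    ]


def _qual_sum(rng, k: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Sum of k iid truncated-normal Phred scores, by normal approximation."""
    k = k.astype(float)
    out = rng.normal(k * mu, sd * np.sqrt(np.maximum(k, 1.0)))
    out = np.where(k > 0, np.maximum(out, k * 2.0), 0.0)  # Phred floor ~2
    return out


def simulate(cfg: SimConfig) -> SimResult:
    """Generate tally-level pooled data plus its truth set, reproducibly."""
    rng = np.random.default_rng(cfg.seed)
    regions = _make_regions(cfg)
    n = cfg.region_length
    L = cfg.read_length
    P = cfg.pools
    pool_ids = list(range(1, P + 1))

    ref_idx = rng.integers(0, 4, size=(cfg.n_regions, n))
    # each position has one designated miscall target base (substitution bias)
    err_idx = (ref_idx + rng.integers(1, 4, size=ref_idx.shape)) % 4

    spikes_by_region: dict[int, list[tuple[int, int, int, int]]] = {}
    truth = TruthSet()
    spike_positions: set[tuple[int, int]] = set()
    for sp in cfg.spikes:
        reg = int(sp.region_label.replace("amplicon", "")) - 1
        if not 0 <= reg < cfg.n_regions or not 0 <= sp.offset < n:
            raise ValueError(f"spike site {sp.region_label}:{sp.offset} outside regions")
        if sp.pool_id not in pool_ids:
            raise ValueError(f"spike pool {sp.pool_id} not in 1..{P}")
        ri = int(ref_idx[reg, sp.offset])
        if sp.alt is None:
            ai = (ri + int(rng.integers(1, 4))) % 4
        else:
            ai = BASE_INDEX[sp.alt]
            if ai == ri:
                raise ValueError("spike alt equals reference base")
        spikes_by_region.setdefault(reg, []).append(
            (sp.offset, sp.pool_id, ai, sp.copies)
        )
        spike_positions.add((reg, sp.offset))
        truth.records.append(
            TruthRecord(
                contig=_region_label(reg), position=sp.offset,
                ref=BASES[ri], alt=BASES[ai], pool_id=sp.pool_id,
                copies=sp.copies,
                expected_waf=sp.copies / cfg.alleles_per_pool,
            )
        )

    layout = _plan_layout(cfg, rng, spike_positions)

    # per-cell background error rate (cycle x strand)
    p_bg = np.full((L, 2), cfg.base_error_rate)
    late = np.arange(1, L + 1) >= cfg.tailcurve_onset_cycle
    p_bg[late, 0] *= cfg.tailcurve_multiplier
    p_bg[late, 1] *= cfg.tailcurve_multiplier * cfg.strand_asymmetry

    p_hot = np.zeros((L, 2))
    p_hot[late, 0] = cfg.tailcurve_hotspots.rate
    p_hot[late, 1] = cfg.tailcurve_hotspots.rate * cfg.strand_asymmetry

    tc_by_region: dict[int, list[int]] = {}
    for c, pos in layout.tailcurve_hotspots:
        tc_by_region.setdefault(_region_index(c), []).append(pos)
    lowq_by_region: dict[int, list[tuple[int, frozenset[int]]]] = {}
    for c, pos, pls in layout.lowq_hotspots:
        lowq_by_region.setdefault(_region_index(c), []).append((pos, pls))
    shared_by_region: dict[int, list[tuple[list[int], frozenset[int]]]] = {}
    for c, ps, pls in layout.shared_clusters:
        shared_by_region.setdefault(_region_index(c), []).append((ps, pls))

    mean_cov = cfg.depth_per_allele * cfg.alleles_per_pool
    tallies: list[RegionTallies] = []
    for reg, region in enumerate(regions):
        ref_seq = "".join(BASES[b] for b in ref_idx[reg])
        rt = RegionTallies(region, pool_ids, L, ref_seq)
        for pi, pool in enumerate(pool_ids):
            cov = rng.poisson(mean_cov, size=n)
            cells = rng.multinomial(cov, np.full(2 * L, 1.0 / (2 * L)))
            cells = cells.reshape(n, L, 2)
            remaining = cells.copy()

            # spiked variant calls (true alleles, high quality)
            for off, sp_pool, ai, copies in spikes_by_region.get(reg, []):
                if sp_pool != pool:
                    continue
                f = copies / cfg.alleles_per_pool
                k = rng.binomial(remaining[off], f)
                remaining[off] -= k
                _accumulate(rt, pi, off, ai, k, rng, cfg.true_quality)

            # shared-error clusters (systematic quality, cycle/strand uniform)
            for positions, pls in shared_by_region.get(reg, []):
                if pool not in pls:
                    continue
                for off in positions:
                    k = rng.binomial(remaining[off], cfg.shared_clusters.rate)
                    remaining[off] -= k
                    _accumulate(rt, pi, off, int(err_idx[reg, off]), k, rng,
                                cfg.systematic_quality)

            # tailcurve hotspots (late-cycle, strand-biased, ordinary quality)
            for off in tc_by_region.get(reg, []):
                k = rng.binomial(remaining[off], p_hot)
                remaining[off] -= k
                _accumulate(rt, pi, off, int(err_idx[reg, off]), k, rng,
                            cfg.systematic_quality)

            # low-quality hotspots
            for off, pls in lowq_by_region.get(reg, []):
                if pool not in pls:
                    continue
                k = rng.binomial(remaining[off], cfg.lowq_hotspots.rate)
                remaining[off] -= k
                _accumulate(rt, pi, off, int(err_idx[reg, off]), k, rng,
                            cfg.error_quality)

            # background errors everywhere (low quality)
            if cfg.base_error_rate > 0:
                k = rng.binomial(remaining, p_bg[None, :, :])
                remaining -= k
                kb = k.sum(axis=(1, 2))
                for off in np.flatnonzero(kb):
                    _accumulate(rt, pi, int(off), int(err_idx[reg, off]),
                                k[off], rng, cfg.error_quality)

            # everything left is a reference call
            idx = np.arange(n)
            rt.counts[pi, idx, ref_idx[reg]] += remaining.astype(np.uint32)
            rt.qual_sums[pi, idx, ref_idx[reg]] += _qual_sum(
                rng, remaining, *cfg.true_quality
            ).astype(np.float32)
        rt.invalidate_cache()
        tallies.append(rt)

    return SimResult(TallySet(tallies), truth, regions, cfg, layout)


def _region_index(contig: str) -> int:
    return int(contig.replace("amplicon", "")) - 1


def _accumulate(rt, pi, off, base_idx, k, rng, quality) -> None:
    """Add k calls (array over (L, 2) cells) of one base at one position."""
    if k.sum() == 0:
        return
    rt.counts[pi, off, base_idx] += k.astype(np.uint32)
    rt.qual_sums[pi, off, base_idx] += _qual_sum(rng, k, *quality).astype(np.float32)


def _plan_layout(
    cfg: SimConfig, rng: np.random.Generator, taken: set[tuple[int, int]]
) -> Layout:
    """Place systematic-error loci, avoiding spikes and one another."""
    layout = Layout()
    occupied = set(taken)
    lo = cfg.edge_margin
    hi = max(lo + 1, cfg.region_length - cfg.edge_margin)

    def free_position(span: int = 1) -> tuple[int, int] | None:
        for _ in range(200):
            reg = int(rng.integers(cfg.n_regions))
            off = int(rng.integers(lo, max(lo + 1, hi - span + 1)))
            cells = {(reg, off + d) for d in range(span)}
            if not cells & occupied:
                occupied.update(cells)
                return reg, off
        return None

    for _ in range(cfg.tailcurve_hotspots.count):
        spot = free_position()
        if spot:
            layout.tailcurve_hotspots.append((_region_label(spot[0]), spot[1]))
    for _ in range(cfg.lowq_hotspots.count):
        spot = free_position()
        if spot:
            size = int(rng.integers(1, min(3, cfg.pools) + 1))
            pools = frozenset(
                int(p) for p in rng.choice(
                    np.arange(1, cfg.pools + 1), size=size, replace=False
                )
            )
            layout.lowq_hotspots.append((_region_label(spot[0]), spot[1], pools))
    sc = cfg.shared_clusters
    for _ in range(sc.count):
        spot = free_position(span=sc.span)
        if spot:
            pools = frozenset(
                int(p) for p in rng.choice(
                    np.arange(1, cfg.pools + 1),
                    size=min(sc.pools_per_cluster, cfg.pools), replace=False,
                )
            )
            positions = [spot[1] + d for d in range(sc.span)]
            layout.shared_clusters.append((_region_label(spot[0]), positions, pools))
    return layout


# ---------------------------------------------------------------------------
# Read-level mode (integration tests of the BAM ingestion path)
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    contig: str
    start: int  # 0-based leftmost reference position
    reverse: bool
    seq: str  # reference orientation, as stored in SAM
    quals: list[int]


def simulate_reads(cfg: SimConfig) -> tuple[dict[int, list[SimRead]], dict[str, str]]:
    """Read-level generation: background errors and spikes only.

    Returns reads per pool and the reference sequence per contig.  Cycle for
    a base at aligned offset j is j+1 on plus-strand reads and L-j on
    minus-strand reads, matching the tally builder's convention.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.region_length, cfg.read_length
    if n < L:
        raise ValueError("region shorter than read length")
    regions = _make_regions(cfg)
    ref_idx = rng.integers(0, 4, size=(cfg.n_regions, n))
    refs = {
        r.label: "".join(BASES[b] for b in ref_idx[i])
        for i, r in enumerate(regions)
    }
    spikes: dict[tuple[int, int], tuple[int, int, int]] = {}
    for sp in cfg.spikes:
        reg = _region_index(sp.region_label)
        ri = int(ref_idx[reg, sp.offset])
        ai = BASE_INDEX[sp.alt] if sp.alt else (ri + 1) % 4
        spikes[(reg, sp.offset)] = (sp.pool_id, ai, sp.copies)

    reads: dict[int, list[SimRead]] = {p: [] for p in range(1, cfg.pools + 1)}
    n_reads = int(round(cfg.depth_per_allele * cfg.alleles_per_pool * n / L))
    mu, sd = cfg.true_quality
    emu, esd = cfg.error_quality
    for reg, region in enumerate(regions):
        for pool in range(1, cfg.pools + 1):
            starts = rng.integers(0, n - L + 1, size=n_reads)
            revs = rng.random(n_reads) < 0.5
            for start, rev in zip(starts, revs):
                base_idx = ref_idx[reg, start : start + L].copy()
                quals = np.clip(
                    np.rint(rng.normal(mu, sd, size=L)), 2, 41
                ).astype(int)
                for j in range(L):
                    cyc = (L - j) if rev else (j + 1)
                    rate = cfg.base_error_rate
                    if cyc >= cfg.tailcurve_onset_cycle:
                        rate *= cfg.tailcurve_multiplier
                        if rev:
                            rate *= cfg.strand_asymmetry
                    sp = spikes.get((reg, start + j))
                    if sp and sp[0] == pool and rng.random() < sp[2] / cfg.alleles_per_pool:
                        base_idx[j] = sp[1]
                    elif rate > 0 and rng.random() < rate:
                        base_idx[j] = (base_idx[j] + int(rng.integers(1, 4))) % 4
                        quals[j] = int(np.clip(round(rng.normal(emu, esd)), 2, 41))
                reads[pool].append(
                    SimRead(
                        contig=region.label, start=int(start), reverse=bool(rev),
                        seq="".join(BASES[b] for b in base_idx),
                        quals=list(quals),
                    )
                )
    return reads, refs


def write_read_level_dataset(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[list[tuple[int, str]], list[TargetRegion], Path]:
    """Write FASTA + sorted/indexed BAMs + manifest for the BAM entry point.

    Returns (manifest entries, regions, reference path).
    """
    import pysam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads, refs = simulate_reads(cfg)
    regions = _make_regions(cfg)

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for label, seq in refs.items():
            fh.write(f">{label}\n{seq}\n")
    pysam.faidx(str(fasta))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": r.label, "LN": len(r)} for r in regions],
    }
    manifest: list[tuple[int, str]] = []
    for pool, pool_reads in reads.items():
        unsorted = out / f"pool{pool}.unsorted.bam"
        bam = out / f"pool{pool}.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as af:
            for i, r in enumerate(pool_reads):
                a = pysam.AlignedSegment(af.header)
                a.query_name = f"p{pool}r{i}"
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.quals)
                )
                a.flag = 16 if r.reverse else 0
                a.reference_name = r.contig
                a.reference_start = r.start
                a.mapping_quality = 60
                a.cigarstring = f"{len(r.seq)}M"
                af.write(a)
        pysam.sort("-o", str(bam), str(unsorted))
        unsorted.unlink()
        pysam.index(str(bam))
        manifest.append((pool, str(bam)))
    with open(out / "manifest.tsv", "w") as fh:
        for pool, path in manifest:
            fh.write(f"{pool}\t{path}\n")
    return manifest, regions, fasta
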