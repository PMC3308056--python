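# servic4e

Rare single-nucleotide variant detection in **pooled amplicon sequencing**
by cross-pool filtering.

When a cohort is sequenced as indexed pools — e.g. 12 libraries of 40
samples, so each pool carries N = 80 alleles at every autosomal site — a
singleton heterozygote appears at an allele frequency of 1/N, uncomfortably
close to the sequencing error rate. Generic variant callers flood such data
with false positives driven by cycle-dependent chemistry errors and locally
clustered, library-specific artifacts. `servic4e` filters candidate
variant-pools (a *variant-pool* is one (site, pool, alternate allele)
hypothesis, the unit of discovery and validation in pooled designs) through
a cascade of statistics that exploit exactly those failure modes.

## The statistics and the cascade

For each candidate variant-pool, four statistics are computed from the
per-position tally of base calls indexed by (nucleotide, sequencing cycle,
strand):

* **continuity** C — the number of cycles (1..L for L-cycle reads) at which
  the variant nucleotide is called; random fragmentation places a true
  allele at many cycles, artifacts at few;
* **weighted allele frequency** w — Σ(Phred of variant calls) / Σ(Phred of
  all calls) at the position;
* **average quality** q̄ — mean Phred score of the variant calls;
* **tailcurve ratio** T — per strand, the fold change of the variant
  proportion between the first ⌈L/2⌉ and the last ⌊L/2⌋ cycles (with a
  one-call pseudocount in each half); cycle-dependent errors concentrate in
  late cycles and on one strand, giving T ≫ 1.

Candidates (every (position, pool) whose most prominent non-reference
allele has w ≥ 0.25/N) then pass through five stages:

1. **trim** — mask primer-length sequence at region extremes (default 0);
2. **cross-pool clustering** — per site, all pools are clustered in (C, w)
   space by k-medoids, with the number of clusters chosen by average
   silhouette width; pools lacking the variant form a baseline cluster that
   is filtered out;
3. **average-quality cutoff** — all candidates are clustered in
   (q̄, log₁₀ w) space and only the high-quality mode is retained (a manual
   cutoff can override the clustering);
4. **tailcurve rule** — a candidate is removed when any strand with ≥ 10
   variant calls has T > 10;
5. **error-pattern model** — within ±15 bp of the site, the modal
   combination of pools with high mismatch rates is extracted; a candidate
   whose positive-pool set matches that local pattern (Jaccard ≥ 0.5) is
   removed.

Retained counts are non-increasing across stages, and a run is byte-for-byte
reproducible given the same inputs and seed.

The package also ships a pooled-data **simulator** (tally-level or
read-level FASTA/BAM output, with spiked singletons, cycle-dependent and
strand-biased error channels, low-quality hotspots and shared cross-pool
error clusters, plus a machine-readable truth set) and a **metrics** module
(confusion counts on a variant-pool basis and the eight derived rates,
including the Matthews correlation coefficient).

## Worked example

```python
from servic4e import simulator, cascade, metrics

cfg = simulator.with_random_singletons(simulator.preset("toy"), 3, seed=11)
res = simulator.simulate(cfg)                     # 4 pools x 8 alleles
params = cascade.CascadeParams(alleles_per_pool=cfg.alleles_per_pool, trim=10)
calls, report = cascade.run(res.tallyset, params)
for stage, n in report.counts().items():
    print(f"{stage:<18} {n}")
for s in calls.sites:
    for p in s.pools:
        c = s.per_pool[p]
        print(f"{s.contig}:{s.position+1} {s.ref}>{s.alt} pool {p} "
              f"w={c.waf:.4f} C={c.continuity} q={c.avg_quality:.1f} "
              f"T={c.tailcurve:.2f} carriers={s.carriers[p]}")
```

prints

```
candidates         7
after_cluster      7
after_quality      3
after_tailcurve    3
after_error_model  3
amplicon01:23 T>A pool 4 w=0.1454 C=19 q=35.5 T=1.30 carriers=1
amplicon01:70 G>T pool 3 w=0.1428 C=15 q=35.7 T=1.01 carriers=1
amplicon02:13 C>T pool 2 w=0.1182 C=16 q=33.8 T=1.29 carriers=1
```

Seven candidates enter the cascade; the quality stage removes four
low-quality artifacts, and the three spiked singletons survive to the call
set, each confined to the pool that truly carries it (w ≈ 1/8 = one
heterozygous allele out of 8, hence one estimated carrier chromosome).

The same pipeline runs from the shell on real data:

```sh
servic4e call --manifest pools.tsv --regions targets.bed --reference ref.fa \
              --alleles 80 --read-length 47 --trim 25 \
              --out calls.vcf --report funnel.tsv
servic4e evaluate --calls calls.vcf --truth assayed.tsv --out metrics.tsv
servic4e simulate --preset toy --singletons 5 --seed 4 --out sim/
```

`call` consumes one sorted, indexed BAM per pool (listed in a two-column
manifest), a BED of target regions, and an indexed FASTA; it writes a VCF
4.2 whose INFO and per-pool FORMAT fields carry the four statistics plus
the estimated carrier count round(w·N). All parameters can also be given in
a YAML file (`--config`); an explicit flag always wins.

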