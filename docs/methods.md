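# Methods

## Data model

All filtering operates on per-position, per-pool tallies of base calls
indexed by (nucleotide ∈ {A,C,G,T}, sequencing cycle ∈ 1..L, strand ∈ {+,−}),
with a parallel array of summed Phred qualities. The cycle of a call is its
1-based index in the read **as sequenced**: for minus-strand alignments the
aligned query offset is reflected (cycle = L − offset), so "late cycles"
always refers to chemistry decay late in a run, not to genome coordinates.
Soft-clipped bases, deletions and reference skips contribute nothing;
ambiguous (N) calls are dropped because they carry no allele identity.
Paired-end mates are tallied as independent reads, each with its own cycle
axis. Coordinates are 0-based half-open internally; BED is consumed
natively and VCF output converts to 1-based.

Candidate enumeration keeps, per (position, pool), only the single most
prominent non-reference allele (highest weighted allele frequency), and
only when that frequency reaches the floor. Multiple alternate alleles
surviving at one site independently are emitted as separate VCF records:
each is its own variant-pool hypothesis.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `waf_floor` | 0.25/N | fraction | a quarter of one allele's expected frequency 1/N, so true singletons survive modest pool-normalisation imbalance |
| `trim` | 0 | bp | masks primer-derived sequence at region extremes; set to the primer length (25 in the amplicon designs emulated here). Trim masks candidate *enumeration* only, not the tallies, so the error-pattern window still sees primer-adjacent mismatches as context |
| `tailcurve_max` | 10 | fold | a generous threshold that removes only clearly erroneous late-cycle profiles |
| `tailcurve_min_strand_calls` | 10 | calls | a strand with fewer variant calls gives too noisy a proportion to judge alone |
| tailcurve pseudocount | 1 | call | keeps the ratio defined when one half-read has no variant coverage while leaving genuinely erroneous profiles above threshold |
| half-read split | ⌈L/2⌉ | cycles | 47 → 24\|23; an explicit convention for odd read lengths |
| `flank` | 15 | bp | the ±15 window in which recurring cross-pool error combinations are sought |
| error-pattern "high" threshold | max(0.005, 0.5·w̄) | fraction | scaled to the site's own mean surviving WAF so the test stays meaningful across coverage levels; applied per site because the filter eliminates whole sites |
| `j_min` | 0.5 | Jaccard | midpoint between the two regimes the filter must separate: identical pool sets (drop) and disjoint ones (keep) |
| `s_min` | 0.25 | silhouette | standard weak-structure convention below which no cluster structure is declared |
| `k_max` | 6 | clusters | pools split into at most a few groups |
| `avg_quality_cutoff` | automatic | Phred | clustering in (q̄, log₁₀ w); a manual value overrides it |
| `seed` | 1 | — | all randomness flows from the single run seed |

## Numerical and algorithmic choices

* **k-medoids.** The PAM objective (total distance of points to their
  nearest medoid, Euclidean on standardized features) is solved exactly by
  enumeration when C(n,k) ≤ 1000 — which covers the per-site pool
  clustering and keeps tiny instances at the global optimum — and otherwise
  by PAM BUILD initialisation plus best-improvement SWAP passes. All ties
  break to the lowest index, so results are deterministic regardless of
  seed. Average silhouette width uses the all-singleton convention
  (silhouette 0), which also handles the two-point edge case: its forced
  k = 2 comparison scores 0 and falls back to a single cluster.
* **Feature scaling.** Per-site pool clustering standardizes (C, w)
  linearly; the global quality filter standardizes (q̄, log₁₀ w). Constant
  features are zeroed rather than divided by zero.
* **Cluster retention.** Per site, the retained pools are the cluster whose
  medoid has the highest (w, C) plus every cluster whose medoid w reaches
  the candidate floor. For a rare variant only the high cluster stands out;
  for a common variant every cluster except the near-zero baseline
  (negative pools) survives. When no structure is found (silhouette below
  `s_min`), pools above the floor are kept. The quality filter retains the
  cluster(s) with the highest medoid q̄; exact ties retain their union,
  favouring sensitivity.
* **Degenerate inputs.** Zero-coverage positions are undefined (NaN) in
  mismatch profiles and can never seed candidates; a zero-quality position
  raises rather than returning a silent 0; an absent variant base yields
  continuity 0 with a warning. A trim that leaves no callable sequence, a
  read longer than the declared cycle count, and a missing BAM index all
  fail fast with the offending file or region named.
* **Confusion arithmetic.** Rates are percentages; zero-denominator
  statistics are reported as 0 and flagged (`undefined`), the usual MCC
  convention. Reported tables round half-up to two decimals.
* **Truth universe.** Evaluation counts only variant-pools that were
  assayed (confirmed positive or negative); calls outside the universe are
  reported separately as *unevaluable* rather than as false positives,
  mirroring how validation by targeted re-sequencing actually constrains
  what can be scored.

## The simulator

The generator emulates indexed pooled amplicon libraries: P pools of N
alleles, per-position coverage Poisson around depth·N spread uniformly over
cycles and strands (random fragmentation), and five signal/error channels:

* **spiked variants** — binomial at copies/N with true-call qualities
  (Phred ≈ 35 ± 3);
* **background errors** — uniform at the base rate (default 0.1%),
  multiplied (default ×5) after an onset cycle, strand-asymmetric (minus
  strand at 0.15× the plus rate), low quality (Phred ≈ 15 ± 5), each
  position miscalling towards one designated substitution target;
* **tailcurve hotspots** — loci whose late-cycle, strand-biased error rate
  (default 0.12) is high enough to produce above-floor candidates in every
  pool. These carry near-true qualities (Phred ≈ 34 ± 3): the defining
  property of cycle-dependent miscalls is that reported quality does not
  expose them, which is why a dedicated tailcurve filter exists at all. The
  rate default places their late-half proportion around 0.1 and their
  tailcurve ratios well past ten-fold — they model the clearly erroneous
  profiles the ten-fold rule is meant to catch, not borderline cases;
* **low-quality hotspots** — loci with frequent Phred-15 miscalls in a
  small random pool subset; the prey of the average-quality stage;
* **shared-error clusters** — runs of adjacent positions (default span 4)
  with ~2% miscall rates recurring in the same random pool subset (default
  3 pools), strand- and cycle-uniform with ordinary qualities, so that only
  the local error-pattern filter can remove them.

Systematic loci are placed away from region extremes and never collide with
spiked sites. Presets mirror the pooled designs the package targets:
`cohort1` (12 pools × 80 alleles, 47-cycle single-end reads, 24 regions of
280 bp, ~30× per-allele coverage), `cohort2` (24 pools × 40 alleles,
100-cycle reads), and `toy` (4 pools × 8 alleles, seconds to run). Default
output injects tallies directly — the cascade consumes tallies, so this is
the fast, exact path; a read-level mode (background errors and spikes only)
emits FASTA plus sorted/indexed BAMs to exercise the alignment-ingestion
path end to end.

**What passing tests do and do not show.** The simulator reproduces the
*structure* of pooled-sequencing error — cycle dependence, strand bias,
quality bimodality, cross-pool recurrence — but not PCR jackpot
amplification, barcode bleed-through, alignment artifacts at amplicon
junctions, indels, or sequence-context-specific error rates. Recovery
results on simulated data therefore demonstrate that each filter removes
the error mode it was designed for and spares disjoint true singletons;
they do not certify sensitivity/specificity on any particular real library,
which depends on normalisation quality and error modes outside this model.

## Problem sizes

The acceptance script and the heaviest test run ten replicates of the
`cohort1` design with 30 spiked singletons each (≈ 2,400× position coverage
per pool, ≈ 8 × 10⁶ tally cells per replicate), chosen as the smallest
experiment in which every error channel produces enough candidates for each
cascade stage's marginal effect to be measured. Unit and property tests run
on toy designs and random tallies.

## Known limitations

* Insertions and deletions are not called; only single-nucleotide variants.
* Pools must share one allele count N; heterogeneous pool sizes are
  rejected.
* The candidate floor (0.25/N), the error-pattern "high" threshold and the
  Jaccard cutoff are heuristics exposed as configuration; published
  behaviour constrains their intent (the worked keep/drop scenarios) but
  not their exact values.
* Continuity counts cycles with the variant on either strand combined; a
  per-strand variant would double the statistic's range without clear
  benefit for the filters that consume it.
* A dense true haplotype could in principle self-mask in the error-pattern
  window (its own sites contributing to the local pattern); window
  positions that are themselves candidates are not excluded from pattern
  extraction.
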