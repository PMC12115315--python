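# Methods

## Selection model

A screen is a set of independent replicate trajectories over a shared input
pool (P0). One passage consists of:

1. **Infection bottleneck.** `B = round(n_cells × moi)` virions are drawn
   from the current pool by a single multinomial on its frequencies. With the
   default 5×10⁶ cells at MOI 0.1 the bottleneck is 500,000 — large enough
   that neutral drift is mild (per-passage coefficient of variation for a
   clone at frequency 1/16,000 is ≈ 18%), small enough to matter over four
   rounds.
2. **Fitness-weighted replication.** Expected progeny of clone *i* are
   proportional to `sampled_i × w_i`; realized progeny are one multinomial
   draw of the fixed output total `B × burst_size` (default burst 100).
   Fitness `w` therefore acts **once per passage**, making it a per-passage
   odds multiplier: for two clones, `odds' = odds × (w_A/w_B)` each round.
   This is a deliberate coarse-graining — a real 48-h infection comprises
   several viral generations, so a measured per-passage `w` of ~2–3 may
   correspond to a much smaller per-cycle advantage.
3. **Neutral amplification.** The screen amplifies virus on a production cell
   line between passages to reset the input MOI. Because the amplification
   host differs from the selection host, it is modeled as fitness-neutral
   expansion and absorbed into the fixed output total. Whether any selection
   occurs during amplification is unknown; attributing all selection to the
   tumor-cell passage is the model's main untestable assumption.

Deterministic mode replaces both draws with `f' = f·w / Σ f·w` and converts
frequencies to integer counts by the largest-remainder method (totals are
preserved exactly; rounding granularity is 1/output_total ≈ 2×10⁻⁸). For
exact closed-form work the two-clone competition simulator
(`simulate_competition(mode="deterministic")`) iterates the frequency map
without rounding and matches `odds_T = odds_0·w^T` to machine precision.

**Seeding.** Replicate *r* uses the generator
`default_rng(SeedSequence(seed, spawn_key=(r,)))`, so trajectories are
reproducible and adding replicates never perturbs earlier ones. Sequencing
streams use `spawn_key=(1000, sample_index)`; planted-clone selection uses
`spawn_key=(99,)`.

## Sequencing model

Each read is the full amplicon `backbone5 + guide + backbone3` (58 nt with
the default 19/22/17-nt layout) for a template drawn i.i.d. from pool
frequencies, with uniform i.i.d. per-base substitutions and no indels;
quality strings are constant Q40. Substitution-only error keeps family
clustering in Hamming space, which is the regime where the directional rule
is exact; indel-tolerant clustering is an extension point, not implemented.
Real amplicon data additionally contain indels, quality-dependent and
position-dependent error, PCR chimeras/jackpots, and barcode cross-talk;
passing tests on simulated reads therefore validate the pipeline's logic,
not its robustness to those artifacts. Read depth of the original experiment
is unreported; the default of 200,000 reads/sample gives ≈ 12 reads per
clone of a uniform 16,000-clone library — enough to rank strong hits, far
too few to resolve small fitness differences.

## Read processing

**Extraction.** Both anchors are located allowing `max_anchor_mm`
substitutions (default 1, no indels), leftmost 5′ placement first, then the
leftmost 3′ placement giving a guide length within `guide_len ±
len_tolerance`. Reads failing extraction count toward
`total − assigned` and are never clustered. A fixed-layout fast path (exact
length, anchors at canonical positions) short-circuits the scan and is
verified in tests to agree with the general search.

**Family clustering.** Distinct sequences are processed in descending count
order (ties lexicographic). Sequence `b` joins the family of representative
`a` iff `Hamming(a,b) ≤ d_max` (default 1) and `count(a) ≥ 2·count(b) − 1`;
among qualifying families the largest representative count wins, ties to the
lexicographically smallest. Members never recruit further members, so true
1-neighbor guides are not chained. At the default error rate (0.5%/base)
reads with ≥ 2 guide substitutions (~0.5% of reads) land outside every true
family and found spurious singleton families; they are the reason family
counts slightly exceed the true clone number and bound the per-read recovery
at ≈ 99.5% of assigned reads. Clustering is within-sample; samples are
harmonized afterwards by exact representative sequence, which avoids
cross-sample chaining at the cost of splitting a family whose representative
differs between samples (not observed at default depths).

## Enrichment and hit calling

Frequencies are counts normalized per sample; pooled frequencies sum counts
across replicates first (samples have equal design depth, so this matches
the cumulative-frequency convention). Enrichment is
`(f_P4 + ε)/(f_input + ε)` with `ε = 0.5 reads / input assigned total`,
symmetric so that clones absent from either sample stay finite — input
frequencies sit near the detection floor (≈ 6×10⁻⁵), where a pseudocount is
the difference between "1446-fold" and "infinite". A hit requires
`f_P4 > threshold` (strict, default 1%) in a replicate; recurrence counts
hit replicates and never uses the pooled frequency.

## Validation statistics

* **Plaque concordance**: exact two-sided binomial test (scipy `binomtest`),
  minimum-likelihood convention — the p-value sums P(j) over outcomes no more
  likely than the observed count (relative tie tolerance 1+10⁻⁷). Picking 20
  plaques gives wide confidence bands; the test formalizes "consistent with
  sequencing", it cannot sharply confirm a frequency.
* **Competition fitness**: `ŵ = [odds(f_T)/odds(f_0)]^(1/T)`, undefined at
  boundary frequencies (an observation of 0/100 or 100/100 plaques carries
  no odds information). Parameterizing fitness as a per-passage odds
  multiplier is the only form identifiable from two endpoints; continuous
  growth-rate models would require within-passage kinetics.
* **Set overlap**: Fisher's exact test on
  `[[nAB, nA−nAB], [nB−nAB, N−nA−nB+nAB]]` with the conditional-MLE odds
  ratio. The universe `N` defaults to 20,000 (approximate mouse
  protein-coding gene count); the tested universe of the original microarray
  is unknown, so `N` is configurable — significance of the shipped example
  holds for every `N ≥ 2,000` (see `examples/gene_overlap_test.py`).
* **Fold-change filter**: symmetric rule `max(r, 1/r) ≥ threshold`,
  direction up/down by the sign of `r − 1`; ΔΔCt fold change `2^(−ΔΔCt)`;
  dual-luciferase ratio-of-ratios. All plain arithmetic, validated by
  worked examples and symmetry properties.

## Numerical choices

* Largest-remainder apportionment everywhere frequencies become counts;
  ties broken by lowest index (stable argsort).
* p-value tie tolerance 1+10⁻⁷ (matches the enumeration oracles to < 10⁻¹²).
* Hit threshold comparisons are strict; ranking ties break lexicographically
  on the representative sequence so reports are fully deterministic.
* Guide generation enumerates and permutes the full k-mer space when it is
  within 4× the requested size (exact even at saturation), otherwise uses
  rejection sampling.

## Problem sizes used by the tests

The default configuration *is* the study condition: 16,000 clones, 5
replicates, MOI 0.1 on 5×10⁶ cells, 4 passages, 200,000 reads/sample at
0.5% error, two planted clones at `w = 3`. The full-scale recovery test runs
this five times (seeds 1–5, ≈ 40 s total); unit and property tests use small
libraries (≤ 100 clones), depths ≤ 20,000, 200–600 Monte-Carlo seeds for
drift/recovery checks, and enumeration oracles on supports ≤ 25 (binomial),
universes ≤ 40 (Fisher), and ≤ 50 distinct sequences (clustering).

## Known limitations

* One fitness number per clone: no epistasis with viral backbone mutations,
  no interferon feedback, no spatial structure, no multi-cycle within-well
  kinetics.
* Planted clones at `w = 3` compound 81-fold over four passages — from a
  uniform 1/16,000 start that reaches only ≈ 0.5%, below the 1% per-replicate
  hit threshold. Strong real hits (implied per-passage `w` up to ≈ 7.7)
  cross the threshold; moderate ones are detectable by ranking but not by
  the threshold/recurrence criterion. This is a property of the screen
  design, not an artifact of the implementation.
* Demultiplexing is out of scope: one FASTQ per sample is assumed.
* No statistical model for enrichment p-values — the screen's own analysis
  is threshold-based; counts are available for users who want to fit one.
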