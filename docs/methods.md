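# Methods

## Stratification grid

Calls are binned on total read depth (TD) and Phred-scaled variant quality
(SNPQ, the VCF `QUAL` column for both caller dialects). All bins are
half-open with the lower edge inclusive (`a ≤ x < b`), the first bin open
below the first edge and the last unbounded above, so the grid partitions
`[0, ∞)²`. Default edges are frozen and regression-tested:

* TD: 5, 10, 20, 40 (five bins, shared by both callers);
* SNPQ, mpileup dialect: 10, 20, 30, 40, 60, 80, 100, 200;
* SNPQ, UnifiedGenotyper dialect: 20, 50, 100, 150, 200, 300, 500, 1000
  (that caller's `QUAL` scale runs roughly 3× higher).

Edges are overridable through `CategoryScheme` (YAML-serializable); custom
edges must be strictly increasing and positive.

## Rates and uncertainty

Per-cell, marginal and pooled validation rates are stored as proportions and
formatted as percentages with one decimal only at the reporting layer; empty
cells render as `0/0 (-)`. Intervals are Clopper–Pearson exact binomial
(beta-quantile form), chosen over Wald/Wilson because many grid cells hold
fewer than ten variants; k = 0 and k = n force the respective bound to 0 / 1.
Confidence defaults to 0.95 and is configurable everywhere. Records with an
unknown Sanger outcome are excluded from every rate but always counted and
reported, never silently dropped.

Pooled "rate above a cutoff" computations only accept cutoffs that coincide
with grid edges; anything else would split cells whose interior composition
is unknown, so it is a usage error rather than an approximation.

## Strand-bias metrics

For mpileup-dialect records the strand-bias metric is the alternate-forward
percentage AF% = 100 · alt_fwd / (alt_fwd + alt_rev), computed over
alternate-supporting reads only (the alternative reading — alternate-forward
over all forward reads — would conflate strand bias with allele fraction and
is not used). AF% is undefined when no read supports the alternate allele;
such records cannot be strand-filtered and fail the filter under the default
undefined-metric policy. For UnifiedGenotyper-dialect records the metric is
the caller-emitted SB score consumed as-is (more negative = less biased; the
sign convention is implied by the calibrated cutoff SB < −10).

## Calibrated hard filters

The presets are conjunctions: mpileup SNPQ ≥ 40 ∧ MQ > 58 ∧ 20 ≤ AF% < 80;
UnifiedGenotyper SNPQ ≥ 300 ∧ MQ > 58 ∧ SB < −10. Two deliberate boundary
choices:

* the quality conjunct uses ≥ so that the filter coincides exactly with the
  grid-edge pooling that produced the 87.7%/83.6% aggregates (a strict >
  is available via `strict_snpq=True`);
* MQ is strictly greater than 58; since common mappers cap MQ at 60 and emit
  near-integer values this retains MQ ∈ {59, 60} (relaxable via
  `strict_mq=False`).

The undefined-metric policy defaults to `fail` (conservative: every retained
call must carry the evidence the filter inspects), with `pass` and `error`
available.

## Cutoff scanning

Candidate thresholds are bin lower edges only. Binwise mode returns the
minimal edge t such that every non-empty bin at/above t meets the target
rate — this is the rule under which the mpileup data yield 80 and the
recalibrated UnifiedGenotyper data yield 300 at an 80% target. Cumulative
mode pools all bins at/above each candidate instead. Empty bins are skipped;
if no edge qualifies the report's threshold is absent rather than clamped.

## Reference counts and synthetic reconstruction

The bundled table stores the per-cell (validated, total) counts of four
Sanger-validated exome call sets (348/336/304/324 variants); marginals are
always recomputed. One printed bin label in the source material read
"200≤SNPQ<3000" where the adjacent bin starts at 300; it is treated as a
typographical error for "200≤SNPQ<300".

The per-variant datasets behind those counts are not redistributed, so
`snvcalib.reconstruct` builds *synthetic* per-variant tables that are exactly
consistent with every published aggregate: cell counts per set; 294 variant
keys shared across sets with 208 validated (the published totals force the
split — 221 = 208 + 13, 213 = 208 + 5, 215 = 208 + 7); and combined-filter
retention of 89/90 (set3) and 72/74 (set4), matching the published 98.9% and
97.3%. Within those constraints the assignment is deterministic: TD/SNPQ take
fixed representative values inside each bin, and MQ/AF%/SB are two-valued
(passing/failing). Consequences: the reconstruction supports regression of
the published aggregates, but its metric *distributions* are degenerate —
per-conjunct intermediate rates other than the quality cutoff (whose
denominators were never published) are not meaningful on it, and profiles
over MQ/AF/SB should use the stochastic simulator instead.

## Synthetic cohort generator

Per variant, a latent truth flag `t ~ Bernoulli(tp_fraction)` (default 0.65,
the unfiltered validation level of the reference panels) drives
class-conditional draws:

* TD ~ 1 + NegBin(mean 20, dispersion 1.6): exome-like coverage with a long
  right tail;
* SNPQ | true = (10 + 30 · ln TD) · exp(N(0, 0.5)): lognormal around a
  location rising with log-depth; SNPQ | false ~ Exp(scale 18). The
  monotone-decreasing false density makes the per-bin validation rate rise
  monotonically in quality (likelihood-ratio ordering), while false
  positives' quality being depth-independent decouples depth from accuracy:
  conditional on quality, deeper calls are no better, matching the observed
  flat-to-negative depth effect;
* MQ | true ~ N(59.3, 0.6), MQ | false ~ N(54, 4), clipped to [0, 60];
  GQ ~ N(80, 18) / N(65, 22) clipped to [0, 99];
* allele fraction Beta(14, 14) / Beta(4, 8); alternate-forward probability
  Beta(30, 30) for true calls and an equal mixture of Beta(0.5, 12) and its
  mirror for false ones, realized as binomial DP4 counts (≥ 1 alternate
  read). This places ≈ 94% of false-positive AF% mass outside [20, 80);
* SB | true ~ N(−30, 8), SB | false ~ N(−2, 5);
* caller membership: both callers with probability 0.9 (true) / 0.35
  (false), otherwise one caller uniformly; both-caller variants share a key
  and the UnifiedGenotyper record scales quality by `gatk_snpq_scale` = 3;
* the Sanger label equals truth unless flipped with probability
  `sanger_error` (default 0: Sanger is treated as gold standard).

All defaults live in `SimParams` and are overridable; generation is fully
reproducible from (params, seed). What the simulator does **not** model:
read-level data (no FASTQ/BAM), zygosity, linkage between neighbouring
sites, region-specific artifact clustering (repeats, CNVs), or batch
effects. Tests passing on synthetic cohorts therefore demonstrate the
pipeline's statistical machinery, not caller behaviour on real genomes.

## Parameter-recovery harness

`recover_rates` compares each well-filled grid cell's empirical validation
rate against the model-implied probability estimated by Monte Carlo from the
same parameters but an *independent* random stream (seed derived via
`SeedSequence`, decorrelated from the generation seed, so agreement is not
an artifact of shared draws). Cells need ≥ 30 records (binomial normality);
fewer than 10 eligible cells is an error. The z-score uses the pooled
standard error of both samples; at the default Monte-Carlo size (200,000)
the oracle noise is small relative to the cohort's.

## Problem sizes and numerical choices

Planted-structure checks run at 50,000 variants (per-bin standard errors
below ~1 pp); replicate-level enrichment checks use 200 cohorts of 1,200
variants, sizes at which the whole suite and the reproduction script each
run in seconds on one core. Binning uses `searchsorted` with right-open
semantics and is property-tested against a linear scan; interval nesting
(99% ⊇ 95%) is swept exhaustively for n ≤ 50; tabular round-trips parse
floats in round-trip precision mode so written cohorts reload bit-identical.

## Known limitations

* The reconstruction's degenerate metric distributions (above).
* The concordance split of a single selected panel uses the companion
  caller's membership list restricted to shared keys; whether the published
  348-variant split was computed against the basic or recalibrated companion
  call set is not documented, so the operation is call-set-agnostic and both
  candidates are exercised in tests.
* VCF parse errors are located by record number, not raw line number (the
  underlying htslib-based reader does not expose line offsets).
* No significance testing between call sets, no ROC/F-score cutoff
  optimisation, and no FILTER-field annotation or VCF writing: the package
  calibrates and evaluates filters, it does not re-emit VCFs.
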