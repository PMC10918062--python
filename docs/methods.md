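# Methods

This note records the statistical model behind `mirmint`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions that make runs reproducible.

## The integration model

miRNAs repress mRNAs post-transcriptionally, so an actively regulating miRNA
should be *anticorrelated* with its targets across samples.  The pipeline
operationalizes this in three cuts:

1. only miRNAs that are both abundant (top `top_n = 100` by mean case-group
   CPM) and differentially expressed (raw p < `alpha_de = 0.05`) are
   examined — the focus set;
2. only predicted targets that are themselves significantly DE are
   correlated, since a target that does not move carries no directional
   information;
3. for each focus miRNA the significantly correlated targets
   (p < `alpha_corr = 0.05`) are split into inverse (ρ < 0) and positive
   (ρ > 0), and a one-proportion test asks whether the inverse fraction
   departs from the null p₀ = 0.5.

p₀ = 0.5 encodes "a significantly correlated target is equally likely to be
inverse or positive under no regulation".  The tested proportion is
x/n = n_inverse/n_sig; testing the complementary fraction
(n_sig − n_inverse)/n_sig gives the identical two-sided p under p₀ = 0.5, so
the two phrasings are interchangeable.  A miRNA becomes a *candidate
regulator* iff its proportion p < `alpha_prop = 0.05` **and** the majority
call is YES (more inverse than positive targets).

Correlation pools all samples of both groups.  With 3 + 3 replicates this is
the only way to reach n = 6 observations per pair, and pooled-sample
anticorrelation is precisely the signal a repressor that responds to the
condition should leave.

## Statistical components

- **Spearman ρ** is the Pearson correlation of average ranks (ties get
  average ranks).  Constant vectors have undefined correlation: the pair is
  dropped and counted, never silently imputed.
- **Spearman p** is exact for n ≤ 8: the two-sided p is the fraction of all
  n! orderings of untied ranks with |ρ_perm| ≥ |ρ| − 1e−12 (the epsilon
  absorbs float noise at the discrete support).  The t approximation
  t = ρ·√((n−2)/(1−ρ²)) takes over for larger n, where it is accurate.  At
  n = 6 the exact null is very coarse: the smallest achievable two-sided p
  is 2/720 ≈ 0.0028 and the 5% two-sided critical value is |ρ| = 0.886.
  Tied observed ranks reuse the untied null, a deliberate approximation that
  is immaterial for continuous count-derived values.
- **One-proportion test**: continuity-corrected normal z (the convention of
  common clinical-statistics calculators), with the corrected numerator
  floored at 0 so x = n·p₀ gives z = 0, p = 1 exactly.  An exact binomial
  variant is available (`prop_method: exact`).
- **Clopper–Pearson interval**: Beta quantiles
  (B(α/2; x, n−x+1), B(1−α/2; x+1, n−x)), pinned to 0 at x = 0 and 1 at
  x = n; reported in percent at full precision, rounded only at table-write
  time (6 significant digits in TSVs).
- **Differential expression**: the default is the pooled-variance two-sided
  Student t on log2(CPM + 1), matching a replicated 3-vs-3 design; one-way
  ANOVA generalizes it to k groups (for 2 groups F = t² exactly); Fisher's
  exact test and Pearson's chi-squared on group-pooled counts serve
  replicate-free designs.  Significance uses the raw p by default —
  matching how small-sample miRNA screens are usually reported — with
  Benjamini–Hochberg adjustment behind a flag.
- **Normalization**: CPM, with TMM scale factors on by default
  (`normalization: cpm+tmm`).  TMM follows the standard recipe: reference =
  sample whose 75th-percentile count fraction is closest to the mean; M and
  A computed pairwise on features nonzero in both samples; rank-trim 30% on
  M and 5% on A; precision-weighted mean of M with inverse asymptotic
  variance weights; factors rescaled to geometric mean 1; fewer than 10
  usable features falls back to factor 1 with a warning.  TMM matters here:
  the simulator (like real placental libraries) contains a handful of
  extremely abundant miRNAs, and when those are differentially expressed,
  plain CPM transfers their shift onto every other feature.

## The simulator

`generate_dataset` emulates a two-group caloric-restriction-style study:
negative-binomial counts (variance μ + φμ², φ = 0.1) with log-normal
baseline means (ln-scale mean 6.0, sd 1.5 → median ≈ 400 counts), per-sample
library factors uniform on [0.7, 1.3], 1546 miRNAs and 5000 mRNAs over
3 + 3 samples.  15% of miRNAs get a planted ±2 log2 fold change; 16 of them
are regulators.  Regulators are re-seated into the abundance upper tail
(log-normal quantiles 0.997–0.9999) because the analysis design only ever
examines the top-100 most abundant miRNAs — regulators the selection stage
cannot see would make every downstream recovery number vacuously zero, and
the empirically reported regulator miRNAs in this literature (let-7 family,
miR-22, miR-26a, …) are indeed among the most abundant.

Each miRNA receives 20 predicted targets drawn without replacement;
regulator target sets are re-drawn disjoint from each other so every planted
pair has one unambiguous coupling sign.  75% of a regulator's targets are
inversely coupled, the rest positively: the target's per-sample log2 mean
shifts by ∓1.5·z_s, where z_s is the regulator's standardized latent log2
expression (baseline plus group shift).  The latent term is deterministic
given the design — no extra per-sample biological jitter is injected — so
coupling expresses itself as a clean between-group anticorrelation, which is
what a 3-vs-3 pooled Spearman can in principle detect.

What the simulator does **not** emulate: sequencing-depth heterogeneity
beyond a scalar library factor, batch effects, correlated biological
replicate structure, mRNA-intrinsic differential expression that is *not*
miRNA-driven, many-to-many regulation of a single gene, or sequence-level
target prediction (targets are abstract pairs).  Passing recovery tests
therefore demonstrate that the statistical machinery detects the planted
signal class, not that real placental data would behave as cleanly.

All draws flow from one `numpy.random.default_rng(seed)` in a documented
order, so a seed fully determines the dataset, and the run manifest (SHA-256
per output) makes end-to-end determinism checkable.

## Small-sample power of the proportion test

With 3 + 3 samples the integration stage is honest about how little six
observations can certify.  Two discrete bottlenecks stack:

1. the exact Spearman test at n = 6 needs |ρ| ≥ 0.886, i.e. near-perfect
   rank agreement *within* groups on top of complete between-group
   separation, so even a strongly coupled pair reaches per-pair
   significance only a minority of the time;
2. the continuity-corrected proportion test needs, e.g., 15 inverse of 20
   significant targets just to touch p = 0.044 — with the typical 4–7
   significant targets per miRNA that survive step 1, p < 0.05 is
   arithmetically out of reach (6 of 6 inverse gives p = 0.041; 5 of 5
   gives p = 0.074).

Consequently, on default-scale simulations the planted regulators rank at
the top of the proportion table with all-inverse target sets and YES calls,
but the candidate cut at `alpha_prop = 0.05` stays almost empty, and
regulator recall through the full pipeline is near zero at 3 vs 3.  The
direction calls and orderings — not the candidate count — carry the signal
at this design size; at 10 + 10 samples the same machinery recovers planted
regulators essentially perfectly.  This limitation is inherent to the
design size, and the package reports it rather than relaxing a threshold.

## Numerical conventions

- TSVs are UTF-8, Unix newlines, reals at 6 significant digits; writers are
  byte-deterministic.
- Percentages in DE summaries round half-up to 1 decimal (reporting
  convention); CI endpoints round only in tables.
- Identifiers match exactly and case-sensitively; an optional flag strips
  species prefixes (`mmu-`) when matching target maps from external
  databases.
- Degenerate inputs have defined outcomes: zero-variance features get
  t = 0, p = 1 (equal means) or p = 0 (unequal); zero margins give p = 1
  with a log note; empty called sets score precision 1.0 by convention;
  miRNAs with fewer than `min_targets = 2` significant targets are excluded
  from proportion testing and counted in the log.
- Test-suite simulations use reduced problem sizes (tens to hundreds of
  features) chosen so each property is measured at adequate power while the
  whole suite stays quick; the calibration and recovery acceptance checks
  run at the full default scale.
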