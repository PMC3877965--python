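# Methods

## The scoring model

`pathsurv` builds pathway-level survival signatures from three ingredients:
median dichotomization, univariate Cox coefficient signs, and an integer
score. For a pathway with genes g = 1…G surviving the gene-level log-rank
filter, the trained signature stores, per gene, the sign s_g ∈ {+1, −1} of
the univariate Cox partial-likelihood coefficient and the training-cohort
median m_g, plus one scalar cutoff c = median of the training cohort's
scores. A patient with expression x_g earns one point per gene whose value
lies on the hazard-increasing side of its median; the patient is called
High-risk when the total score is ≥ c. Nothing continuous is transferred
between cohorts — only signs, medians and an integer cutoff — which is the
design's bet on cross-platform robustness.

Two places need a "whose median?" decision:

- **Gene medians at scoring time** (`median_source`): default `cohort` —
  each scored cohort's own gene medians. Medians adapt to each platform's
  intensity scale, which is the only way the rule can work across arrays
  with different dynamic ranges; `signature` mode (stored training medians)
  is provided for within-platform use, and is what cross-validation uses,
  since both halves share one platform.
- **Score cutoff at transfer time** (`cutoff_mode`): default `training`
  (the frozen cutoff). When signature genes are missing from a platform the
  attainable score range shrinks, so training mode falls back to the scored
  cohort's median score (logged); `cohort` mode always uses the local
  median.

Ties follow one convention throughout: at-or-above goes High (median rule,
score cutoff, and tertile cuts alike). With 6+ tied integer scores at the
cutoff the High/Low split can be quite unbalanced; no correction is applied,
the group sizes are reported.

Genes whose Cox fit is degenerate (constant expression, no score
information) are dropped at training with a warning and contribute no
point in either direction.

## Statistical primitives

- **Log-rank test**: the standard two-group chi-square (1 df) from
  hypergeometric moments at each distinct event time; subjects censored at
  an event time remain at risk through it. Implemented as a batched numpy
  routine evaluating thousands of gene-wise group assignments against one
  outcome in a single pass; the test suite pins it to an independently
  coded brute-force oracle on all small datasets (exhaustively over
  labelings, n ≤ 8) and to lifelines on larger ones.
- **Univariate Cox**: Newton–Raphson on the Breslow partial likelihood,
  batched over genes via cumulative risk-set sums, step-clipped, |β| capped
  at 20. Separation or non-convergence falls back to the sign of the score
  statistic at β = 0 with the convergence flag cleared — only the sign
  feeds the pipeline, and the sign is tie-convention-invariant in practice.
  Wald p-values use the observed information at the optimum.
- **Kaplan–Meier and multivariate Cox** are thin lifelines wrappers; the
  median survival time is the earliest time the product-limit estimate
  drops to ≤ 0.5 (infinite when it never does).
- **Quantile normalization** replaces each sample's sorted values by the
  across-sample mean at each rank; within-sample ties get the mean of the
  reference values over the tied span (the dominant convention). With ties
  the shared-multiset property and idempotence hold only approximately —
  exactly in the tie-free case — which the tests state explicitly.
  Normalization is applied per cohort, never jointly: each platform's
  distributional quirks are removed against its own reference.
- **Probe collapsing** keeps only probes annotated to exactly one gene and
  averages probes per gene; multi-gene probes are dropped, not duplicated,
  so no gene inherits ambiguous signal.

## Validation machinery

**Cross-validated predictability.** Each of the `n_partitions` (default 50)
random halvings yields two evaluations (train A → test B and the reverse),
so 100 held-out log-rank tests per pathway. The gene filter is re-run
inside every training half, so a pathway's gene content legitimately varies
across folds. Odd cohorts split ⌈n/2⌉/⌊n/2⌋ with the larger half training
first, alternating across partitions. Folds that cannot be evaluated (a
zero-event half, an untrainable pathway, all scores on one side of the
cutoff) are skipped and the denominator is reported rather than silently
shrunk. Selection demands ≥ 10/100 significant at α/K and ≥ 30/100 at α.

This gate exists because the training-set screen is anti-conservative by
construction: the same cohort selects genes at p < 0.1, orients their
signs, and then tests the resulting score. Under a global null most
screened catalogs still produce a Bonferroni-passing pathway, and the
acceptance suite asserts this optimism directly rather than pretending the
screen p-value is calibrated. The held-out CV evaluations are calibrated
(their null significance frequency matches α within binomial error), and
the family-wise error of the full discovery rule — screen AND dual-threshold
CV selection — is controlled at the Bonferroni level.

**Resampling null.** Each replicate draws a same-size gene set uniformly
without replacement from the training cohort's full gene universe, trains
it exactly like a real signature (signs, medians, cutoff — but no gene
filter), transfers it to every evaluation cohort and counts cohorts with
p ≤ 0.05 (inclusive). The reported p-value is the fraction of replicates
whose count reaches the observed count. Sampling from the full universe
rather than the filtered pool is the conservative choice — a pre-filtered
pool would inflate null performance; a `gene_pool` argument lets callers
choose otherwise. Every replicate re-trains from scratch; degenerate
replicates count zero significances and are tallied.

## The synthetic-data generator

The generator is the package's study system: per-gene i.i.d. standard
normal expression; survival from an exponential proportional-hazards model,
hazard = `baseline_hazard` · exp(Σ β_g x_g) over the planted genes;
independent exponential censoring and/or an administrative cutoff; cohort
location/scale shifts applied after survival generation so platform
distortion never touches true risk; platform-missing genes emulated by row
deletion. Defaults emulate the multi-cohort microarray setting the pipeline
targets: 200 patients × 2,000 genes per cohort (multi-cohort runs use a few
hundred training patients and ~150 per external cohort), baseline hazard
0.02 events/month with censoring hazard 0.01/month (≈ 60% observed events
at these scales, typical of lung-cancer follow-up), and planted effects of
|β| = 1 per unit expression for a "strong" signature.

Any continuous expression distribution would do — the pipeline consumes
only medians and ranks — and the exponential baseline is the simplest
model satisfying the proportional-hazards assumption the Cox step exploits.
What the generator deliberately omits: gene–gene correlation blocks,
probe-level noise, non-proportional hazards, and informative censoring.
Passing tests therefore certify the pipeline's mechanics and calibration
under its own assumptions, not robustness to correlated real
transcriptomes.

The packaged 16-gene apoptotic-execution-phase catalog
(`load_example_signature`) ships as a realistic fixture: published gene
symbols with their reported association signs and gene-level log-rank
p-values, usable as a pathway of authentic size and sign mixture.

## Numerical and design choices

- Gene filtering retains p < 0.1 strictly; p ≥ 0.1 is excluded (boundary
  cases are measure-zero with continuous data). The threshold is loose on
  purpose: pathway aggregation needs enough member genes to retain meaning,
  and over-stringent filtering overfits single cohorts.
- Bonferroni divides by the catalog size K, whatever it is; 0.05/24 in the
  canonical 24-pathway screen.
- All tests are two-sided; log-rank ties use the exact hypergeometric
  moments (no approximation choice needed).
- Scores over missing genes are never rescaled — a 14-of-16-gene platform
  scores 0–14 and splits at its own median (≈ 7), preserving the
  half-the-genes interpretation of the cutoff.
- Tertile grouping cuts at the empirical 1/3 and 2/3 quantiles with the
  at-or-above convention; heavy integer ties give deterministic, possibly
  unequal groups, flagged when a group vanishes.
- The Wilcoxon comparison is High vs Low tertile — the extreme-group
  contrast that matches the score's monotone-risk interpretation.
- Pipeline seeds: one master seed, per-stage sub-seeds via
  `SeedSequence.spawn` (cross-validation, then resampling), echoed in the
  manifest; every output table header carries the seed and a config hash.
- Simulation scales in the test and acceptance suites (e.g. 200 null
  screens at 150 × 400, 500-replicate resampling, 150-partition CV
  calibration) were chosen so each check's Monte-Carlo error is small
  relative to the asserted band — 3σ binomial bands throughout.

## Known limitations

- Only the coefficient sign is transferred; magnitude information is
  discarded by design, costing power within-platform for robustness
  across platforms.
- The integer score's discreteness produces cutoff ties that can unbalance
  High/Low groups, lowering discriminating ability in small cohorts.
- The screen's training-set p-values must not be read as calibrated
  evidence (see above); discovery claims rest on the CV gate and external
  transfer.
- No stratified/weighted log-rank variants, time-varying covariates, or
  proportional-hazards diagnostics; the multivariate Cox wrapper is a
  reporting convenience, not a modelling framework.
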