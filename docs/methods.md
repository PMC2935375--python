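# Methods

## Study design being modelled

The package analyses (and simulates) a two-cohort, two-region expression
study of the Flinders rat model of depression. Two cohorts of animals are
bred six months apart: cohort 1 with 12 FRL and 9 FSL animals, cohort 2
with 10 FRL and 8 FSL. Both the hippocampus (HIP) and prefrontal/frontal
cortex (P/FC) are profiled from every animal; array labelling is performed
in two batches per cohort, so batch is nested within cohort and never
crosses it. The forced-swim test (5-minute scored exposure; immobility in
seconds is the readout) is run on every animal before tissue collection.

## Differential-expression model

Each probeset's log2 intensity is modelled by fixed-effects least squares:

    y = mu + line + cohort + line:cohort + batch(cohort) + e

with full-rank treatment coding. Three FSL−FRL contrasts are tested from
the single full-data fit: within cohort 1 (`line[FSL]`), within cohort 2
(`line[FSL] + line[FSL]:cohort[2]`), and combined (the unweighted mean of
the two per-cohort differences — a least-squares-means style contrast that
is not driven by the cohorts' unequal sizes). All three share the pooled
residual variance with df = n − rank(X) (33 for the full design), giving
each probeset its own background-variability estimate. p-values are
two-sided from the t distribution; no multiple-testing correction is
applied in the core results because the replication filter is the error
control (Benjamini–Hochberg q-values for the combined contrast are emitted
as an extra column for convenience).

Batch is a *fixed* factor. With only two labelling batches per cohort a
random-effect variance component would be estimated from a single degree
of freedom and is unstable; in balanced designs the fixed- and mixed-model
line contrasts coincide. A REML random-batch variant would be a natural
extension but is not provided.

Fold changes use the signed convention: a log2 difference d maps to
+2^d when d ≥ 0 and −2^(−d) otherwise, so the magnitude is always ≥ 1 and
the sign says which line is higher (+ = higher in FSL).

### Preprocessing

* **Normalisation**: each array is scaled so its median intensity equals
  the global median of array medians. This is a deliberately transparent
  stand-in for heavier cross-array normalisation engines; it preserves
  within-array structure exactly and can be switched off for
  pre-normalised input.
* **Expression filter**: a probeset is kept only if its intensity exceeds
  30 (strictly) in at least 50% of the samples of *each* line, lines
  pooled across cohorts. Both threshold and fraction are configurable.
  Whether the original analysis pooled cohorts for this filter is not
  documented; pooling is this package's choice.
* **Log transform**: log2 after flooring intensities at 1, so sub-unit
  background cannot produce negative-infinite values.

### Chance expectations and replication

`expected_chance_count(N, alpha, k) = N·alpha^k` is the expected number of
probesets passing k independent α-level criteria under the global null.
The replicated set of a region is {p_cohort1 ≤ α} ∩ {p_cohort2 ≤ α}
(ties inclusive); concordance is the fraction of the replicated set whose
per-cohort fold changes share a sign. The cross-region report intersects
the two regions' replicated sets and quotes the share of the HIP
replicated set; its chance expectation uses k = 3 (each additional
criterion beyond the first multiplies the expectation by α), matching the
convention the N·α^k numbers are usually quoted with. Expected counts are
presented half-up-rounded, with the raw value always retained. N defaults
to the probesets actually tested; a switch allows the full-array
N = 31,099 to reproduce printed expectations.

**Known deviation from the idealised formula**: because the per-cohort
tests of one probeset share the pooled residual-variance estimate, they
are positively dependent under the null — a probeset whose variance is
underestimated tends to pass in both cohorts. At these degrees of freedom
the realised null intersection runs roughly 30% above N·α², so N·α² is a
slightly conservative chance benchmark (the discrepancy shrinks as
residual df grow). Tests assert the intersection within Poisson bounds,
which accommodate this.

## qPCR arm

Quantification is absolute. Each assay has a standard curve fitted by
least squares to a genomic-DNA dilution series, Ct = intercept +
slope·log10(copies); a valid curve has slope < 0, and the amplification
efficiency is 10^(−1/slope) − 1 (−3.32 cycles per decade ⇔ 100%
efficiency, i.e. perfect doubling). Replicate Cts are averaged per sample
before inversion; copies are reported per 10 ng of RNA input, floored at
0.5 copies so non-detects survive the log transform. A reverse-
transcriptase-minus control within 5 cycles of the test Ct flags possible
genomic-DNA contamination.

RNA-loading differences move every assay of a sample together, so they are
estimated from invariant (housekeeper-like) genes: the loading score is
the first principal component of the samples × invariant-assays matrix of
log2 copies (column-centred; sign fixed so a higher score means more RNA).
The score enters each assay's ANOVA as a continuous covariate rather than
as a divisor, so its coefficient — and therefore the degree of correction
— is estimated per assay. Invariant genes can be nominated directly or
selected from the array data (`select_invariant`: well expressed above a
configurable quantile, coefficient of variation below a bound, all line
contrasts clearly non-significant, ranked by CV). The per-assay model is
otherwise identical to the expression model, fitted on log2 copies, with
the same three contrasts and signed fold changes.

## Behavioural arm

Per cohort, immobility is tested with the classical one-way F
(MS_between/MS_within, df (1, n−2)). `anova_from_summary` reconstructs
this F exactly from group means, SEMs and sizes — SD_i = SEM_i·√n_i,
SS_within = Σ(n_i−1)SD_i², SS_between = n₁n₂/(n₁+n₂)·(Δmean)² — because
the one-way F is a function of those summaries alone; reconstructing from
published summaries (160.3±15.6 s, n=9 vs 98.1±14.5 s, n=12) reproduces
the published F(1,19) = 8.31 to within rounding of the printed values.
The combined analysis is an additive line + cohort model without
interaction (38–39 animals with three estimated means leave n−3 residual
df), using type-II sums of squares from statsmodels.

## Synthetic-data generator

`generate_study` emulates the study's statistical structure with known
ground truth. For probeset g and sample s:

    intensity = max(floor, 2^(baseline_g + effect_g·[s is FSL]
                              + cohort_offset_g + batch_offset_g + noise))

* **Baselines** are log2-normal (mean 7, SD 2 — a realistic microarray
  dynamic range in scanner units where 30 is near background).
* **Line effects**: each probeset is truly DE with probability `frac_de`
  (default 0.1). Effects come from a bulk/tail mixture — 95% from a
  truncated normal with |log2FC| < 1 (most real changes are sub-2-fold),
  5% from a uniform tail between 2-fold and 40-fold, mirroring the rare
  extreme differences the model shows. A DE probeset affects both regions
  with probability `frac_shared_regions` (default 0.6, the order of the
  observed cross-region share), otherwise one region at random.
* **Technical structure**: gene-specific cohort and batch offsets (SD 0.1
  each on log2) and residual noise (SD 0.25); batches are assigned within
  cohort, stratified by line so both lines appear in every batch.
* **qPCR**: per-animal log2 loading factors ~ N(0, 0.25²) common to all
  assays; true copies follow the assay's configured FSL/FRL ratio; Cts
  follow a 100%-efficiency curve (slope −3.32, intercept 40) plus
  N(0, 0.15²) cycles per replicate, in triplicate; RT-minus controls sit
  at the 40-cycle ceiling; dilution series are noise-free (calibration
  error is not the phenomenon under study).
* **Swim times**: normal per line × cohort with the published means and
  SDs reconstructed from the published SEMs, truncated to [0, 300] s.

All randomness derives from one seed through spawned child streams;
identical (config, seed) pairs give byte-identical outputs.

**What the generator does not emulate**: probe-level (11-oligo) structure
and sequence-polymorphism hybridisation artefacts; heavy-tailed or
intensity-dependent noise; correlated gene modules; partial RNA
degradation. Passing tests therefore demonstrate the pipeline's
correctness and calibration under the design's assumptions, not
robustness to every pathology of real arrays.

## Numerical choices and problem sizes

* Exact-fit residuals below 1e−20 of the response's scale are snapped to
  zero so the zero-variance contract (p = 0 with a warning flag) triggers
  deterministically.
* p-values are clipped into (0, 1] at the smallest positive float.
* Expected-count presentation rounds half-up; raw values are retained.
* Probesets near the intensity floor have attenuated effect estimates
  (clipping compresses the FSL−FRL difference); recovery tests therefore
  use well-expressed baselines, and real analyses should trust fold
  changes of near-background probesets less.
* Test-suite and acceptance-script simulations use 1,500–10,000 probesets
  and 30–40 replicate studies — sizes chosen so every Monte-Carlo bound
  asserted is comfortably informative while the whole suite runs in well
  under a minute on one core.

## Known limitations

* Fixed-effects batch adjustment only; no REML variance components.
* No empirical-Bayes variance moderation (each probeset stands alone, as
  in the original design); low-df variance estimates make the per-cohort
  null intersection modestly exceed N·α² (see above).
* The median-scaling normalisation corrects only global level shifts, not
  intensity-dependent (banana-shaped) distortions.
* qPCR efficiency is assumed constant across the calibration range.
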