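# Methods

## The quantities

`gazentropy` analyzes visual scanning over a small set of areas of interest
(AOIs) as a first-order Markov chain. A trial's fixation stream is mapped to
an AOI symbol sequence; consecutive same-AOI fixations are (by default)
collapsed into dwells, and the chain is summarised by the simple viewing
probabilities `p_i` and the row-conditional transition matrix `p_ij`. Two
Shannon measures follow:

- **Stationary gaze entropy (SGE)**: `H_s = -Σ_i p_i log2 p_i`. High SGE
  means gaze mass is spread evenly across the AOIs; low SGE means gaze
  concentrates on few of them.
- **Gaze transition entropy (GTE)**:
  `H_t = -Σ_i p_i Σ_j p_ij log2 p_ij`. High GTE means the next AOI is hard
  to predict from the current one (exploratory, flexible scanning); low GTE
  means stereotyped scan patterns.

Both use base-2 logarithms (bits) and the continuity convention
`0·log 0 = 0`; rows of `p_ij` without observed outgoing transitions
contribute nothing. Because published magnitudes cannot always be attributed
to a convention, raw bits and normalized values are always reported
together. Normalization divides by `log2(n)` for SGE and, when
self-transitions are structurally excluded by collapsing, by `log2(n-1)` for
GTE (with three AOIs, `log2 2 = 1`, so collapsed GTE bits and normalized GTE
coincide).

## Conventions that change the numbers

Three analysis choices materially affect GTE and are explicit flags:

- `collapse` (default on): merge runs of same-AOI fixations so
  self-transitions are excluded. This follows the transition-entropy
  tradition of treating the dwell, not the fixation, as the chain step.
- `offaoi_policy` (default `drop`): fixations outside every AOI are removed
  (counted, not silently lost) so the alphabet stays the task AOIs.
  Dropping happens *before* collapsing, so an off-AOI interruption inside
  one task region does not manufacture a self-transition; the reverse order
  is available for sensitivity analysis.
- `p_i_estimator` (default `visit_frequency`): simple relative frequency of
  symbols in the (collapsed) sequence. `dwell_weighted` and
  `left_eigenvector` (stationary distribution of the estimated `p_ij`) are
  offered for sensitivity analysis.

AOI rectangles are half-open, `[x_min, x_max) × [y_min, y_max)`, so every
screen point belongs to exactly one AOI or to the off-AOI complement with no
tie-breaking. An I-DT dispersion-threshold detector (defaults 50 px,
100 ms) is available for raw gaze samples but is never applied implicitly
to fixation-level input.

## Inference layer

Condition effects are tested with a 2 (communication frequency, between
participants) × 2 (tracking difficulty, within participants) split-plot
ANOVA — the standard fit is delegated to `pingouin.mixed_anova` — giving
F(1, N−2) per effect and generalized eta-squared
`η²G = SS_effect / (SS_effect + SS_error_between + SS_error_within)`, the
effect size appropriate when a design mixes within- and between-subject
factors. Participants whose system-monitoring error rate exceeds 0.50
(strictly above) are excluded before estimation, so a 40-person cohort with
one forced poor monitor analyzes as N = 39 with error df 37.

Bayes factors use the BIC identity
`BF10 = exp((BIC_null − BIC_alt)/2) = (1 + df1·F/df2)^{n/2} · n^{−df1/2}`
with `n` = number of participants. This is a unit-information
approximation: it orders evidence like a default-prior Bayes factor but is
not numerically identical to one, and it is labeled as such. Evidence
labels follow the standard half-decade Jeffreys bands (3.16, 10, 31.6, 100,
with reciprocal bands "for null"). Note that some published reports label
BF₁₀ ≈ 17.5 "very strong" although it falls in the standard 10–31.6
"strong" band; this package applies the standard bands.

Confidence intervals on condition margins are between-subject t-intervals
on participant-level values (each participant contributes their mean at
that margin); no within-subject (Cousineau–Morey) correction is applied.

## The synthetic cohort generator

No participant-level gaze data are publicly deposited for this paradigm, so
the generator produces cohorts with the statistical skeleton the analysis
assumes, matching the study design's printed composition:

- 40 participants (split 20/20 between communication-frequency groups), two
  20-minute trials each, one per difficulty level in randomized order;
- monitoring-aid schedules of 28 Hit + 12 false-alarm alerts per trial
  (70% aid reliability) at uniform-random times with ≥ 5 s separation;
- 16 (High) vs 4 (Low) auditory communication events with ≥ 30 s
  separation; each event pulls the first fixation within 2 s onto the
  communication AOI, an interruption-driven switch;
- gaze as a zero-diagonal Markov chain over the three AOIs (tracking,
  system monitoring, communication) with a cell-specific transition matrix;
  one fixation per visit, coordinates uniform in the AOI rectangle;
- log-normal dwells (median 400 ms, σ_log 0.5 — a standard heavy-tailed
  stand-in for fixation durations), 30 ms saccade gaps;
- off-AOI fixations *inserted* between visits at rate 0.02, so the default
  drop-then-collapse pipeline recovers the underlying visit chain exactly;
- monitoring error rates from a moment-matched Beta (mean 0.12, sd 0.08),
  with one random participant forced above 0.50 by default to exercise the
  exclusion rule;
- per-participant heterogeneity as logit-normal offsets (sd 0.30) on each
  row's transition probability, drawn once per participant and applied to
  both trials — a random intercept, so the within-participant difficulty
  contrast stays paired.

All randomness derives from a single cohort seed through
`numpy.random.SeedSequence` substreams (per participant, then per trial),
so identical seeds give bit-identical cohorts and any trial is reproducible
in isolation.

### Choosing the default transition matrices

Each cell's matrix has the structure "tracking ↔ monitoring alternation
with occasional excursions to communication", parameterized by the
excursion probabilities. A feasibility analysis shaped the defaults: for a
zero-diagonal 3-state chain the stationary mass of any AOI cannot exceed
1/2, so normalized SGE is bounded below by `1/log2 3 ≈ 0.63`, and jointly
with normalized GTE near 0.2 the reachable SGE floor is ≈ 0.71. Published
normalized SGE values near 0.58 alongside GTE near 0.19 are therefore not
jointly attainable once self-transitions are excluded — an indication that
such values come from calculators that retain self-transitions. The
defaults were solved so analytic normalized GTE is exactly 0.245 / 0.215 /
0.200 / 0.170 in the Easy-High / Easy-Low / Difficult-High / Difficult-Low
cells (margins 0.230 vs 0.185 for difficulty, 0.2225 vs 0.1925 for
communication frequency), with analytic normalized SGE falling on the
feasible boundary (0.756 / 0.742 / 0.735 / 0.720). Both orderings — Easy >
Difficult and High > Low — hold for both measures, the directions reported
for this paradigm.

The communication-event pull adds transitions the chain itself would rarely
produce, raising estimated GTE in High-frequency cells by roughly
0.03–0.05 bits. This is intentional — interruption-driven switching is the
mechanism hypothesized to raise entropy under frequent communication — but
it means estimator-recovery checks are run with the pull disabled
(`n_comm_messages = 0`), where the generating chain is the analytic truth.
Under those conditions the full pipeline recovers per-cell analytic SGE/GTE
with mean bias below 0.01 bits; the residual bias combines the plug-in
entropy estimator's finite-sample bias and the Jensen gap of averaging
entropies over jittered participant matrices (≈ 0.004 bits at sd 0.30).

### What the generator does not emulate

Real eye data have smooth pursuit on the tracking task, center-of-AOI
biases, dwell/transition dependence, task-event-locked dynamics beyond the
communication pull, and drift/noise in AOI assignment. Passing tests show
the estimators and inference layer are correct and well-calibrated under
the assumed Markov structure — not that real scanning is first-order
Markov, nor that empirical entropy values will match the analytic targets.

## Verification problem sizes

The default test suite and `scripts/acceptance.py` size their simulations
as follows: chain recovery at 10^5 transitions (100 seeds in the suite, 30
in the script; error < 0.01 bits required in ≥ 95%); end-to-end cohort
recovery over 100 (suite) / 30 (script) cohorts at the default 1200-s
trials; directional replication over 200 (suite) / 100 (script) cohorts at
600-s trials — the shortest length that accommodates the full default event
composition (16 messages at ≥ 30 s separation), with the full 40-person
design. Oracle equivalence uses 1000 random sequences (transition counting
vs brute-force pair counting, exact) and 50 random balanced designs (ANOVA
vs a from-scratch sums-of-squares decomposition, 1e-8).

## Numerical notes and edge cases

- Probability vectors are validated to sum to 1 within 1e-9; supported rows
  of `p_ij` within 1e-12.
- Sequences shorter than 2 symbols raise an insufficient-data error naming
  the trial; trials whose fixations are all off-AOI raise an
  empty-sequence error rather than returning an empty chain.
- Unvisited AOIs keep all-zero rows in `p_ij` and zero mass in `p_i`; they
  contribute nothing to either entropy.
- The left-eigenvector estimator takes the eigenvector of `p_ijᵀ` closest
  to eigenvalue 1, clipped and renormalized; for reducible chains this
  selects one recurrent class.
- Constant-valued ANOVA input (zero variance everywhere) is reported as
  F = 0, η²G = 0 for all effects rather than 0/0.
- Aggregated condition matrices are unweighted means over trials (each
  trial counts equally regardless of its transition count), so aggregate
  rows need not sum to 1.

## Known limitations

- The BIC Bayes factor is not a default-prior (JZS) Bayes factor; treat its
  magnitude as indicative.
- GTE/SGE are first-order, stationary summaries: no higher-order structure,
  no time-resolved (sliding-window) entropy, no non-stationarity handling.
- Exact AOI pixel geometry of the original display is not published; the
  bundled layout is a plausible reconstruction on a 1920×1080 canvas and
  only matters for the synthetic generator, not for user-supplied data.
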