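# gazentropy

Entropy-based analysis of visual scanning over areas of interest (AOIs),
for researchers studying attention allocation in multitasking environments
(supervisory control, aviation, driving, MATB-II-style task batteries).

Conventional gaze summaries such as percent dwell time describe *where*
operators look but not *how* their gaze moves. `gazentropy` models the
scanpath as a first-order Markov chain over AOIs and computes two
information-theoretic summaries:

- **Stationary gaze entropy (SGE)** — the Shannon entropy of the AOI
  viewing distribution, `H_s = -Σᵢ pᵢ log₂ pᵢ`: how evenly gaze is spread
  over the display.
- **Gaze transition entropy (GTE)** — the stationary-weighted conditional
  entropy of the transition matrix,
  `H_t = -Σᵢ pᵢ Σⱼ pᵢⱼ log₂ pᵢⱼ`: how unpredictable the next gaze target
  is given the current one. Low GTE indicates stereotyped, highly
  structured scanning; high GTE indicates flexible or exploratory
  switching.

Around the estimators the package provides the full study pipeline:
fixation/AOI file I/O, optional I-DT fixation detection, dwell collapsing
and off-AOI handling, per-condition transition-matrix aggregation, a
2 (between) × 2 (within) mixed-design ANOVA layer with generalized
eta-squared and BIC-approximate Bayes factors, and a synthetic cohort
generator that emulates a MATB-II-like experiment (three task AOIs,
70%-reliable monitoring aid with 28 Hit + 12 false-alarm alerts per
20-minute trial, 16 vs 4 auditory communication interruptions) so the whole
pipeline is testable without access to participant data.

## Worked example

```python
from gazentropy import GazeEntropyModel, CohortDesign

model = GazeEntropyModel.from_simulation(CohortDesign(seed=7))
results = model.fit()
print(results.summary())
```

prints

```
Gaze entropy analysis
================================================================
participants analyzed: 39 (excluded: P028)
trials: 78   AOIs: 3
conventions: collapse=True, offaoi_policy=drop, p_i=visit_frequency

-- gte_norm --
  difficulty=Difficult     mean 0.2117  95% CI [0.1989, 0.2245]  n=39
  difficulty=Easy          mean 0.2569  95% CI [0.2419, 0.2719]  n=39
  comm_frequency=High      mean 0.2624  95% CI [0.2489, 0.2758]  n=19
  comm_frequency=Low       mean 0.2077  95% CI [0.1918, 0.2236]  n=20
  between_main  F(1,37) =    29.95  eta2_G = 0.414  BF10 = 1.69e+04 (decisive)
  within_main   F(1,37) =   138.53  eta2_G = 0.325  BF10 = 2.45e+12 (decisive)
  interaction   F(1,37) =     0.29  eta2_G = 0.001  BF10 = 0.187 (substantial (for null))

-- sge_norm --
  difficulty=Difficult     mean 0.7381  95% CI [0.7324, 0.7439]  n=39
  difficulty=Easy          mean 0.7595  95% CI [0.7527, 0.7662]  n=39
  comm_frequency=High      mean 0.7598  95% CI [0.7537, 0.7660]  n=19
  comm_frequency=Low       mean 0.7383  95% CI [0.7303, 0.7463]  n=20
  between_main  F(1,37) =    19.68  eta2_G = 0.318  BF10 = 655 (decisive)
  within_main   F(1,37) =   138.90  eta2_G = 0.315  BF10 = 2.55e+12 (decisive)
  interaction   F(1,37) =     0.19  eta2_G = 0.001  BF10 = 0.177 (substantial (for null))
```

Reading the output: one simulated participant of the 40 recruited exceeded
the 50% monitoring-error exclusion threshold, leaving N = 39 and the error
df of 37 for each F test. Gaze was less random under Difficult tracking
(normalized GTE 0.21 vs 0.26; SGE 0.74 vs 0.76, Easy > Difficult) and more
random under frequent communication interruptions (High > Low on both
measures) — the condition orderings the generator injects through its
cell-specific transition matrices and interruption-driven switches.

Real data enter the same way from files:

```python
model = GazeEntropyModel.from_files("fixations.csv", "aoi_layout.yaml",
                                    participants_path="participants.csv")
results = model.fit()
results.per_trial               # tidy per-trial entropy table
results.condition_matrix("difficulty", "Easy")   # mean transition matrix
results.anova("gte_norm")       # mixed ANOVA for one measure
results.plot_condition_matrices()
```

The same pipeline is scriptable from a shell:

```bash
gazentropy simulate --seed 7 --outdir cohort/
gazentropy analyze --fixations cohort/fixations.csv \
    --layout cohort/aoi_layout.yaml --participants cohort/participants.csv \
    --outdir out/
gazentropy run --seed 7 --outdir out/        # end-to-end in one step
```

Every run writes tab-delimited tables (per-trial entropies, per-condition
transition matrices, ANOVA reports) plus a `manifest.json` with the seed
and conventions; identical seed and configuration reproduce outputs
byte-for-byte.

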