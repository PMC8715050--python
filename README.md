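# saccvigor

Simulation and analysis of incentive effects on saccadic effort.

## The problem

In speeded eye-movement tasks, monetary incentives modulate how much
oculomotor effort people invest: with more money at stake, observers make
saccades more frequently, hit more targets, and move their eyes faster than
their own stereotyped amplitude–velocity relationship predicts — even when the
reward cue is masked to the edge of conscious perception.  Quantifying these
effects requires a pipeline with several fragile stages: saccade detection
from noisy gaze traces, main-sequence fitting, within-subject effort metrics,
reward scoring, awareness criteria, and repeated-measures inference.  Errors
in any stage silently bias the result.

`saccvigor` implements that pipeline for a paradigm in which observers make
back-and-forth saccades for 8 s between a central fixation cross and 18
peripheral targets (radius 0.75°, eccentricity 11.5°, drawn per trial from 42
candidate ring locations), after seeing a masked 1- or 50-cent coin at one of
three display durations.  Crucially, every stage is testable: the package
ships a synthetic-gaze generator whose traces carry full ground truth (true
saccade times, amplitudes, peak velocities, and injected condition effects),
so detection, metrics, and statistics are all validated by parameter
recovery rather than by eyeballing.

## The core quantities

* **Saccade detection.** Positions are smoothed with a Savitzky–Golay filter
  (order 2, 20 ms support); 2-D velocity comes from central differences.  The
  *fixed-threshold* detector marks onsets where speed exceeds 35°/s; the
  *adaptive* detector sets per-trial thresholds at mean + 4 SD (peak) and
  mean + 2.5 SD (onset/offset) of the trial's velocity noise, estimated
  iteratively.  Events shorter than 10 ms or closer than 40 ms to the
  previous one are discarded.

* **Main sequence and vigor.** Per subject, peak velocity *v* versus
  amplitude *x* of all saccades is fit with the hyperbola

      v(x) = α · (1 − 1 / (1 + β·x)),

  and each condition's **vigor** is the ratio of the measured to the expected
  mean peak velocity — a within-subject effort measure above and beyond
  amplitude (vigor > 1: faster than this person's typical saccade).

* **Reward scoring.** A trial's payout for LT of NT hit targets is

      gained = coin · (10^(LT/NT) − (1 − LT/NT)) / 10,

  i.e. 0 with no hits, the full coin with all 18, convex in between.

* **Awareness.** 4AFC coin-identification tables are scored with group-level
  one-tailed t tests (correct vs 50% chance, "seen" vs 0) and per-subject
  exact one-sided binomial tests.

* **Inference.** Repeated-measures ANOVA (contrast formulation) with
  Greenhouse–Geisser correction, a mean-centred between-subject visibility
  covariate, partial η², and Bonferroni-corrected paired post hocs with
  Cohen's d_z.  Sample-size planning inverts the noncentral-t power function
  of the paired t test.

## Worked example

```python
from saccvigor.pipeline import PipelineConfig, run, report

cfg = PipelineConfig(seed=7, n_subjects=8, n_blocks=1, trials_per_block=12)
bundle = run(cfg)
print(bundle.anova_tables["frequency"].head(2).to_string(index=False))
```

prints (frequency ANOVA, first effects):

```
                  effect        F  df1  df2  epsilon     p_gg   eta_p2
            reward_cents 4.654178  1.0  6.0      1.0 0.074348 0.436841
 reward_cents:visibility 0.059839  1.0  6.0      1.0 0.814901 0.009875
```

The generator injected a within-subject reward effect on saccade frequency
(calibrated to d_z = 0.65) and ±1% velocity gains; at this small demo size
(8 subjects, 12 trials) the frequency effect is visible but not significant
(F(1,6) = 4.65, p = 0.074), while the vigor post hoc recovers the injected
±1% gain almost exactly (mean high−low difference ≈ 0.02, i.e. 1.01 vs 0.99).
`report(bundle)` renders the full condition summary, e.g.

```
### frequency
- 1 cents, 100 ms: 31.375 +/- 2.912
- 50 cents, 100 ms: 32.375 +/- 2.475
```

Single computations work directly, with the same numbers the task displays:

```python
>>> from saccvigor.reward_task import gained_reward
>>> gained_reward(50, 12, 18)      # 12 of 18 targets on a 50-cent trial
21.541277501397225
>>> from saccvigor.awareness_stats import required_n_paired_t
>>> required_n_paired_t(dz=0.65, alpha=0.05, power=0.8, tails="one")
17
```

A CLI mirrors the library: `saccvigor simulate | detect | reward | awareness |
power | run | config init` (see `saccvigor --help`).

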