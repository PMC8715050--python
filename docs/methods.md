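# Methods

## The task being simulated

Each 8-s trial of the speeded saccade task presents 18 circular targets
(radius 0.75°) at 11.5° eccentricity, drawn without replacement from 42
candidate locations, around a central fixation cross.  The observer
alternates between fixation and targets; a target counts as hit when gaze
enters a criterion radius (1.2° online, 2.4° in offline re-analysis) and the
fixation zone (2.5°) must be re-entered between hits.  Payout per trial is
`coin · (10^(LT/NT) − (1 − LT/NT))/10` for LT of NT targets hit, with coin
values of 1 or 50 cents cued — possibly below the awareness threshold — at
display durations of 17 ms, an individual threshold duration, or 100 ms.
The experiment runs 5 blocks of 42 trials, counterbalanced to 35 trials per
reward × duration cell.

## Synthetic gaze generator

The generator is first-class, tested code: it is the oracle against which
every analysis stage is validated.

**Saccade waveform.** Each saccade has a half-sine speed profile
`v(t) = v_p · sin(π t / D)` with duration `D = π·A / (2·v_p)`, so the
integrated path length equals the amplitude A exactly and the speed is zero
at both endpoints with a single interior peak.  The half-sine was chosen over
profiles with quadratic takeoff (e.g. raised cosine) for two reasons: its
duration–amplitude ratio `v_p·D/A = π/2 ≈ 1.57` is close to the ~1.6–1.7 seen
in human saccades (a raised cosine gives 2.0, implying unrealistically long
saccades), and its linear velocity rise puts the 35°/s threshold crossing
within ~1 ms of true movement onset, matching how quickly real saccades
become detectable.  Peak velocity follows the hyperbolic main sequence
`v_p = g · α(1 − 1/(1 + βA))`, with g a condition-specific gain.

**Trial assembly.** Gaze alternates fixation → target → fixation.  Target
choice prefers unvisited targets with probability 0.6 (otherwise uniform),
which reproduces realistic hit counts (~12–14 of 18) without scripting a
fixed scan path.  Landing points scatter around the destination with
isotropic SD 0.6°; when a target landing misses the online hit radius
(1.2°), a corrective saccade to the target centre follows with probability
0.5.  Intersaccadic pauses are truncated-normal (SD 50 ms, floor 60 ms); the
floor guarantees that no ground-truth event can be discarded by the
detectors' 40-ms minimum-ISI rule, keeping recovery scores interpretable.
Measurement noise is iid Gaussian per sample and axis (default 0.02°,
typical of a video eye tracker after calibration).

**Population defaults** target the scale of published group data for this
kind of task: baseline frequency 31.5 ± 3.3 saccades/trial, α = 560°/s
(SD 40), β = 0.25/° (SD 0.03) — giving peak velocities near 390–420°/s at
10–11.5° amplitudes — and per-subject 4AFC visibility probabilities of
roughly 0.61 / 0.85 / 0.995 correct at the three durations.

**Effect calibration.** The reward effect on frequency is injected as
per-subject gains `1 ± δ_i/2` (high/low reward) with `δ_i ~ N(c, σ_g)`,
σ_g = 0.03.  For baseline frequency `f ~ N(μ_f, σ_f)` the paired difference
`d = f·δ` has `d_z = μ_f c / sqrt((μ_f² + σ_f²)σ_g² + σ_f² c²)`; inverting
for a target d_z gives

    c = d_z σ_g · sqrt((μ_f² + σ_f²) / (μ_f² − d_z² σ_f²)).

At the default d_z = 0.65 this yields c ≈ 0.020, i.e. a ~2% frequency gain —
about 0.6 extra saccades per trial, the order of magnitude such experiments
report.  Velocity gains are symmetric multipliers (default 1.01/0.99) around
1, because vigor is measured relative to the subject's own pooled main
sequence: a condition can only be faster than the subject's average if
another is slower.

**Randomness.** One master seed; per-subject and per-trial streams are split
with `numpy.random.SeedSequence`, so any subset of the data is reproducible
in isolation and datasets are byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: post-saccadic oscillations and glissades, smooth
pursuit or drift during fixation, blinks and realistic dropout structure
(missing data enter only via validity flags), saccadic curvature, latency
dynamics, pupil size, and any masking/visibility psychophysics beyond
Bernoulli response generation.  Detector scores on synthetic traces are
therefore upper bounds on real-data performance, not estimates of it.

## Detection

Positions are smoothed with a Savitzky–Golay filter of order 2 and 20-ms
support per valid segment; 20 ms is 20 samples at 1000 Hz, an even number,
so the nearest odd width (21 samples) is used.  2-D speed is the norm of
central-difference derivatives of the filtered positions (one-sided at
segment ends); acceleration is the central difference of speed.  Detection
never crosses a gap of invalid samples.

**Fixed-threshold detector.**  Onset: first sample with speed > 35°/s.  The
event's *core* is the run of above-threshold samples; its reported offset is
the first later sample where speed is below threshold *and* |d(speed)/dt| is
below 1000°/s² (the eye has stopped decelerating).  A literal "acceleration
below 35" offset rule would mix units and, at 35°/s², never terminate inside
a trial, so the settling threshold is a separate configurable constant.  The
10-ms duration floor is applied to the core, not core + settling tail:
otherwise the tail would promote any brief noise spike past the floor,
defeating its purpose.  When two events are separated by less than 40 ms the
later one is discarded (discarding, rather than merging, keeps the first
onset's timing intact).

**Adaptive detector.**  Per trial, the peak threshold is mean + 4 SD and the
onset/offset threshold mean + 2.5 SD of the velocity samples.  Computed over
the raw trial these statistics are dominated by the saccades themselves (at a
~20% saccade duty cycle, mean + 4 SD exceeds the saccadic peaks and nothing
is detected), so by default the thresholds are estimated iteratively:
starting from 200°/s, mean and SD are recomputed over the samples below the
current threshold until it moves by < 1°/s, which converges onto the trial's
fixation-noise level.  Events grow outward from each above-peak-threshold
excursion to the onset-threshold crossings; the 10-ms duration floor and a
40-ms minimum preceding fixation apply.  The onset threshold is floored at
10°/s: below the smoothing filter's own leakage scale (the spurious ~5–10°/s
the 21-sample filter leaks within ±10 ms of a saccade edge) an adaptive
threshold stops being meaningful — the floor only binds on nearly noise-free
data.  The non-iterative, literal mean + k·SD variant remains available
(`AdaptiveConfig(iterative=False)`).

## Metrics

Frequency is the raw event count per trial, irrespective of landing
position.  Landing classification assigns each saccade endpoint to the
nearest destination (some target vs the fixation cross); the landing error is
the distance to that centre.  Hit counting walks the raw gaze samples with
the alternation rule (re-enter the 2.5° fixation zone between hits); each
target can be hit once; the offline radius (2.4°) applies the same rule by
default, switchable to "any close landing" via `requires_refixation=False`
since published descriptions of offline re-scoring are ambiguous on this
point.

The main-sequence fit is nonlinear least squares of `v = α(1 − 1/(1+βx))`
pooled over all of a subject's saccades (per detector), initialised at
α₀ = 1.1·max(v) with β₀ solved from the median point, bounds α ∈ (0, 5·max v],
β ∈ (0, 10], and two fallback starts.  It requires ≥ 20 saccades spanning
≥ 2° of amplitude (below that, α and β trade off freely).  Condition vigor is
the ratio of condition means — mean measured velocity over mean expected
velocity — not the mean of per-saccade ratios.

## Statistics

Frequency and peak velocity are z-scored within subject across all trials
(sample SD, n−1) before cell aggregation when a common scale is needed;
zero-variance subjects map to zeros rather than NaN.

The repeated-measures ANOVA uses the contrast (multivariate) formulation:
for each within effect an orthonormal contrast matrix C (Kronecker product
over factors) transforms the subject × cell matrix, and the transformed
responses are regressed on the between-subject design (intercept,
mean-centred covariate, optionally a group factor with centred treatment
codes).  The univariate F is the trace ratio of hypothesis and error SSCP
matrices; on balanced designs without a covariate this reproduces the
classical partitioned-SS table exactly (verified against both a brute-force
3-subject decomposition and pingouin to ~1e-9).  The Greenhouse–Geisser
epsilon is computed per effect from that effect's error covariance,
`ε = tr(Σ)²/(q·tr(Σ²))`, clipped to [1/q, 1]; it equals 1 identically for
2-level factors.  Epsilon scales the F test's degrees of freedom, leaving F
itself unchanged.  Partial η² is tr(H)/(tr(H)+tr(E)).  Covariate × within
interactions are included by default (switchable), since the visibility
covariate is scientifically expected to moderate the reward effect.  Up to
three within factors are supported (reward × duration × parameter type).

Two caveats discovered while validating and worth stating: the GG-corrected
p is only guaranteed ≥ the uncorrected p in the rejection region (for F well
below 1, shrinking both df can lower p — pingouin behaves identically); and
partial η² is exactly invariant to per-subject centring and global rescaling
of the measure, but *not* to per-subject rescaling, so z-scoring can shift
η² slightly between subjects of unequal variability.

Post hoc paired t tests are two-tailed by default (one-tailed available
where a directional hypothesis is prespecified), Bonferroni-corrected as
`min(1, m·p)`, with `d_z = mean(diff)/SD(diff)`.

Awareness: group tests are one-tailed (greater) one-sample t tests of
per-subject proportions against 50% (correct) and 0 ("seen"), with phases
pooled first; zero-variance cohorts are flagged degenerate and resolved by
direction.  The per-subject criterion is the exact binomial tail
`P(X ≥ k | n, 1/2)` with decision `p ≤ α` (boundary included, the
conventional reading).  `required_n_paired_t` scans n upward and returns the
first n whose noncentral-t power reaches the target; its bracketing property
(power(n) ≥ target > power(n−1)) is tested.

## Problem sizes used in validation

Detector recovery runs 1,000 synthetic trials per condition (~34,000
saccades); main-sequence recovery uses 2,000 saccades per subject and 50
seeds; the ANOVA type-I calibration uses 5,000 null cohorts of 20 subjects;
the power-link simulation 1,000 cohorts of 17; the binomial check enumerates
every n ≤ 200.  These sizes put Monte-Carlo standard errors comfortably
inside the asserted tolerances (e.g. SE ≈ 0.003 for the type-I rate against
a ±0.01 band) while keeping the whole validation suite at about a minute on
one CPU.

## Known limitations

Besides the generator gaps above: the detectors implement no glissade or
microsaccade handling and no blink reconstruction; EyeLink EDF/ASC files are
not parsed (gaze enters via the documented CSV dialect); the ANOVA requires
complete within-subject grids (no mixed-model fallback for missing cells);
and payouts are kept as exact real cents, with rounding left to
presentation.
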