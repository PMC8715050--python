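"""Parameter-recovery experiments: the package's own correctness yardsticks.

Every generator in :mod:`saccvigor.synthetic_gaze` carries its ground truth,
so each analysis stage can be scored against what was actually generated:
detectors against the true event list, the main-sequence fit against the
generating (alpha, beta), vigor against injected velocity gains, and the
statistics against their nominal error rates.  These routines are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effort_stats import posthoc_paired, rm_anova
from .gaze_io import GazeTrace
from .saccade_detect import detect_adaptive, detect_fixed
from .saccade_metrics import fit_main_sequence, vigor_ratio
from .synthetic_gaze import (
    AgentProfile,
    EffectSpec,
    TaskGeometry,
    main_sequence_velocity,
    make_layout,
    synth_experiment,
    synth_trial,
)

__all__ = [
    "DetectorScore",
    "match_events",
    "score_detector",
    "main_sequence_recovery",
    "vigor_recovery",
    "anova_type1_rate",
    "paired_power_rate",
]


@dataclass
class DetectorScore:
    sensitivity: float
    precision: float
    n_true: int
    n_detected: int
    onset_errors_ms: np.ndarray  # matched events only

    @property
    def max_abs_onset_error_ms(self) -> float:
        return float(np.max(np.abs(self.onset_errors_ms))) if len(self.onset_errors_ms) else np.nan


def match_events(truth_events, detected, tol_ms: float = 4.0):
    """Greedy one-to-one matching of detected to true saccades by onset time.

    A true event counts as recovered when some unused detection has its onset
    within ``tol_ms`` of the true onset.  Returns
    ``(n_matched, onset_errors)``.
    """
    used = set()
    errors = []
    for ev in truth_events:
        candidates = [
            (abs(d.onset_t - ev.true_onset), i)
            for i, d in enumerate(detected)
            if i not in used
        ]
        if candidates:
            err, i = min(candidates)
            if err <= tol_ms:
                used.add(i)
                errors.append(detected[i].onset_t - ev.true_onset)
    return len(used), np.asarray(errors)


def score_detector(
    detector: str,
    n_trials: int,
    noise_sd: float,
    seed: int,
    tol_ms: float = 4.0,
    geometry: TaskGeometry = TaskGeometry(),
) -> DetectorScore:
    """Event-level sensitivity and precision over seeded synthetic trials."""
    detect = {"fixed": detect_fixed, "adaptive": detect_adaptive}[detector]
    ss = np.random.SeedSequence(seed)
    tp = n_true = n_det = 0
    all_errors = []
    for trial_seq in ss.spawn(n_trials):
        rng = np.random.default_rng(trial_seq)
        agent = AgentProfile(noise_sd=noise_sd)
        layout = make_layout(geometry, rng)
        t, x, y, valid, events = synth_trial(layout, agent, (50, "100"), rng, geometry)
        det = detect(GazeTrace(t, x, y, valid, geometry.sampling_rate))
        matched, errors = match_events(events, det, tol_ms)
        tp += matched
        n_true += len(events)
        n_det += len(det)
        all_errors.append(errors)
    return DetectorScore(
        sensitivity=tp / n_true if n_true else np.nan,
        precision=tp / n_det if n_det else np.nan,
        n_true=n_true,
        n_detected=n_det,
        onset_errors_ms=np.concatenate(all_errors) if all_errors else np.array([]),
    )


def main_sequence_recovery(
    alpha: float = 560.0,
    beta: float = 0.25,
    n_saccades: int = 2000,
    velocity_noise: float = 0.0,
    n_seeds: int = 1,
    seed: int = 0,
):
    """Worst-case relative error of (alpha, beta) over seeded refits.

    Saccade amplitudes are drawn uniformly on [2, 20] deg and peak velocities
    from the hyperbolic law with optional multiplicative Gaussian noise.
    """
    worst = np.zeros(2)
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        x = rng.uniform(2.0, 20.0, n_saccades)
        v = main_sequence_velocity(x, alpha, beta)
        if velocity_noise > 0:
            v = v * (1.0 + rng.normal(0.0, velocity_noise, n_saccades))
        fit = fit_main_sequence(x, v)
        worst = np.maximum(
            worst,
            [abs(fit.alpha_hat - alpha) / alpha, abs(fit.beta_hat - beta) / beta],
        )
    return worst


def vigor_recovery(
    gain_high: float = 1.05,
    gain_low: float = 0.95,
    n_saccades: int = 2000,
    velocity_noise: float = 0.05,
    n_seeds: int = 50,
    seed: int = 0,
):
    """Mean recovered vigor of two conditions with injected velocity gains.

    One synthetic subject per seed: amplitudes span [2, 20] deg, half the
    saccades carry ``gain_high`` and half ``gain_low``; the main sequence is
    fitted on the pooled saccades (as in the per-subject analysis) and each
    condition's vigor is the measured/expected mean-velocity ratio.
    """
    recovered = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        x = rng.uniform(2.0, 20.0, n_saccades)
        base = main_sequence_velocity(x, 560.0, 0.25)
        cond = np.arange(n_saccades) % 2 == 0
        gains = np.where(cond, gain_high, gain_low)
        v = base * gains
        if velocity_noise > 0:
            v = v * (1.0 + rng.normal(0.0, velocity_noise, n_saccades))
        fit = fit_main_sequence(x, v)
        recovered.append(
            (vigor_ratio(x[cond], v[cond], fit), vigor_ratio(x[~cond], v[~cond], fit))
        )
    return np.mean(recovered, axis=0)


def anova_type1_rate(
    n_replicates: int = 5000,
    n_subjects: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    effect: str = "A",
) -> float:
    """Type-I error of the GG-corrected within effect on null cohorts.

    Each replicate draws iid normal cell values on a 2 x 3 within grid with an
    independent subject covariate; the rejection rate of the named effect at
    the given alpha is returned.
    """
    rng = np.random.default_rng(seed)
    idx = pd.DataFrame(
        [(s, a, b) for s in range(n_subjects) for a in ("a1", "a2") for b in ("b1", "b2", "b3")],
        columns=["subject", "A", "B"],
    )
    rejections = 0
    for _ in range(n_replicates):
        df = idx.copy()
        df["y"] = rng.normal(size=len(df))
        cov = dict(zip(range(n_subjects), rng.normal(size=n_subjects)))
        df["cov"] = df["subject"].map(cov)
        res = rm_anova(df, "y", ["A", "B"], "subject", covariate="cov")
        rejections += res.loc[res["effect"] == effect, "p_gg"].iloc[0] < alpha
    return rejections / n_replicates


def paired_power_rate(
    freq_dz: float = 0.65,
    n_subjects: int = 17,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts where the one-tailed reward contrast on
    true per-subject frequency means rejects at ``alpha``.

    Ties the analytic sample-size computation to simulation: at the generator's
    calibrated dz and its planning sample size the rate should sit near the
    planned power.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        data = synth_experiment(
            n_subjects,
            effects=EffectSpec(freq_dz=freq_dz),
            seed=int(rng.integers(2**31 - 1)),
            include_traces=False,
            include_afc=False,
        )
        ph = posthoc_paired(
            data.true_means,
            dv="true_frequency",
            condition="reward_cents",
            pairs=[(50, 1)],
            tails="one",
        )
        rejections += ph["p_raw"].iloc[0] < alpha
    return rejections / n_replicates
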