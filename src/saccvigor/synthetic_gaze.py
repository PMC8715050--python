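"""Task-structured synthetic gaze data with known ground truth.

Emulates a speeded multi-target saccade task: on every trial the eye
alternates for 8 s between a central fixation cross and 18 peripheral
targets placed on an 11.5 deg ring (drawn from 42 equally spaced candidate
locations).  Saccade kinematics obey a hyperbolic main sequence

    v_peak(x) = alpha * (1 - 1 / (1 + beta * x))

and each saccade is rendered as a half-sine speed profile (linear takeoff,
single peak, zero speed at both ends) of duration D = pi * x / (2 * v_peak),
so the integrated path length equals the amplitude exactly.  Condition
effects enter as multiplicative gains on saccade frequency and on peak
velocity, which is what downstream detectors and vigor metrics must recover.

Effect calibration
------------------
A per-subject reward contrast on frequency gain, delta_i ~ N(c, sigma_g),
is applied as gains 1 +/- delta_i/2 to the high/low reward conditions of a
subject with baseline frequency f_i ~ N(mu_f, sigma_f).  The paired
difference d_i = f_i * delta_i then has Cohen's dz = E[d]/SD[d], and the
mean contrast that yields a target dz is the closed form

    c = dz * sigma_g * sqrt((mu_f**2 + sigma_f**2) / (mu_f**2 - dz**2 * sigma_f**2))

implemented in :func:`gain_contrast_for_dz`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CohortError,
    CounterbalanceError,
    DegenerateWaveformError,
    InvalidGeometryError,
)

__all__ = [
    "TaskGeometry",
    "AgentProfile",
    "GroundTruthEvent",
    "PopulationParams",
    "EffectSpec",
    "ExperimentData",
    "main_sequence_velocity",
    "gain_contrast_for_dz",
    "make_layout",
    "make_schedule",
    "synth_saccade",
    "synth_trial",
    "synth_experiment",
    "synth_afc",
    "DURATION_LEVELS",
    "REWARD_LEVELS",
]

#: Display-duration condition labels: shortest (near-subliminal), individual
#: visibility threshold, and clearly visible.
DURATION_LEVELS = ("17", "D_indiv", "100")
#: Coin values in cents (low, high).
REWARD_LEVELS = (1, 50)

#: Minimum intersaccadic pause, ms (truncation point of the pause distribution).
MIN_PAUSE_MS = 60.0


def main_sequence_velocity(amplitude, alpha, beta):
    """Peak velocity (deg/s) predicted by the hyperbolic main sequence."""
    amplitude = np.asarray(amplitude, dtype=float)
    return alpha * (1.0 - 1.0 / (1.0 + beta * amplitude))


@dataclass(frozen=True)
class TaskGeometry:
    """Spatial and temporal layout of the saccade task."""

    n_candidates: int = 42
    eccentricity: float = 11.5  # deg
    target_radius: float = 0.75  # deg
    n_targets: int = 18
    hit_radius_online: float = 1.2  # deg, hit criterion used during the task
    hit_radius_offline: float = 2.4  # deg, more liberal offline criterion
    fixation_radius_online: float = 2.5  # deg, refixation zone
    trial_duration: float = 8000.0  # ms
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self):
        if self.n_targets > self.n_candidates:
            raise InvalidGeometryError(
                f"n_targets={self.n_targets} exceeds n_candidates={self.n_candidates}"
            )
        if self.trial_duration <= 0 or self.sampling_rate <= 0:
            raise InvalidGeometryError("trial_duration and sampling_rate must be positive")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration / self.dt_ms))


@dataclass
class AgentProfile:
    """Generating parameters of one simulated observer.

    ``freq_gain_by_condition`` / ``vel_gain_by_condition`` map a condition key
    ``(reward_cents, duration_condition)`` to a multiplicative gain; missing
    keys default to 1.
    """

    alpha: float = 560.0  # deg/s, main-sequence asymptote
    beta: float = 0.25  # 1/deg, main-sequence curvature
    isi_mean: float = 190.0  # ms, mean intersaccadic pause at gain 1
    isi_sd: float = 50.0  # ms
    landing_sd: float = 0.6  # deg, saccade end-point scatter
    noise_sd: float = 0.02  # deg, per-sample measurement noise
    corrective_prob: float = 0.5  # P(corrective saccade | landing outside hit zone)
    explore_prob: float = 0.6  # P(aim at a not-yet-visited target)
    freq_gain_by_condition: dict = field(default_factory=dict)
    vel_gain_by_condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for gains in (self.freq_gain_by_condition, self.vel_gain_by_condition):
            if any(g <= 0 for g in gains.values()):
                raise ValueError("condition gains must be positive")

    def peak_velocity(self, amplitude, vel_gain: float = 1.0):
        return vel_gain * main_sequence_velocity(amplitude, self.alpha, self.beta)


@dataclass(frozen=True)
class GroundTruthEvent:
    """Oracle label for one generated saccade."""

    true_onset: float  # ms
    true_offset: float  # ms
    true_amplitude: float  # deg
    true_peak_velocity: float  # deg/s
    destination: int  # target index, or -1 for the fixation cross

    def __post_init__(self):
        if self.true_offset <= self.true_onset:
            raise ValueError("true_offset must exceed true_onset")
        if self.true_amplitude <= 0:
            raise ValueError("true_amplitude must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_layout(geometry: TaskGeometry, rng_seed) -> np.ndarray:
    """Draw ``n_targets`` distinct positions from the candidate ring.

    Candidates are equally spaced on the circle of radius ``eccentricity``
    centred on the screen centre.  Returns an ``(n_targets, 2)`` array of
    (x, y) positions in degrees.
    """
    rng = _as_rng(rng_seed)
    angles = 2.0 * np.pi * np.arange(geometry.n_candidates) / geometry.n_candidates
    candidates = geometry.eccentricity * np.column_stack([np.cos(angles), np.sin(angles)])
    chosen = rng.choice(geometry.n_candidates, size=geometry.n_targets, replace=False)
    return candidates[chosen]


def make_schedule(
    n_blocks: int,
    trials_per_block: int,
    reward_levels=REWARD_LEVELS,
    durations=DURATION_LEVELS,
    rng_seed=0,
) -> pd.DataFrame:
    """Counterbalanced, randomly ordered trial schedule.

    Every (reward, duration) cell appears exactly
    ``n_blocks * trials_per_block / (len(reward_levels) * len(durations))``
    times over the experiment; order is shuffled with the given seed.
    """
    rng = _as_rng(rng_seed)
    reward_levels = list(reward_levels)
    durations = list(durations)
    total = n_blocks * trials_per_block
    n_cells = len(reward_levels) * len(durations)
    if total % n_cells != 0:
        raise CounterbalanceError(
            f"{total} trials cannot be balanced over {n_cells} condition cells"
        )
    per_cell = total // n_cells
    cells = [(r, d) for r in reward_levels for d in durations]
    labels = np.repeat(np.arange(n_cells), per_cell)
    rng.shuffle(labels)
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, n_blocks + 1), trials_per_block),
            "trial": np.tile(np.arange(1, trials_per_block + 1), n_blocks),
            "reward_cents": [cells[i][0] for i in labels],
            "duration_condition": [cells[i][1] for i in labels],
        }
    )


def _saccade_duration_ms(amplitude, peak_velocity):
    """Duration of a half-sine saccade: D = pi * A / (2 * vp), in ms."""
    return 1000.0 * np.pi * amplitude / (2.0 * peak_velocity)


def synth_saccade(amplitude, direction, agent: AgentProfile, vel_gain=1.0, dt=1.0):
    """Render one saccade as sampled displacement, speed, and its oracle event.

    Returns ``(displacement, speed, event)`` where ``displacement`` is an
    (n, 2) array of offsets from the start position sampled every ``dt`` ms,
    ``speed`` the corresponding tangential speed in deg/s, and ``event`` the
    :class:`GroundTruthEvent` with onset at t=0.
    """
    if amplitude <= 0:
        raise DegenerateWaveformError("amplitude must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    vp = float(agent.peak_velocity(amplitude, vel_gain))
    dur = _saccade_duration_ms(amplitude, vp)
    if dur < 2.0 * dt:
        raise DegenerateWaveformError(
            f"saccade of {amplitude:.3f} deg lasts {dur:.2f} ms < 2 samples at dt={dt} ms"
        )
    # sample at (approximately) dt with both endpoints exact, so the emitted
    # speed is zero at onset and offset
    n_steps = max(int(round(dur / dt)), 2)
    t = np.linspace(0.0, dur, n_steps + 1)
    phase = t / dur
    path = amplitude * 0.5 * (1.0 - np.cos(np.pi * phase))
    speed = vp * np.sin(np.pi * phase)
    event = GroundTruthEvent(
        true_onset=0.0,
        true_offset=dur,
        true_amplitude=float(amplitude),
        true_peak_velocity=vp,
        destination=-1,
    )
    return path[:, None] * direction[None, :], speed, event


def _trunc_normal(rng, mean, sd, low):
    """One draw from N(mean, sd) truncated below at ``low`` (by redraw/clipping)."""
    for _ in range(16):
        v = rng.normal(mean, sd)
        if v >= low:
            return v
    return low


FIXATION = -1


def synth_trial(
    layout: np.ndarray,
    agent: AgentProfile,
    condition,
    rng_seed,
    geometry: TaskGeometry = TaskGeometry(),
):
    """Simulate one 8-s trial of back-and-forth saccades.

    ``condition`` is either a ``(reward_cents, duration_condition)`` key or an
    object with those attributes.  Returns ``(t, x, y, valid, events)`` with
    sample arrays over the task window and the chronologically ordered list of
    :class:`GroundTruthEvent`.
    """
    rng = _as_rng(rng_seed)
    if hasattr(condition, "reward_cents"):
        key = (condition.reward_cents, condition.duration_condition)
    else:
        key = tuple(condition)
    freq_gain = agent.freq_gain_by_condition.get(key, 1.0)
    vel_gain = agent.vel_gain_by_condition.get(key, 1.0)

    # The frequency gain rescales the whole saccade cycle (pause + movement)
    # so that the expected saccade count scales with the gain.
    leg_dur = _saccade_duration_ms(
        geometry.eccentricity, agent.peak_velocity(geometry.eccentricity)
    )
    cycle = (agent.isi_mean + leg_dur) / freq_gain
    pause_mean = max(cycle - leg_dur, MIN_PAUSE_MS)

    trial_end = geometry.trial_duration
    events: list[GroundTruthEvent] = []
    segments = []  # (t0, dur, p0, p1) for rendering
    pos = np.zeros(2)
    t = _trunc_normal(rng, pause_mean, agent.isi_sd, MIN_PAUSE_MS)
    at_fixation = True
    visited: set[int] = set()

    def _add_saccade(t0, p0, dest, vgain, destination):
        amp = float(np.linalg.norm(dest - p0))
        if amp <= 1e-6:
            return None
        vp = float(agent.peak_velocity(amp, vgain))
        dur = _saccade_duration_ms(amp, vp)
        if t0 + dur > trial_end:
            return None
        events.append(GroundTruthEvent(t0, t0 + dur, amp, vp, destination))
        segments.append((t0, dur, p0.copy(), dest.copy()))
        return t0 + dur

    while True:
        if at_fixation:
            unvisited = [i for i in range(len(layout)) if i not in visited]
            if unvisited and rng.random() < agent.explore_prob:
                idx = int(rng.choice(unvisited))
            else:
                idx = int(rng.integers(len(layout)))
            visited.add(idx)
            centre = layout[idx]
            dest = centre + rng.normal(0.0, agent.landing_sd, size=2)
            t_new = _add_saccade(t, pos, dest, vel_gain, idx)
            if t_new is None:
                break
            pos, t = dest, t_new
            err = float(np.linalg.norm(pos - centre))
            if err > geometry.hit_radius_online and rng.random() < agent.corrective_prob:
                t_c = t + _trunc_normal(rng, pause_mean, agent.isi_sd, MIN_PAUSE_MS)
                dest_c = centre + rng.normal(0.0, agent.landing_sd / 3.0, size=2)
                t_new = _add_saccade(t_c, pos, dest_c, vel_gain, idx)
                if t_new is None:
                    break
                pos, t = dest_c, t_new
            at_fixation = False
        else:
            dest = rng.normal(0.0, agent.landing_sd, size=2)
            t_new = _add_saccade(t, pos, dest, vel_gain, FIXATION)
            if t_new is None:
                break
            pos, t = dest, t_new
            at_fixation = True
        t += _trunc_normal(rng, pause_mean, agent.isi_sd, MIN_PAUSE_MS)
        if t >= trial_end:
            break

    # Render the sample grid: constant position between saccades, half-sine
    # displacement inside each saccade.
    n = geometry.n_samples
    ts = np.arange(n) * geometry.dt_ms
    x = np.zeros(n)
    y = np.zeros(n)
    cursor = 0
    cur = np.zeros(2)
    for t0, dur, p0, p1 in segments:
        i0 = int(np.searchsorted(ts, t0))
        x[cursor:i0] = cur[0]
        y[cursor:i0] = cur[1]
        i1 = int(np.searchsorted(ts, t0 + dur))
        phase = np.clip((ts[i0:i1] - t0) / dur, 0.0, 1.0)
        frac = 0.5 * (1.0 - np.cos(np.pi * phase))
        x[i0:i1] = p0[0] + (p1[0] - p0[0]) * frac
        y[i0:i1] = p0[1] + (p1[1] - p0[1]) * frac
        cursor = i1
        cur = p1
    x[cursor:] = cur[0]
    y[cursor:] = cur[1]

    if agent.noise_sd > 0:
        x = x + rng.normal(0.0, agent.noise_sd, size=n)
        y = y + rng.normal(0.0, agent.noise_sd, size=n)
    valid = np.ones(n, dtype=bool)
    return ts, x, y, valid, events


@dataclass(frozen=True)
class PopulationParams:
    """Between-subject distributions of the generating agent parameters.

    Defaults are set to produce cohorts on the scale of a typical incentive
    experiment: ~31.5 saccades per 8-s trial, peak velocities near 390 deg/s
    at ~10 deg amplitudes, end-point scatter ~0.6 deg.
    """

    freq_mean: float = 31.5  # saccades per trial
    freq_sd: float = 3.3
    alpha_mean: float = 560.0
    alpha_sd: float = 40.0
    beta_mean: float = 0.25
    beta_sd: float = 0.03
    isi_sd: float = 50.0
    landing_sd: float = 0.6
    noise_sd: float = 0.02
    corrective_prob: float = 0.5
    explore_prob: float = 0.6
    # 4AFC visibility of the reward cue by display duration: mean/SD of the
    # per-subject probability of a correct coin identification and of a
    # "seen" report.
    p_correct_mean: dict = field(
        default_factory=lambda: {"17": 0.61, "D_indiv": 0.85, "100": 0.995}
    )
    p_correct_sd: dict = field(
        default_factory=lambda: {"17": 0.07, "D_indiv": 0.14, "100": 0.01}
    )
    p_seen_mean: dict = field(
        default_factory=lambda: {"17": 0.10, "D_indiv": 0.44, "100": 0.98}
    )
    p_seen_sd: dict = field(
        default_factory=lambda: {"17": 0.13, "D_indiv": 0.12, "100": 0.02}
    )


def gain_contrast_for_dz(dz, sigma_g, mu_f, sigma_f):
    """Mean high-low frequency-gain contrast that yields a target Cohen's dz.

    With baseline frequency f ~ N(mu_f, sigma_f) and per-subject contrast
    delta ~ N(c, sigma_g) applied as gains 1 +/- delta/2, the paired
    difference f*delta has dz = mu_f*c / sqrt((mu_f^2+sigma_f^2)*sigma_g^2
    + sigma_f^2*c^2); solving for c gives the closed form below.
    """
    if dz <= 0:
        return 0.0
    denom = mu_f**2 - dz**2 * sigma_f**2
    if denom <= 0:
        raise ValueError("target dz unreachable for this between-subject SD")
    return dz * sigma_g * np.sqrt((mu_f**2 + sigma_f**2) / denom)


@dataclass(frozen=True)
class EffectSpec:
    """Condition effects injected into the cohort.

    ``freq_dz`` is the target within-subject effect size of reward on saccade
    frequency (high minus low coin value, pooled over display durations);
    ``sigma_gain`` the between-subject SD of the gain contrast.  Velocity
    gains are symmetric multipliers around 1 applied to high/low reward.
    """

    freq_dz: float = 0.65
    sigma_gain: float = 0.03
    vel_gain_high: float = 1.01
    vel_gain_low: float = 0.99
    vel_gain_sd: float = 0.005

    def frequency_contrast(self, pop: PopulationParams) -> float:
        return gain_contrast_for_dz(self.freq_dz, self.sigma_gain, pop.freq_mean, pop.freq_sd)


@dataclass
class ExperimentData:
    """Cohort-level synthetic dataset with its generating ground truth."""

    geometry: TaskGeometry
    agents: dict  # subject -> AgentProfile
    trials: pd.DataFrame  # subject, block, trial, reward_cents, duration_condition
    layouts: dict  # (subject, block, trial) -> (n_targets, 2) array
    traces: dict  # (subject, block, trial) -> (t, x, y, valid); empty if not rendered
    truth: pd.DataFrame  # per-saccade oracle labels
    true_means: pd.DataFrame  # subject x condition true frequency / velocity gain
    afc: pd.DataFrame  # 4AFC response table
    base_frequency: dict  # subject -> f_i


def _clip01(v):
    return float(np.clip(v, 0.0, 1.0))


def synth_experiment(
    n_subjects: int,
    population: PopulationParams = PopulationParams(),
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
    n_blocks: int = 5,
    trials_per_block: int = 42,
    geometry: TaskGeometry = TaskGeometry(),
    include_traces: bool = True,
    include_afc: bool = True,
    afc_trials_per_duration: int = 80,
) -> ExperimentData:
    """Generate a full synthetic cohort, reproducible from one master seed.

    Per-subject and per-trial random streams are split off the master seed
    with :class:`numpy.random.SeedSequence`, so any subject's data can be
    regenerated independently.  With ``include_traces=False`` only the
    generating truth (per-condition means, agents, AFC tables) is produced,
    which is what statistical power experiments need.
    """
    if n_subjects < 2:
        raise CohortError("need at least 2 subjects for downstream statistics")
    master = np.random.SeedSequence(seed)
    subj_seeds = master.spawn(n_subjects)

    c = effects.frequency_contrast(population)
    leg_dur = None

    agents, layouts, traces = {}, {}, {}
    trial_rows, truth_rows, mean_rows, afc_frames = [], [], [], []
    base_frequency = {}

    for s_idx, sseq in enumerate(subj_seeds):
        subject = s_idx + 1
        rng = np.random.default_rng(sseq)
        f_i = max(rng.normal(population.freq_mean, population.freq_sd), 5.0)
        delta_i = rng.normal(c, effects.sigma_gain)
        vjit = rng.normal(0.0, effects.vel_gain_sd)
        alpha = max(rng.normal(population.alpha_mean, population.alpha_sd), 100.0)
        beta = max(rng.normal(population.beta_mean, population.beta_sd), 0.02)

        freq_gains, vel_gains = {}, {}
        for dur in DURATION_LEVELS:
            freq_gains[(50, dur)] = 1.0 + delta_i / 2.0
            freq_gains[(1, dur)] = 1.0 - delta_i / 2.0
            vel_gains[(50, dur)] = effects.vel_gain_high + vjit
            vel_gains[(1, dur)] = effects.vel_gain_low + vjit

        agent = AgentProfile(
            alpha=alpha,
            beta=beta,
            isi_mean=0.0,  # set below from the target frequency
            isi_sd=population.isi_sd,
            landing_sd=population.landing_sd,
            noise_sd=population.noise_sd,
            corrective_prob=population.corrective_prob,
            explore_prob=population.explore_prob,
            freq_gain_by_condition=freq_gains,
            vel_gain_by_condition=vel_gains,
        )
        leg_dur = _saccade_duration_ms(
            geometry.eccentricity, agent.peak_velocity(geometry.eccentricity)
        )
        agent.isi_mean = max(geometry.trial_duration / f_i - leg_dur, MIN_PAUSE_MS)
        agents[subject] = agent
        base_frequency[subject] = f_i

        for reward in REWARD_LEVELS:
            for dur in DURATION_LEVELS:
                mean_rows.append(
                    {
                        "subject": subject,
                        "reward_cents": reward,
                        "duration_condition": dur,
                        "true_frequency": f_i * freq_gains[(reward, dur)],
                        "true_vel_gain": vel_gains[(reward, dur)],
                    }
                )

        # 4AFC responses (two phases pooled downstream).
        if include_afc:
            pc = {
                d: _clip01(rng.normal(population.p_correct_mean[d], population.p_correct_sd[d]))
                for d in DURATION_LEVELS
            }
            ps = {
                d: _clip01(rng.normal(population.p_seen_mean[d], population.p_seen_sd[d]))
                for d in DURATION_LEVELS
            }
            for phase in (1, 2):
                for dur in DURATION_LEVELS:
                    tab = synth_afc(
                        pc[dur], ps[dur], afc_trials_per_duration // 2, rng
                    )
                    tab.insert(0, "subject", subject)
                    tab.insert(1, "phase", phase)
                    tab.insert(2, "duration_condition", dur)
                    afc_frames.append(tab)

        schedule = make_schedule(
            n_blocks, trials_per_block, REWARD_LEVELS, DURATION_LEVELS, rng
        )
        schedule.insert(0, "subject", subject)
        trial_rows.append(schedule)

        if include_traces:
            for row in schedule.itertuples(index=False):
                key = (subject, row.block, row.trial)
                layout = make_layout(geometry, rng)
                layouts[key] = layout
                ts, x, y, valid, events = synth_trial(
                    layout,
                    agent,
                    (row.reward_cents, row.duration_condition),
                    rng,
                    geometry,
                )
                traces[key] = (ts, x, y, valid)
                for ev in events:
                    truth_rows.append(
                        {
                            "subject": subject,
                            "block": row.block,
                            "trial": row.trial,
                            "onset_ms": ev.true_onset,
                            "offset_ms": ev.true_offset,
                            "amplitude_deg": ev.true_amplitude,
                            "peak_vel_deg_s": ev.true_peak_velocity,
                            "destination": ev.destination,
                        }
                    )

    truth_cols = [
        "subject", "block", "trial", "onset_ms", "offset_ms",
        "amplitude_deg", "peak_vel_deg_s", "destination",
    ]
    return ExperimentData(
        geometry=geometry,
        agents=agents,
        trials=pd.concat(trial_rows, ignore_index=True),
        layouts=layouts,
        traces=traces,
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
        true_means=pd.DataFrame(mean_rows),
        afc=(
            pd.concat(afc_frames, ignore_index=True)
            if afc_frames
            else pd.DataFrame(
                columns=[
                    "subject", "phase", "duration_condition",
                    "coin", "response", "correct", "seen",
                ]
            )
        ),
        base_frequency=base_frequency,
    )


def synth_afc(p_correct: float, p_seen: float, n_trials: int, rng_seed) -> pd.DataFrame:
    """Simulate a 4AFC coin-identification block.

    Each response carries the shown coin, the chosen answer (one of
    ``seen_50 / seen_1 / guess_50 / guess_1``), a Bernoulli(p_correct) correct
    flag and a Bernoulli(p_seen) seen flag.
    """
    if not (0.0 <= p_correct <= 1.0 and 0.0 <= p_seen <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    rng = _as_rng(rng_seed)
    coin = rng.choice([1, 50], size=n_trials)
    correct = rng.random(n_trials) < p_correct
    seen = rng.random(n_trials) < p_seen
    answer = np.where(correct, coin, np.where(coin == 1, 50, 1))
    response = np.where(seen, "seen_", "guess_").astype(object) + answer.astype(str)
    return pd.DataFrame(
        {
            "coin": coin,
            "response": response,
            "correct": correct.astype(int),
            "seen": seen.astype(int),
        }
    )
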