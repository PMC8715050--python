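"""Saccade detection from gaze traces.

Two detectors are provided:

* :func:`detect_fixed` — positions are smoothed with a Savitzky-Golay filter
  (order 2, 20-ms support), 2-D speed is taken by central differences, a
  saccade starts at the first sample exceeding a fixed 35 deg/s threshold and
  ends at the first subsequent sample where speed has dropped back below the
  threshold and the speed derivative has settled.  Events shorter than 10 ms
  are discarded, and when two events are separated by less than 40 ms the
  later one is dropped.

* :func:`detect_adaptive` — a noise-scaled variant: the peak threshold is set
  to mean + 4 SD and the onset/offset threshold to mean + 2.5 SD of the
  trial's speed samples.  By default the thresholds are estimated
  iteratively, recomputing mean and SD over the samples below the current
  threshold until convergence, so they settle on the trial's fixation-noise
  level rather than being inflated by the saccades themselves.  Events
  shorter than 10 ms or preceded by less than 40 ms of fixation are
  discarded.

Both detectors are deterministic and operate per valid segment; no event can
span a gap of invalid samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateInputError
from .gaze_io import GazeTrace

__all__ = [
    "DetectorConfig",
    "AdaptiveConfig",
    "SaccadeEvent",
    "smooth",
    "speed_series",
    "accel_series",
    "detect_fixed",
    "detect_adaptive",
    "events_to_frame",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Fixed-threshold detector parameters."""

    sg_order: int = 2
    sg_window_ms: float = 20.0  # rounded up to the nearest odd sample count
    velocity_threshold: float = 35.0  # deg/s
    accel_threshold: float = 1000.0  # deg/s^2, offset settling criterion
    min_duration_ms: float = 10.0
    min_isi_ms: float = 40.0

    def window_samples(self, dt_ms: float) -> int:
        w = int(round(self.sg_window_ms / dt_ms))
        if w % 2 == 0:
            w += 1  # SG filters need odd support; 20 ms at 1 kHz -> 21 samples
        return max(w, self.sg_order + 2 if (self.sg_order + 2) % 2 == 1 else self.sg_order + 3)


@dataclass(frozen=True)
class AdaptiveConfig:
    """Noise-scaled detector parameters."""

    peak_k: float = 4.0  # SD multiplier of the peak threshold
    onset_k: float = 2.5  # SD multiplier of the onset/offset threshold
    min_duration_ms: float = 10.0
    min_prior_fixation_ms: float = 40.0
    sg_order: int = 2
    sg_window_ms: float = 20.0
    iterative: bool = True  # estimate thresholds from below-threshold samples
    init_threshold: float = 200.0  # deg/s, starting point of the iteration
    max_iterations: int = 50
    convergence_deg_s: float = 1.0
    # floor of the onset threshold: below the smoothing filter's own leakage
    # scale (the spurious speed the filter leaks just outside a saccade) an
    # adaptive threshold is meaningless, e.g. on noise-free synthetic data
    min_onset_threshold: float = 10.0

    def window_samples(self, dt_ms: float) -> int:
        return DetectorConfig(
            sg_order=self.sg_order, sg_window_ms=self.sg_window_ms
        ).window_samples(dt_ms)


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade with its kinematics."""

    onset_index: int
    offset_index: int
    onset_t: float  # ms
    offset_t: float  # ms
    peak_velocity: float  # deg/s, max 2-D speed between onset and offset
    amplitude: float  # deg, straight-line onset->offset displacement
    x_onset: float = np.nan
    y_onset: float = np.nan
    x_offset: float = np.nan
    y_offset: float = np.nan

    @property
    def duration_ms(self) -> float:
        return self.offset_t - self.onset_t


def _valid_segments(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal runs of valid samples."""
    v = np.asarray(valid, dtype=bool)
    if not v.any():
        return
    edges = np.flatnonzero(np.diff(v.astype(np.int8)))
    starts = list(edges[~v[edges]] + 1)
    stops = list(edges[v[edges]] + 1)
    if v[0]:
        starts.insert(0, 0)
    if v[-1]:
        stops.append(len(v))
    yield from zip(starts, stops)


def smooth(trace: GazeTrace, config: DetectorConfig = DetectorConfig()):
    """Savitzky-Golay smoothed x and y positions, per valid segment.

    Segments shorter than the filter window are returned unfiltered.  Returns
    ``(x_smooth, y_smooth)``; invalid samples keep their raw values.
    """
    window = config.window_samples(trace.dt_ms)
    xs = trace.x.copy()
    ys = trace.y.copy()
    for start, stop in _valid_segments(~trace.missing):
        if stop - start < window:
            continue
        xs[start:stop] = savgol_filter(trace.x[start:stop], window, config.sg_order)
        ys[start:stop] = savgol_filter(trace.y[start:stop], window, config.sg_order)
    return xs, ys


def speed_series(x: np.ndarray, y: np.ndarray, dt_ms: float) -> np.ndarray:
    """2-D speed (deg/s) via central differences; one-sided at the ends."""
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 samples for a speed series")
    dt_s = dt_ms / 1000.0
    vx = np.gradient(np.asarray(x, dtype=float), dt_s)
    vy = np.gradient(np.asarray(y, dtype=float), dt_s)
    return np.hypot(vx, vy)


def accel_series(speed: np.ndarray, dt_ms: float) -> np.ndarray:
    """Derivative of the 2-D speed (deg/s^2) via central differences."""
    if len(speed) < 3:
        raise DegenerateInputError("need at least 3 samples for an acceleration series")
    return np.gradient(np.asarray(speed, dtype=float), dt_ms / 1000.0)


def _make_event(trace, xs, ys, speed_local, start, on_local, off_local):
    seg = speed_local[on_local : off_local + 1]
    i_on, i_off = start + on_local, start + off_local
    return SaccadeEvent(
        onset_index=int(i_on),
        offset_index=int(i_off),
        onset_t=float(trace.t[i_on]),
        offset_t=float(trace.t[i_off]),
        peak_velocity=float(seg.max()),
        amplitude=float(np.hypot(xs[i_off] - xs[i_on], ys[i_off] - ys[i_on])),
        x_onset=float(xs[i_on]),
        y_onset=float(ys[i_on]),
        x_offset=float(xs[i_off]),
        y_offset=float(ys[i_off]),
    )


def _apply_duration_filter(events, min_duration_ms):
    return [e for e in events if e.duration_ms >= min_duration_ms]


def _apply_isi_filter(events, min_isi_ms):
    """Drop the later of two events separated by less than the minimum ISI."""
    kept = []
    for e in events:
        if kept and (e.onset_t - kept[-1].offset_t) < min_isi_ms:
            continue
        kept.append(e)
    return kept


def detect_fixed(trace: GazeTrace, config: DetectorConfig = DetectorConfig()):
    """Fixed-threshold saccade detection (35 deg/s on SG-filtered 2-D speed)."""
    xs, ys = smooth(trace, config)
    events = []
    for start, stop in _valid_segments(~trace.missing):
        if stop - start < 3:
            continue
        speed = speed_series(xs[start:stop], ys[start:stop], trace.dt_ms)
        accel = accel_series(speed, trace.dt_ms)
        above = speed > config.velocity_threshold
        n = stop - start
        i = 0
        while i < n:
            if not above[i]:
                i += 1
                continue
            onset = i
            # core of the event: samples above the velocity threshold; the
            # duration floor applies to this core so that the settling tail
            # below cannot promote a brief noise spike into a valid saccade
            j = onset + 1
            while j < n and above[j]:
                j += 1
            core_ms = (j - onset) * trace.dt_ms
            # offset: first sample where speed is back below threshold AND
            # the speed derivative has settled (eye no longer decelerating)
            while j < n and (
                speed[j] > config.velocity_threshold
                or abs(accel[j]) > config.accel_threshold
            ):
                j += 1
            offset = min(j, n - 1)
            if core_ms >= config.min_duration_ms:
                events.append(_make_event(trace, xs, ys, speed, start, onset, offset))
            i = j + 1
    events = _apply_isi_filter(events, config.min_isi_ms)
    return events


def _adaptive_thresholds(speed: np.ndarray, config: AdaptiveConfig):
    """Peak and onset thresholds: mean + k*SD, optionally iterated.

    In iterative mode the statistics are recomputed over samples below the
    current peak threshold until it moves by less than ``convergence_deg_s``,
    so the thresholds track the trial's fixation noise level.
    """
    m, s = float(np.mean(speed)), float(np.std(speed))
    if s == 0.0:
        return None, None
    if config.iterative:
        # start below typical saccadic peaks and let the threshold converge
        # onto the trial's fixation-noise level
        pt = config.init_threshold
        for _ in range(config.max_iterations):
            below = speed[speed < pt]
            if len(below) < 10:
                break
            m_b, s_b = float(np.mean(below)), float(np.std(below))
            if s_b == 0.0:
                break
            m, s = m_b, s_b
            pt_new = m + config.peak_k * s
            if abs(pt_new - pt) < config.convergence_deg_s:
                pt = pt_new
                break
            pt = pt_new
    else:
        pt = m + config.peak_k * s
    ot = max(m + config.onset_k * s, config.min_onset_threshold)
    pt = max(pt, config.min_onset_threshold * config.peak_k / config.onset_k)
    return pt, ot


def detect_adaptive(trace: GazeTrace, config: AdaptiveConfig = AdaptiveConfig()):
    """Noise-scaled saccade detection (mean + 4 SD peak, mean + 2.5 SD bounds)."""
    sg = DetectorConfig(sg_order=config.sg_order, sg_window_ms=config.sg_window_ms)
    xs, ys = smooth(trace, sg)
    events = []
    for start, stop in _valid_segments(~trace.missing):
        if stop - start < 3:
            continue
        speed = speed_series(xs[start:stop], ys[start:stop], trace.dt_ms)
        pt, ot = _adaptive_thresholds(speed, config)
        if pt is None:
            continue
        n = stop - start
        above_peak = speed > pt
        above_onset = speed > ot
        i = 0
        while i < n:
            if not above_peak[i]:
                i += 1
                continue
            # grow the event outward from the peak region to the onset-threshold
            # crossings on both sides
            onset = i
            while onset > 0 and above_onset[onset - 1]:
                onset -= 1
            j = i
            while j < n - 1 and above_onset[j + 1]:
                j += 1
            offset = min(j + 1, n - 1)  # first settled sample after the burst
            events.append(_make_event(trace, xs, ys, speed, start, onset, offset))
            i = j + 1
    events = _apply_duration_filter(events, config.min_duration_ms)
    # drop events whose preceding fixation (gap since the previous event) is
    # too short for a reliable onset estimate
    events = _apply_isi_filter(events, config.min_prior_fixation_ms)
    return events


def events_to_frame(events, subject=None, block=None, trial=None, algorithm=None) -> "pd.DataFrame":
    """Tabulate a list of events (one row per saccade)."""
    import pandas as pd

    rows = [
        {
            "onset_ms": e.onset_t,
            "offset_ms": e.offset_t,
            "amplitude_deg": e.amplitude,
            "peak_vel_deg_s": e.peak_velocity,
            "x_onset": e.x_onset,
            "y_onset": e.y_onset,
            "x_offset": e.x_offset,
            "y_offset": e.y_offset,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "onset_ms", "offset_ms", "amplitude_deg", "peak_vel_deg_s",
            "x_onset", "y_onset", "x_offset", "y_offset",
        ],
    )
    for name, value in [
        ("algorithm", algorithm), ("trial", trial), ("block", block), ("subject", subject),
    ]:
        if value is not None:
            df.insert(0, name, value)
    return df
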