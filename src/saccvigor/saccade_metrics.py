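"""Effort metrics from detected saccades.

Per trial: saccade frequency (count over the 8-s window, irrespective of
landing position), target hits (gaze entering a criterion radius around a
target, with a return to the fixation zone required between successive hits),
and landing classification (each saccade ends nearer to a target or to the
fixation cross).

Per subject: the main-sequence fit v = alpha * (1 - 1/(1 + beta * x)) pooled
over all of the subject's saccades, and per-condition vigor, the ratio of the
measured mean peak velocity to the mean velocity the fit predicts for the
same amplitudes.  Vigor is a ratio of condition means, so a condition whose
velocities sit 5% above the subject's stereotyped main sequence yields a
vigor near 1.05 regardless of its amplitude mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DegenerateInputError, FitError
from .synthetic_gaze import TaskGeometry, main_sequence_velocity

__all__ = [
    "MainSequenceFit",
    "frequency",
    "classify_destination",
    "count_hits",
    "fit_main_sequence",
    "vigor_ratio",
    "summarize_conditions",
]


@dataclass(frozen=True)
class MainSequenceFit:
    """Fitted hyperbolic amplitude-velocity relationship of one subject."""

    alpha_hat: float  # deg/s, asymptotic peak velocity
    beta_hat: float  # 1/deg
    n_saccades_fit: int

    def predict(self, amplitude):
        """Expected peak velocity for the given amplitudes."""
        return main_sequence_velocity(amplitude, self.alpha_hat, self.beta_hat)


def frequency(events) -> int:
    """Number of saccades in one trial, irrespective of landing position."""
    return len(events)


def classify_destination(endpoint, layout: np.ndarray, fixation=(0.0, 0.0)):
    """Nearest-destination rule for a saccade end point.

    The saccade is target-directed when its end point is closer to some
    target centre than to the fixation cross.  Returns
    ``(kind, index, landing_error)`` with ``kind`` in {"target", "fixation"},
    ``index`` the target index (or -1), and the distance to the chosen centre.
    """
    endpoint = np.asarray(endpoint, dtype=float)
    d_fix = float(np.linalg.norm(endpoint - np.asarray(fixation, dtype=float)))
    d_targets = np.linalg.norm(np.asarray(layout) - endpoint[None, :], axis=1)
    i = int(np.argmin(d_targets))
    if d_targets[i] < d_fix:
        return "target", i, float(d_targets[i])
    return "fixation", -1, d_fix


def count_hits(
    x: np.ndarray,
    y: np.ndarray,
    layout: np.ndarray,
    mode: str = "offline",
    geometry: TaskGeometry = TaskGeometry(),
    requires_refixation: bool = True,
):
    """Ordered list of target hits from a gaze trace.

    A target is hit when a gaze sample falls within the mode's radius of its
    centre (online 1.2 deg, offline 2.4 deg); each target can be hit at most
    once, and — per the task's alternation rule — gaze must re-enter the
    fixation zone (2.5 deg) between successive hits.  The offline rule can be
    relaxed to count any close landing with ``requires_refixation=False``.
    """
    if mode == "online":
        radius = geometry.hit_radius_online
    elif mode == "offline":
        radius = geometry.hit_radius_offline
    else:
        raise ValueError(f"unknown hit mode: {mode!r}")
    pts = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    finite = np.isfinite(pts).all(axis=1)
    d_fix = np.linalg.norm(pts, axis=1)
    in_fix = finite & (d_fix <= geometry.fixation_radius_online)
    # (n_samples, n_targets) hit mask; trials are short enough for this to be cheap
    d_t = np.linalg.norm(pts[:, None, :] - np.asarray(layout)[None, :, :], axis=2)
    in_target = finite[:, None] & (d_t <= radius)

    hits = []
    unhit = np.ones(len(layout), dtype=bool)
    armed = True
    for i in range(len(pts)):
        if not armed and in_fix[i]:
            armed = True
        if (armed or not requires_refixation) and unhit.any():
            cand = np.flatnonzero(in_target[i] & unhit)
            if len(cand):
                j = int(cand[np.argmin(d_t[i, cand])])
                hits.append(j)
                unhit[j] = False
                armed = False
    return hits


def fit_main_sequence(amplitudes, peak_velocities) -> MainSequenceFit:
    """Least-squares hyperbolic main-sequence fit over a subject's saccades.

    Initialised at alpha0 = 1.1 * max(v) with beta0 solved from the
    median-amplitude point; bounded restarts guard against the flat basin at
    small beta.
    """
    x = np.asarray(amplitudes, dtype=float)
    v = np.asarray(peak_velocities, dtype=float)
    keep = np.isfinite(x) & np.isfinite(v) & (x > 0)
    x, v = x[keep], v[keep]
    if len(x) < 20:
        raise DegenerateInputError(f"need >= 20 saccades to fit, got {len(x)}")
    if x.max() - x.min() < 2.0:
        raise FitError("amplitudes span < 2 deg: alpha and beta are not identifiable")

    vmax = float(v.max())
    alpha0 = 1.1 * vmax
    xm, vm = float(np.median(x)), float(np.median(v))
    # solve vm = alpha0 (1 - 1/(1+beta xm)) for beta at the median point
    r = min(vm / alpha0, 0.95)
    beta0 = r / ((1.0 - r) * xm) if xm > 0 else 0.1
    bounds = ([1e-6, 1e-6], [5.0 * vmax, 10.0])

    def model(xx, a, b):
        return a * (1.0 - 1.0 / (1.0 + b * xx))

    last_exc = None
    for a0, b0 in [(alpha0, beta0), (vmax, 0.2), (2.0 * vmax, 0.05)]:
        try:
            popt, _ = curve_fit(
                model, x, v, p0=[a0, np.clip(b0, 1e-4, 9.9)], bounds=bounds, maxfev=20000
            )
            return MainSequenceFit(float(popt[0]), float(popt[1]), int(len(x)))
        except RuntimeError as exc:  # pragma: no cover - only on pathological data
            last_exc = exc
    raise FitError(f"main-sequence fit did not converge: {last_exc}")


def vigor_ratio(amplitudes, peak_velocities, fit: MainSequenceFit) -> float:
    """Condition vigor: mean measured / mean expected peak velocity."""
    x = np.asarray(amplitudes, dtype=float)
    v = np.asarray(peak_velocities, dtype=float)
    if len(x) == 0:
        return float("nan")
    return float(np.mean(v) / np.mean(fit.predict(x)))


def summarize_conditions(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    hits_per_trial: pd.DataFrame,
    fits: dict,
    landing_errors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of effort measures per subject x reward x duration cell.

    ``events`` must carry ``subject, block, trial, amplitude_deg,
    peak_vel_deg_s``; ``hits_per_trial`` carries ``subject, block, trial,
    n_hits``; ``fits`` maps subject -> :class:`MainSequenceFit`;
    ``landing_errors`` optionally carries per-event ``landing_error_deg``.
    Excluded trials are simply absent from ``trials`` and contribute nothing.
    """
    key = ["subject", "block", "trial"]
    ev = events.merge(trials[key + ["reward_cents", "duration_condition"]], on=key)
    if landing_errors is not None:
        ev = ev.merge(landing_errors, how="left")

    per_trial = (
        ev.groupby(key + ["reward_cents", "duration_condition"], as_index=False)
        .agg(n_saccades=("peak_vel_deg_s", "size"))
    )
    # trials with zero detected saccades still count toward mean frequency
    per_trial = trials[key + ["reward_cents", "duration_condition"]].merge(
        per_trial, how="left"
    )
    per_trial["n_saccades"] = per_trial["n_saccades"].fillna(0)
    per_trial = per_trial.merge(hits_per_trial, how="left", on=key)

    cell = ["subject", "reward_cents", "duration_condition"]
    rows = []
    for c, grp in per_trial.groupby(cell):
        subject = c[0]
        ev_c = ev[
            (ev["subject"] == c[0])
            & (ev["reward_cents"] == c[1])
            & (ev["duration_condition"] == c[2])
        ]
        fit = fits.get(subject)
        row = {
            "subject": c[0],
            "reward_cents": c[1],
            "duration_condition": c[2],
            "n_hits": grp["n_hits"].mean(),
            "frequency": grp["n_saccades"].mean(),
            "peak_vel": ev_c["peak_vel_deg_s"].mean(),
            "vigor": (
                vigor_ratio(ev_c["amplitude_deg"], ev_c["peak_vel_deg_s"], fit)
                if fit is not None and len(ev_c)
                else np.nan
            ),
            "amplitude": ev_c["amplitude_deg"].mean(),
            "endpoint_error": (
                ev_c["landing_error_deg"].mean() if "landing_error_deg" in ev_c else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
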