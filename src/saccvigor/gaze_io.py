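"""Plain-text gaze and metadata I/O, resampling, and missing-data exclusion.

File dialects (all UTF-8, comma-separated, '.' decimal):

* gaze table:   ``subject,block,trial,t_ms,x_deg,y_deg,valid``
* trial table:  ``subject,block,trial,reward_cents,duration_condition``
* 4AFC table:   ``subject,phase,duration_condition,coin,response,correct,seen``

"Missing" samples are those flagged invalid by the tracker or carrying
non-finite coordinates.  A trial is excluded when strictly more than 25% of
its samples over the 8-s task window are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, FormatError

__all__ = [
    "GazeTrace",
    "GAZE_COLUMNS",
    "read_gaze",
    "write_gaze",
    "read_trials",
    "write_trials",
    "read_afc",
    "write_afc",
    "resample_to_1000",
    "missing_fraction",
    "exclude_trial",
    "MISSING_FRACTION_LIMIT",
]

GAZE_COLUMNS = ["subject", "block", "trial", "t_ms", "x_deg", "y_deg", "valid"]

#: Trials with a missing-sample fraction strictly above this are discarded.
MISSING_FRACTION_LIMIT = 0.25


@dataclass
class GazeTrace:
    """One trial's sampled eye position."""

    t: np.ndarray  # ms, strictly increasing, constant step
    x: np.ndarray  # deg, relative to screen centre
    y: np.ndarray  # deg
    valid: np.ndarray  # bool per sample
    sampling_rate: float  # Hz

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise FormatError("t, x, y, valid must have equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.sampling_rate, atol=1e-6):
                raise FormatError("timestamps must have a constant step of 1000/rate ms")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def missing(self) -> np.ndarray:
        return ~self.valid | ~np.isfinite(self.x) | ~np.isfinite(self.y)


def write_gaze(dataset: dict, path, sampling_rate: float = 1000.0) -> None:
    """Write traces keyed by ``(subject, block, trial)`` to one gaze table.

    ``dataset`` values are either :class:`GazeTrace` or ``(t, x, y, valid)``
    tuples sampled at ``sampling_rate``.
    """
    frames = []
    for (subject, block, trial), value in dataset.items():
        if isinstance(value, GazeTrace):
            t, x, y, valid = value.t, value.x, value.y, value.valid
        else:
            t, x, y, valid = value
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "block": block,
                    "trial": trial,
                    "t_ms": t,
                    "x_deg": x,
                    "y_deg": y,
                    "valid": np.asarray(valid).astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze(path, sampling_rate: float = 1000.0) -> dict:
    """Read a gaze table back into ``{(subject, block, trial): GazeTrace}``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(GAZE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"gaze file missing columns: {sorted(missing_cols)}")
    out = {}
    for key, grp in df.groupby(["subject", "block", "trial"], sort=True):
        key = tuple(k.item() if hasattr(k, "item") else k for k in key)
        t = grp["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"non-monotone timestamps in trial {key}")
        try:
            out[key] = GazeTrace(
                t,
                grp["x_deg"].to_numpy(dtype=float),
                grp["y_deg"].to_numpy(dtype=float),
                grp["valid"].to_numpy().astype(bool),
                sampling_rate,
            )
        except FormatError as exc:
            raise FormatError(f"trial {key}: {exc}") from exc
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "block", "trial", "reward_cents", "duration_condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trial file missing columns: {sorted(missing)}")
    return df


def write_afc(afc: pd.DataFrame, path) -> None:
    afc.to_csv(path, index=False)


def read_afc(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "phase", "duration_condition", "coin", "correct", "seen"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"4AFC file missing columns: {sorted(missing)}")
    return df


def resample_to_1000(trace: GazeTrace) -> GazeTrace:
    """Upsample a trace to 1000 Hz by linear interpolation.

    Original samples are preserved bit-for-bit at coincident timestamps;
    inserted samples between two valid neighbours are linearly interpolated,
    while samples between or beyond invalid neighbours are marked invalid
    (gaps are never interpolated across).
    """
    if trace.sampling_rate == 1000.0:
        return trace
    if 1000.0 % trace.sampling_rate != 0:
        raise FormatError(f"cannot upsample {trace.sampling_rate} Hz to 1000 Hz evenly")
    factor = int(1000.0 // trace.sampling_rate)
    n_old = len(trace.t)
    if n_old < 2:
        raise DegenerateInputError("need at least 2 samples to resample")
    n_new = (n_old - 1) * factor + 1
    t_new = trace.t[0] + np.arange(n_new) * 1.0
    x_new = np.empty(n_new)
    y_new = np.empty(n_new)
    valid_new = np.zeros(n_new, dtype=bool)
    x_new[::factor] = trace.x
    y_new[::factor] = trace.y
    valid_new[::factor] = trace.valid
    ok = trace.valid & np.isfinite(trace.x) & np.isfinite(trace.y)
    for j in range(1, factor):
        w = j / factor
        seg_ok = ok[:-1] & ok[1:]
        x_new[j::factor] = (1 - w) * trace.x[:-1] + w * trace.x[1:]
        y_new[j::factor] = (1 - w) * trace.y[:-1] + w * trace.y[1:]
        valid_new[j::factor] = seg_ok
    return GazeTrace(t_new, x_new, y_new, valid_new, 1000.0)


def missing_fraction(trace: GazeTrace) -> float:
    """Fraction of missing samples (invalid flag or non-finite coordinates)."""
    if len(trace.t) == 0:
        raise DegenerateInputError("empty trace")
    return float(np.mean(trace.missing))


def exclude_trial(trace: GazeTrace) -> bool:
    """True when the trial must be discarded (missing fraction > 25%, strict)."""
    return missing_fraction(trace) > MISSING_FRACTION_LIMIT
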