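"""Payout rule and block-level reward accounting.

The gained reward on a trial is an exponential fraction of the shown coin:

    gained = coin_value * (10**(LT/NT) - (1 - LT/NT)) / 10

where LT is the number of landed (hit) targets and NT the total number of
targets shown.  The fraction is 0 at LT=0, 1 at LT=NT, and strictly
increasing and convex in LT/NT, so late hits are worth more than early ones.
Payouts are kept as exact real cents; rounding is a presentation concern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gained_reward", "block_account"]


def gained_reward(coin_value: float, landed_targets, total_targets: int = 18):
    """Gained reward in cents for LT of NT targets hit. Vectorised over LT."""
    lt = np.asarray(landed_targets, dtype=float)
    if total_targets <= 0:
        raise ValueError("total_targets must be positive")
    if coin_value <= 0:
        raise ValueError("coin_value must be positive")
    if np.any(lt < 0) or np.any(lt > total_targets):
        raise ValueError("landed_targets must lie in [0, total_targets]")
    frac = lt / total_targets
    out = coin_value * (10.0**frac - (1.0 - frac)) / 10.0
    return float(out) if np.isscalar(landed_targets) else out


def block_account(trial_rewards, coin_values) -> pd.DataFrame:
    """Running total and progress-bar fraction over one block.

    ``bar_fraction`` scales the cumulative gained reward by the block's
    maximum possible earnings (the sum of the shown coin values), as the
    on-screen reward bar does.
    """
    gained = np.asarray(trial_rewards, dtype=float)
    coins = np.asarray(coin_values, dtype=float)
    if gained.shape != coins.shape:
        raise ValueError("trial_rewards and coin_values must have equal length")
    cumulative = np.cumsum(gained)
    return pd.DataFrame(
        {
            "gained_cents": gained,
            "cumulative_cents": cumulative,
            "bar_fraction": cumulative / coins.sum(),
        }
    )
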