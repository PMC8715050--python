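"""Subliminal-awareness criteria on 4AFC tables and paired-t power analysis.

A masked reward cue counts as subliminal when (a) group-level correct coin
identifications do not exceed chance (50% in this two-coin 4AFC, since the
seen/guess dimension does not affect correctness) and (b) the probability of
"seen" reports does not exceed 0.  Both are one-tailed one-sample t tests on
per-subject proportions pooled over the two test phases.  A stricter
per-subject criterion uses an exact one-sided binomial test against chance.

The sample-size computation inverts the power function of a paired t test via
the noncentral t distribution, the same computation standard power software
performs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AfcSummary",
    "GroupTestResult",
    "summarize_afc",
    "group_tests",
    "binomial_above_chance",
    "split_groups",
    "paired_t_power",
    "required_n_paired_t",
]


@dataclass(frozen=True)
class AfcSummary:
    subject: int
    duration_condition: str
    p_correct: float
    p_seen: float
    n_trials: int


@dataclass(frozen=True)
class GroupTestResult:
    """One-tailed one-sample t test of per-subject proportions."""

    null_value: float
    mean: float
    sd: float
    t: float
    p: float  # one-tailed (greater)
    dz: float
    n: int
    degenerate: bool  # zero variance across subjects


def summarize_afc(responses: pd.DataFrame) -> pd.DataFrame:
    """Per subject x duration proportions, pooled across test phases."""
    grouped = responses.groupby(["subject", "duration_condition"], as_index=False).agg(
        p_correct=("correct", "mean"),
        p_seen=("seen", "mean"),
        n_trials=("correct", "size"),
        n_correct=("correct", "sum"),
    )
    return grouped


def _one_tailed_greater(values, null_value) -> GroupTestResult:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        # all subjects identical: report direction only
        return GroupTestResult(
            null_value, mean, 0.0, np.nan,
            0.0 if mean > null_value else 1.0,
            np.nan, n, True,
        )
    t = (mean - null_value) / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, n - 1))
    dz = (mean - null_value) / sd
    return GroupTestResult(null_value, mean, sd, float(t), p, float(dz), n, False)


def group_tests(summaries: pd.DataFrame, duration_condition: str):
    """Group-level subliminality tests for one display duration.

    Returns ``(correct_vs_chance, seen_vs_zero)``: one-tailed (greater)
    one-sample t tests of per-subject correct proportions against 50% and of
    seen proportions against 0.
    """
    cell = summaries[summaries["duration_condition"] == duration_condition]
    return (
        _one_tailed_greater(cell["p_correct"], 0.5),
        _one_tailed_greater(cell["p_seen"], 0.0),
    )


def binomial_above_chance(correct: int, n: int, chance: float = 0.5, alpha: float = 0.05):
    """Exact one-sided binomial test: is the correct count above chance?

    Returns ``(above_chance, p)`` with p = P(X >= correct | Binomial(n, chance));
    the decision uses p <= alpha.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= correct <= n:
        raise ValueError("correct must lie in [0, n]")
    p = float(stats.binomtest(correct, n, chance, alternative="greater").pvalue)
    return p <= alpha, p


def split_groups(above_chance: dict) -> tuple[list, list]:
    """Partition subjects into (at-chance, above-chance) groups."""
    at_chance = sorted(s for s, flag in above_chance.items() if not flag)
    above = sorted(s for s, flag in above_chance.items() if flag)
    return at_chance, above


def paired_t_power(dz: float, n: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Power of a paired t test at effect size dz with n pairs."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = dz * np.sqrt(n)
    if tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    raise ValueError("tails must be 'one' or 'two'")


def required_n_paired_t(
    dz: float, alpha: float = 0.05, power: float = 0.8, tails: str = "one", n_max: int = 100000
) -> int:
    """Smallest n giving at least the target power for a paired t test."""
    if dz <= 0:
        raise ValueError("dz must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if paired_t_power(dz, n, alpha, tails) >= power:
            return n
    raise ValueError(f"power {power} not reached by n={n_max}")
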