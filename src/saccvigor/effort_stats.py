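"""Within-subject inferential layer: z-scoring, repeated-measures ANOVA with
Greenhouse-Geisser correction and a continuous between-subject covariate, and
Bonferroni-corrected paired post hoc comparisons with Cohen's dz.

The RM-ANOVA uses the contrast (multivariate) formulation: for every
within-subject effect an orthonormal contrast matrix C is applied to the
subject-by-cell matrix Y, and the transformed responses U = Y C are regressed
on the between-subject design X (intercept, mean-centred covariate, group
codes).  The univariate F for a between-term L is

    F = (tr(H) / (q * df_h)) / (tr(E) / (q * df_e)),

with H and E the hypothesis and error SSCP matrices and q the contrast
dimension; this reproduces the classical partitioned-SS repeated-measures
table for balanced designs without a covariate.  Sphericity is handled per
effect with the Greenhouse-Geisser epsilon

    eps = tr(Sigma)^2 / (q * tr(Sigma^2)),   Sigma = E / df_e,

which equals 1 exactly for 2-level factors and scales the F test's degrees of
freedom (the F value itself is unchanged).  Partial eta squared is
tr(H) / (tr(H) + tr(E)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import IncompleteDesignError

__all__ = [
    "AnovaEffect",
    "PairedComparison",
    "zscore_within_subject",
    "mean_center",
    "rm_anova",
    "posthoc_paired",
]


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p_gg: float
    p_uncorrected: float
    eta_p2: float


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple
    mean_diff: float
    t: float
    p_raw: float
    p_bonferroni: float
    dz: float
    n: int
    tails: str


def zscore_within_subject(values, ddof: int = 1) -> np.ndarray:
    """Standardise one subject's per-trial values to mean 0, SD 1.

    Zero-variance input yields all zeros (degenerate, but legal) rather than
    NaNs, so that constant subjects drop out of condition contrasts.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 trials to z-score")
    sd = v.std(ddof=ddof)
    if sd == 0.0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def mean_center(values) -> np.ndarray:
    """Centre a between-subject covariate so it sums to zero."""
    v = np.asarray(values, dtype=float)
    return v - v.mean()


def _orthonormal_contrast(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the complement of the unit vector."""
    basis = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))[0]
    return basis[:, 1:]


def _pivot_complete(data, dv, within, subject):
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise IncompleteDesignError(f"missing within-subject cells for subjects {bad}")
    # full factorial cell set, in a fixed level order
    levels = [sorted(data[f].unique(), key=str) for f in within]
    full = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(
        levels[0], name=within[0]
    )
    missing = set(full) - set(wide.columns)
    if missing:
        raise IncompleteDesignError(f"design has empty cells: {sorted(missing, key=str)}")
    wide = wide.reindex(columns=full)
    return wide, levels


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within,
    subject: str = "subject",
    covariate: str | None = None,
    between: str | None = None,
    include_covariate_interactions: bool = True,
) -> pd.DataFrame:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    data
        Long-format cell means: one row per subject x within-cell (per-trial
        data are averaged within cells first).
    dv, within, subject
        Dependent variable, list of within-subject factor columns (1-3
        factors), and the subject identifier column.
    covariate
        Optional subject-level continuous covariate; it is mean-centred and,
        when ``include_covariate_interactions`` is set, its interactions with
        every within effect are tested too.
    between
        Optional categorical between-subject factor (e.g. an awareness group).

    Returns a DataFrame with one row per effect: F, (uncorrected) df, the
    Greenhouse-Geisser epsilon, GG-corrected p, uncorrected p, and partial
    eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1 to 3 within-subject factors")
    for f in within:
        if data[f].nunique() < 2:
            raise ValueError(f"within factor {f!r} needs >= 2 levels")
    wide, levels = _pivot_complete(data, dv, within, subject)
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    subjects = wide.index

    # between-subject design
    X_cols = [np.ones(n)]
    term_names = ["(intercept)"]
    term_cols = {"(intercept)": [0]}
    if covariate is not None:
        cov = (
            data[[subject, covariate]].drop_duplicates(subject).set_index(subject)[covariate]
        )
        cov = mean_center(cov.reindex(subjects).to_numpy(dtype=float))
        term_cols[covariate] = [len(X_cols)]
        X_cols.append(cov)
        term_names.append(covariate)
    if between is not None:
        grp = (
            data[[subject, between]].drop_duplicates(subject).set_index(subject)[between]
        ).reindex(subjects)
        glevels = sorted(grp.unique(), key=str)
        cols = []
        for lev in glevels[1:]:  # treatment coding, centred
            d = (grp == lev).to_numpy(dtype=float)
            cols.append(d - d.mean())
        term_cols[between] = list(range(len(X_cols), len(X_cols) + len(cols)))
        X_cols.extend(cols)
        term_names.append(between)
    X = np.column_stack(X_cols)
    p_rank = np.linalg.matrix_rank(X)
    df_e = n - p_rank
    if df_e < 1:
        raise ValueError("not enough subjects for the between-subject design")
    XtX_inv = np.linalg.pinv(X.T @ X)

    # within-effect contrast matrices
    contrasts = [_orthonormal_contrast(len(lv)) for lv in levels]
    means = [np.full((len(lv), 1), 1.0 / np.sqrt(len(lv))) for lv in levels]

    def kron_all(mats):
        out = np.array([[1.0]])
        for m in mats:
            out = np.kron(out, m)
        return out

    effects = []  # (name, C, tested between-term)
    # within effects and their interactions with each between term
    for order in range(1, len(within) + 1):
        for combo in combinations(range(len(within)), order):
            mats = [contrasts[i] if i in combo else means[i] for i in range(len(within))]
            C = kron_all(mats)
            ename = ":".join(within[i] for i in combo)
            effects.append((ename, C, "(intercept)"))
            if covariate is not None and include_covariate_interactions:
                effects.append((f"{ename}:{covariate}", C, covariate))
            if between is not None:
                effects.append((f"{ename}:{between}", C, between))
    # between-subject effects (grand-mean contrast)
    C_mean = kron_all(means)
    if covariate is not None:
        effects.append((covariate, C_mean, covariate))
    if between is not None:
        effects.append((between, C_mean, between))

    rows = []
    for name, C, term in effects:
        U = Y @ C  # n x q
        q = C.shape[1]
        B = XtX_inv @ (X.T @ U)
        E = U.T @ U - B.T @ (X.T @ X) @ B
        cols = term_cols[term]
        L = np.zeros((len(cols), X.shape[1]))
        for r, cix in enumerate(cols):
            L[r, cix] = 1.0
        LB = L @ B
        M = np.linalg.pinv(L @ XtX_inv @ L.T)
        H = LB.T @ M @ LB
        df_h = len(cols)
        ss_eff = float(np.trace(H))
        ss_err = float(np.trace(E))
        df1 = q * df_h
        df2 = q * df_e
        if ss_err <= 0:
            F = np.inf
            p_unc = p_gg = 0.0
            eps = 1.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            if q > 1:
                sigma = E / df_e
                eps = float(np.trace(sigma) ** 2 / (q * np.trace(sigma @ sigma)))
                eps = float(np.clip(eps, 1.0 / q, 1.0))
            else:
                eps = 1.0
            p_unc = float(stats.f.sf(F, df1, df2))
            p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
        rows.append(
            AnovaEffect(
                effect=name,
                F=float(F),
                df1=float(df1),
                df2=float(df2),
                epsilon=eps,
                p_gg=p_gg,
                p_uncorrected=p_unc,
                eta_p2=float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0 else np.nan,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def posthoc_paired(
    cells: pd.DataFrame,
    dv: str,
    condition: str,
    pairs=None,
    subject: str = "subject",
    tails: str = "two",
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Paired t tests between condition cells with Bonferroni correction.

    ``cells`` holds one value per subject x condition; ``pairs`` is a list of
    (level_a, level_b) tuples (all pairwise by default).  One-tailed tests use
    the alternative mean(a) > mean(b).  ``p_bonferroni = min(1, p * m)`` with
    m the number of comparisons (overridable via ``n_comparisons`` when the
    family is larger than the pairs computed here).
    """
    wide = cells.pivot_table(index=subject, columns=condition, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    if pairs is None:
        pairs = list(combinations(levels, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for a, b in pairs:
        paired = wide[[a, b]].dropna()
        n = len(paired)
        if n < 2:
            raise ValueError(f"fewer than 2 complete subjects for pair {(a, b)}")
        d = paired[a].to_numpy(dtype=float) - paired[b].to_numpy(dtype=float)
        sd = d.std(ddof=1)
        if sd == 0.0:
            t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
            p_raw = 1.0 if d.mean() == 0 else 0.0
            dz = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        else:
            t = d.mean() / (sd / np.sqrt(n))
            if tails == "one":
                p_raw = float(stats.t.sf(t, n - 1))
            else:
                p_raw = float(2.0 * stats.t.sf(abs(t), n - 1))
            dz = d.mean() / sd
        rows.append(
            PairedComparison(
                pair=(a, b),
                mean_diff=float(d.mean()),
                t=float(t),
                p_raw=float(p_raw),
                p_bonferroni=float(min(1.0, p_raw * m)),
                dz=float(dz),
                n=n,
                tails=tails,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
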