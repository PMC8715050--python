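import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saccvigor.effort_stats import (
    mean_center,
    posthoc_paired,
    rm_anova,
    zscore_within_subject,
)
from saccvigor.exceptions import IncompleteDesignError


def _grid(n, levels_a=("a1", "a2"), levels_b=("b1", "b2", "b3"), seed=0, effect_a=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n):
        base = rng.normal(0, 1)
        for a in levels_a:
            for b in levels_b:
                y = base + rng.normal(0, 1) + (effect_a if a == levels_a[-1] else 0.0)
                rows.append({"subject": s, "A": a, "B": b, "y": y})
    return pd.DataFrame(rows)


def brute_force_two_factor_rm(df):
    """Classical partitioned-SS two-factor RM-ANOVA on a complete grid."""
    wide = df.pivot_table(index="subject", columns=["A", "B"], values="y")
    n = len(wide)
    a_levels = sorted(df["A"].unique())
    b_levels = sorted(df["B"].unique())
    a, b = len(a_levels), len(b_levels)
    y = wide.to_numpy().reshape(n, a, b)
    m = y.mean()
    m_s, m_a, m_b = y.mean((1, 2)), y.mean((0, 2)), y.mean((0, 1))
    m_ab, m_as, m_bs = y.mean(0), y.mean(2), y.mean(1)
    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_as - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = a * np.sum((m_bs - m_s[:, None] - m_b[None, :] + m) ** 2)
    ss_abs = np.sum(
        (
            y
            - m_ab[None]
            - m_as[:, :, None]
            - m_bs[:, None, :]
            + m_a[None, :, None]
            + m_b[None, None, :]
            + m_s[:, None, None]
            - m
        )
        ** 2
    )
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return {"A": f_a, "B": f_b, "A:B": f_ab}


class TestZScore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore_within_subject(rng.normal(5, 3, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(
        a=st.floats(0.1, 100), b=st.floats(-50, 50),
        seed=st.integers(0, 1000),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_affine_invariance(self, a, b, seed):
        v = np.random.default_rng(seed).normal(0, 1, 30)
        assert np.allclose(zscore_within_subject(v), zscore_within_subject(a * v + b), atol=1e-8)

    def test_zero_variance_maps_to_zeros(self):
        assert np.array_equal(zscore_within_subject(np.full(10, 3.0)), np.zeros(10))

    def test_equal_standardized_effects_align_across_scales(self):
        # two subjects with different raw scales but the same standardized
        # condition contrast produce identical z-scored contrasts
        cond = np.tile([0, 1], 20)
        raw1 = 10.0 + 2.0 * cond + 0.1 * np.sin(np.arange(40))
        raw2 = 500.0 + 100.0 * cond + 5.0 * np.sin(np.arange(40))
        z1, z2 = zscore_within_subject(raw1), zscore_within_subject(raw2)
        c1 = z1[cond == 1].mean() - z1[cond == 0].mean()
        c2 = z2[cond == 1].mean() - z2[cond == 0].mean()
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestMeanCenter:
    def test_sums_to_zero_and_idempotent(self):
        v = np.array([3.0, 1.0, 7.5, -2.0])
        c = mean_center(v)
        assert c.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(mean_center(c), c)

    def test_constant_covariate_all_zero(self):
        assert np.allclose(mean_center(np.full(5, 4.2)), 0.0)


class TestRmAnova:
    def test_two_level_factor_has_unit_epsilon(self):
        res = rm_anova(_grid(10), "y", ["A", "B"], "subject")
        assert res.loc[res["effect"] == "A", "epsilon"].iloc[0] == 1.0

    def test_matches_brute_force_ss_decomposition_on_toy_grid(self):
        df = _grid(3, seed=42)
        res = rm_anova(df, "y", ["A", "B"], "subject").set_index("effect")
        brute = brute_force_two_factor_rm(df)
        for eff, f in brute.items():
            assert res.loc[eff, "F"] == pytest.approx(f, rel=1e-9)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        df = _grid(12, seed=3, effect_a=0.5)
        mine = rm_anova(df, "y", ["A", "B"], "subject").set_index("effect")
        ref = pg.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="subject", correction=True, effsize="np2"
        ).set_index("Source")
        for eff, src in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert mine.loc[eff, "p_gg"] == pytest.approx(ref.loc[src, "p_GG_corr"], rel=1e-6)
            assert mine.loc[eff, "epsilon"] == pytest.approx(ref.loc[src, "eps"], rel=1e-6)
            assert mine.loc[eff, "eta_p2"] == pytest.approx(ref.loc[src, "np2"], rel=1e-9)

    def test_gg_correction_conservative_where_it_matters(self):
        # the correction is conservative in the rejection region: for any
        # effect approaching significance the corrected p is never smaller
        for seed in range(8):
            res = rm_anova(_grid(8, seed=seed, effect_a=0.8), "y", ["A", "B"], "subject")
            small = res[res["p_uncorrected"] <= 0.1]
            assert (small["p_gg"] >= small["p_uncorrected"] - 1e-12).all()
            assert ((res["epsilon"] > 0) & (res["epsilon"] <= 1.0)).all()

    def test_partial_eta_invariant_to_centering_and_global_scale(self):
        # within-effect eta_p2 is exactly invariant to subtracting a
        # per-subject constant and to one common rescaling of the measure
        df = _grid(10, seed=9, effect_a=0.6)
        res_raw = rm_anova(df, "y", ["A", "B"], "subject").set_index("effect")
        dfz = df.copy()
        dfz["y"] = dfz.groupby("subject")["y"].transform(lambda v: v - v.mean()) * 3.7
        res_z = rm_anova(dfz, "y", ["A", "B"], "subject").set_index("effect")
        for eff in ("A", "B", "A:B"):
            assert res_z.loc[eff, "eta_p2"] == pytest.approx(res_raw.loc[eff, "eta_p2"], abs=1e-9)
            assert res_z.loc[eff, "F"] == pytest.approx(res_raw.loc[eff, "F"], rel=1e-9)

    def test_epsilon_approaches_one_under_compound_symmetry(self):
        # compound-symmetric covariance satisfies sphericity: for large n the
        # estimated epsilon concentrates near 1
        rng = np.random.default_rng(0)
        n = 400
        rows = []
        for s in range(n):
            base = rng.normal(0, 2)
            for b in ("b1", "b2", "b3"):
                rows.append({"subject": s, "B": b, "y": base + rng.normal(0, 1)})
        res = rm_anova(pd.DataFrame(rows), "y", ["B"], "subject")
        assert res.loc[res["effect"] == "B", "epsilon"].iloc[0] > 0.97

    def test_missing_cell_rejected(self):
        df = _grid(6).query("~(subject == 2 and A == 'a1' and B == 'b2')")
        with pytest.raises(IncompleteDesignError):
            rm_anova(df, "y", ["A", "B"], "subject")

    def test_single_level_factor_rejected(self):
        df = _grid(6).query("A == 'a1'")
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["A", "B"], "subject")

    def test_covariate_and_group_terms_present(self):
        df = _grid(12, seed=1)
        cov = {s: float(s) for s in range(12)}
        df["vis"] = df["subject"].map(cov)
        df["grp"] = np.where(df["subject"] % 2 == 0, "g1", "g2")
        res = rm_anova(df, "y", ["A", "B"], "subject", covariate="vis", between="grp")
        names = set(res["effect"])
        assert {"A", "B", "A:B", "vis", "grp", "A:vis", "A:grp"} <= names

    def test_three_within_factors_supported(self):
        rng = np.random.default_rng(2)
        rows = [
            {"subject": s, "A": a, "B": b, "C": c, "y": rng.normal()}
            for s in range(8)
            for a in ("a1", "a2")
            for b in ("b1", "b2", "b3")
            for c in ("c1", "c2")
        ]
        res = rm_anova(pd.DataFrame(rows), "y", ["A", "B", "C"], "subject")
        assert "A:B:C" in set(res["effect"])


class TestPosthoc:
    def _cells(self, diffs, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(len(diffs)):
            base = rng.normal(0, 1)
            rows.append({"subject": s, "cond": "hi", "y": base + diffs[s]})
            rows.append({"subject": s, "cond": "lo", "y": base})
        return pd.DataFrame(rows)

    def test_identical_vectors_give_null_result(self):
        cells = self._cells(np.zeros(6))
        res = posthoc_paired(cells, "y", "cond", pairs=[("hi", "lo")])
        r = res.iloc[0]
        assert r["t"] == 0.0 and r["p_raw"] == 1.0 and r["dz"] == 0.0

    def test_single_comparison_uncorrected(self):
        cells = self._cells(np.random.default_rng(1).normal(0.5, 1, 10))
        res = posthoc_paired(cells, "y", "cond", pairs=[("hi", "lo")])
        assert res.iloc[0]["p_bonferroni"] == res.iloc[0]["p_raw"]

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(8):
            for c in ("c1", "c2", "c3"):
                rows.append({"subject": s, "cond": c, "y": rng.normal()})
        res = posthoc_paired(pd.DataFrame(rows), "y", "cond")
        assert len(res) == 3
        assert np.allclose(
            res["p_bonferroni"], np.minimum(1.0, res["p_raw"] * 3), atol=1e-12
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            posthoc_paired(self._cells([0.1]), "y", "cond", pairs=[("hi", "lo")])
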