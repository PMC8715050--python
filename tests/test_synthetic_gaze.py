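import numpy as np
import pytest
from scipy import stats

from saccvigor.exceptions import (
    CohortError,
    CounterbalanceError,
    DegenerateWaveformError,
    InvalidGeometryError,
)
from saccvigor.synthetic_gaze import (
    AgentProfile,
    EffectSpec,
    PopulationParams,
    TaskGeometry,
    gain_contrast_for_dz,
    main_sequence_velocity,
    make_layout,
    make_schedule,
    synth_afc,
    synth_experiment,
    synth_saccade,
    synth_trial,
)


class TestLayout:
    def test_positions_on_ring_and_distinct(self, geometry):
        layout = make_layout(geometry, 1)
        assert layout.shape == (18, 2)
        radii = np.linalg.norm(layout, axis=1)
        assert np.all(np.abs(radii - 11.5) < 1e-9)
        assert len(np.unique(layout.round(12), axis=0)) == 18

    def test_exhaustive_draw_uses_every_candidate_once(self):
        geo = TaskGeometry(n_candidates=42, n_targets=42)
        layout = make_layout(geo, 3)
        assert len(np.unique(layout.round(12), axis=0)) == 42

    def test_same_seed_reproduces_layout(self, geometry):
        assert np.array_equal(make_layout(geometry, 7), make_layout(geometry, 7))

    def test_too_many_targets_rejected(self):
        with pytest.raises(InvalidGeometryError):
            TaskGeometry(n_candidates=10, n_targets=18)


class TestSchedule:
    def test_full_design_has_35_trials_per_cell(self):
        sched = make_schedule(5, 42, (1, 50), ("17", "D_indiv", "100"), 0)
        counts = sched.groupby(["reward_cents", "duration_condition"]).size()
        assert len(sched) == 210
        assert (counts == 35).all()

    def test_minimal_counterbalance(self):
        sched = make_schedule(1, 6, (1, 50), ("A", "B", "C"), 5)
        counts = sched.groupby(["reward_cents", "duration_condition"]).size()
        assert (counts == 1).all()

    def test_indivisible_totals_rejected(self):
        with pytest.raises(CounterbalanceError):
            make_schedule(5, 40, (1, 50), ("A", "B", "C"), 0)


class TestSynthSaccade:
    def test_peak_speed_matches_hyperbolic_law(self):
        # v(10) = 560 * (1 - 1/3.5) = 400 deg/s
        agent = AgentProfile(alpha=560.0, beta=0.25)
        _, speed, event = synth_saccade(10.0, (1.0, 0.0), agent, vel_gain=1.0, dt=1.0)
        assert event.true_peak_velocity == pytest.approx(400.0)
        assert speed.max() <= 400.0 + 1e-9

    def test_peak_speed_linear_in_gain(self):
        agent = AgentProfile()
        _, _, e1 = synth_saccade(8.0, (0.0, 1.0), agent, vel_gain=1.0)
        _, _, e2 = synth_saccade(8.0, (0.0, 1.0), agent, vel_gain=1.05)
        assert e2.true_peak_velocity == pytest.approx(1.05 * e1.true_peak_velocity)

    def test_trapezoid_integral_of_speed_equals_amplitude(self):
        # independent oracle: integrate the emitted speed profile
        agent = AgentProfile()
        _, speed, event = synth_saccade(10.0, (1.0, 0.0), agent, dt=1.0)
        step_s = event.true_offset / (len(speed) - 1) / 1000.0
        integral = np.trapezoid(speed, dx=step_s)
        assert integral == pytest.approx(10.0, abs=0.05)

    def test_displacement_path_length_matches_amplitude(self):
        agent = AgentProfile()
        disp, _, _ = synth_saccade(10.0, (0.6, 0.8), agent, dt=1.0)
        path = np.sum(np.linalg.norm(np.diff(disp, axis=0), axis=1))
        assert path == pytest.approx(10.0, rel=0.005)

    def test_speed_profile_unimodal_zero_at_ends(self):
        agent = AgentProfile()
        _, speed, _ = synth_saccade(12.0, (1.0, 0.0), agent, dt=1.0)
        assert speed[0] == pytest.approx(0.0, abs=1e-9)
        assert speed[-1] == pytest.approx(0.0, abs=1e-9)
        peak = np.argmax(speed)
        assert np.all(np.diff(speed[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(speed[peak:]) <= 1e-9)

    def test_waveform_too_short_for_sampling_step_rejected(self):
        # small saccades are slow (duration -> pi/(2*alpha*beta)), so only a
        # coarse sampling step makes the waveform unrepresentable
        with pytest.raises(DegenerateWaveformError):
            synth_saccade(0.05, (1.0, 0.0), AgentProfile(), dt=10.0)

    def test_kinematic_law_over_amplitude_range(self):
        # over 1,000 saccades in [2, 20] deg the generated peak obeys the law
        rng = np.random.default_rng(0)
        agent = AgentProfile()
        amps = rng.uniform(2.0, 20.0, 1000)
        for a in amps[:: 50]:
            _, _, ev = synth_saccade(a, (1.0, 0.0), agent)
            expected = main_sequence_velocity(a, agent.alpha, agent.beta)
            assert abs(ev.true_peak_velocity - expected) / expected < 0.005
        # and the sampled profiles stay within 0.5% for the full batch
        errs = []
        for a in amps:
            _, speed, ev = synth_saccade(a, (1.0, 0.0), agent)
            errs.append(abs(ev.true_peak_velocity - main_sequence_velocity(a, agent.alpha, agent.beta)))
        assert max(errs) < 0.005 * agent.alpha


class TestSynthTrial:
    def test_trace_consistent_with_ground_truth(self, geometry):
        rng = np.random.default_rng(2)
        agent = AgentProfile(noise_sd=0.0)
        layout = make_layout(geometry, rng)
        t, x, y, valid, events = synth_trial(layout, agent, (50, "100"), rng, geometry)
        assert len(t) == geometry.n_samples
        assert len(events) > 5
        # events ordered and non-overlapping
        onsets = [e.true_onset for e in events]
        offsets = [e.true_offset for e in events]
        assert all(onsets[i + 1] > offsets[i] for i in range(len(events) - 1))
        # trace is exactly still outside events (noiseless)
        speed = np.hypot(np.diff(x), np.diff(y)) * geometry.sampling_rate
        moving = speed > 1e-9
        for i in np.flatnonzero(moving):
            assert any(e.true_onset - 1.5 <= t[i] <= e.true_offset + 0.5 for e in events)

    def test_huge_pauses_give_pure_fixation(self, geometry):
        agent = AgentProfile(noise_sd=0.0, isi_mean=1e6, isi_sd=0.0)
        layout = make_layout(geometry, 0)
        t, x, y, valid, events = synth_trial(layout, agent, (1, "17"), 0, geometry)
        assert events == []
        assert np.all(x == 0.0) and np.all(y == 0.0)

    def test_frequency_gain_raises_saccade_count(self, geometry):
        lo, hi = [], []
        layout = make_layout(geometry, 0)
        for s in range(60):
            a_lo = AgentProfile(freq_gain_by_condition={(1, "17"): 0.9})
            a_hi = AgentProfile(freq_gain_by_condition={(1, "17"): 1.1})
            *_, ev_lo = synth_trial(layout, a_lo, (1, "17"), 1000 + s, geometry)
            *_, ev_hi = synth_trial(layout, a_hi, (1, "17"), 2000 + s, geometry)
            lo.append(len(ev_lo))
            hi.append(len(ev_hi))
        assert np.mean(hi) > np.mean(lo)


class TestSynthExperiment:
    def test_reproducible_from_master_seed(self):
        d1 = synth_experiment(3, seed=11, n_blocks=1, trials_per_block=6)
        d2 = synth_experiment(3, seed=11, n_blocks=1, trials_per_block=6)
        assert d1.trials.equals(d2.trials)
        assert d1.truth.equals(d2.truth)
        assert d1.afc.equals(d2.afc)
        for key in d1.traces:
            for a, b in zip(d1.traces[key], d2.traces[key]):
                assert np.array_equal(a, b)

    def test_cohort_of_one_rejected(self):
        with pytest.raises(CohortError):
            synth_experiment(1, seed=0)

    def test_true_means_reflect_injected_frequency_effect(self):
        data = synth_experiment(
            40, effects=EffectSpec(freq_dz=0.65), seed=5, include_traces=False
        )
        wide = data.true_means.pivot_table(
            index="subject", columns="reward_cents", values="true_frequency"
        )
        d = wide[50] - wide[1]
        assert d.mean() > 0
        dz = d.mean() / d.std(ddof=1)
        assert 0.3 < dz < 1.1  # one cohort's dz scatters around the target

    def test_null_effect_calibration(self):
        # with no injected effect the paired t rejects at ~alpha
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            data = synth_experiment(
                10,
                effects=EffectSpec(freq_dz=0.0),
                seed=int(rng.integers(2**31 - 1)),
                include_traces=False,
                include_afc=False,
            )
            wide = data.true_means.pivot_table(
                index="subject", columns="reward_cents", values="true_frequency"
            )
            d = (wide[50] - wide[1]).to_numpy()
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            rej += stats.t.sf(t, len(d) - 1) < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.035)

    def test_gain_contrast_closed_form_matches_simulation(self):
        pop = PopulationParams()
        c = gain_contrast_for_dz(0.65, 0.03, pop.freq_mean, pop.freq_sd)
        rng = np.random.default_rng(1)
        f = rng.normal(pop.freq_mean, pop.freq_sd, 200000)
        delta = rng.normal(c, 0.03, 200000)
        d = f * delta
        assert d.mean() / d.std(ddof=1) == pytest.approx(0.65, abs=0.01)


class TestSynthAfc:
    def test_chance_generator(self):
        tab = synth_afc(0.5, 0.2, 4000, 0)
        assert tab["correct"].mean() == pytest.approx(0.5, abs=0.03)

    def test_perfect_generator(self):
        tab = synth_afc(1.0, 1.0, 50, 0)
        assert tab["correct"].all()
        assert tab["seen"].all()
        assert (tab["response"] == "seen_" + tab["coin"].astype(str)).all()

    def test_correct_counts_binomially_distributed(self):
        # chi-square GOF of correct counts against Binomial(80, 0.61)
        rng = np.random.default_rng(7)
        counts = np.array(
            [synth_afc(0.61, 0.1, 80, rng)["correct"].sum() for _ in range(4000)]
        )
        lo, hi = 38, 60  # pool the tails outside this range
        edges = np.arange(lo, hi + 1)
        obs = np.array([(counts == k).sum() for k in edges], dtype=float)
        obs = np.concatenate([[np.sum(counts < lo)], obs, [np.sum(counts > hi)]])
        pmf = stats.binom.pmf(edges, 80, 0.61)
        exp = np.concatenate(
            [[stats.binom.cdf(lo - 1, 80, 0.61)], pmf, [stats.binom.sf(hi, 80, 0.61)]]
        ) * len(counts)
        chi2 = np.sum((obs - exp) ** 2 / exp)
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            synth_afc(1.2, 0.0, 10, 0)
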