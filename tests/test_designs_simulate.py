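"""Phase plans, the transfer rule, and the break-run-break generator."""

import numpy as np
import pytest

import peakshift as ps
from peakshift.designs import plan_experiment
from peakshift.simulate import SimConfig, make_subjects, sample_run_window


def cfg_for(design, **kw):
    return SimConfig(plan=plan_experiment(design), **kw)


class TestPlans:
    def test_16to32_probe_lengths_cover_96_to_128(self):
        plan = plan_experiment("exp1_16to32")
        assert plan.phase("change").probe_bounds() == (96.0, 128.0)
        assert plan.phase("test").probe_bounds() == (96.0, 128.0)

    def test_train_probe_bounds_follow_longest_duration(self):
        plan = plan_experiment("exp1_8to4")
        assert plan.phase("train").probe_bounds() == (48.0, 64.0)  # 3-4 x 16 s

    def test_control_keeps_exposed_cue_duration(self):
        plan = plan_experiment("exp1_control")
        assert plan.retrained_cues() == {"short": 8.0}
        assert plan.changed_cue_shift() == 0.0

    def test_exp2_maps_short_cue_to_12s(self):
        plan = plan_experiment("exp2_8to12")
        assert plan.retrained_cues()["short"] == 12.0
        assert plan.changed_cue_shift() == pytest.approx(0.5)

    def test_exp4_uncorrelated_flags_covariance_violation(self):
        assert plan_experiment("exp4a_uncorrelated").covariance_violated
        assert not plan_experiment("exp4a_correlated").covariance_violated

    def test_exp5_has_one_test_session_per_context(self):
        plan = plan_experiment("exp5_context")
        tests = [p for p in plan.phases if p.name == "test"]
        assert sorted(p.context for p in tests) == ["A", "B"]
        assert all(p.sessions == 1 for p in tests)
        assert plan.change_context == "B"

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            plan_experiment("exp9_nonsense")


class TestEffectivePeakTime:
    def test_changed_cue_expresses_new_duration(self):
        c = cfg_for("exp1_16to32")
        assert ps.effective_peak_time("long", "test", "A", c.plan, c) == 32.0

    def test_zero_transfer_keeps_training_duration(self):
        c = cfg_for("exp1_16to32", tau=0.0)
        assert ps.effective_peak_time("short", "test", "A", c.plan, c) == 8.0

    def test_transfer_arithmetic_at_calibration(self):
        # tau = 0.59 with a +100% changed-cue shift: 8 s -> 12.72 s
        c = cfg_for("exp1_16to32", tau=0.59)
        pt = ps.effective_peak_time("short", "test", "A", c.plan, c)
        assert pt == pytest.approx(8 * 1.59)

    def test_transfer_linearity_is_exact(self):
        # programmed shift of the unshifted cue equals tau * delta exactly
        for tau in (0.0, 0.25, 0.5, 1.0):
            c = cfg_for("exp1_16to32", tau=tau)
            pt = ps.effective_peak_time("short", "test", "A", c.plan, c)
            assert 100 * (pt - 8) / 8 == pytest.approx(100 * tau * 1.0)

    def test_covariance_violation_blocks_transfer(self):
        c = cfg_for("exp4a_uncorrelated", tau=0.8)
        assert ps.effective_peak_time("medium", "test", "A", c.plan, c) == 8.0

    def test_context_attenuation_applies_off_context(self):
        c = cfg_for("exp5_context", tau=0.5, context_attenuation=0.4)
        in_ctx = ps.effective_peak_time("short", "test", "B", c.plan, c)
        out_ctx = ps.effective_peak_time("short", "test", "A", c.plan, c)
        assert in_ctx == pytest.approx(8 * 1.5)
        assert out_ctx == pytest.approx(8 * 1.2)

    def test_unknown_cue_raises(self):
        c = cfg_for("exp1_8to4")
        with pytest.raises(KeyError):
            ps.effective_peak_time("nope", "test", "A", c.plan, c)


class TestSampleTrial:
    def test_zero_baseline_confines_responses_to_run(self, rng):
        c = cfg_for("exp1_8to4", r_low=0.0)
        for _ in range(50):
            t = ps.sample_trial(16.0, "probe", 64.0, 16.0, c, rng,
                                meta=_meta())
            if t.n_responses:
                assert t.responses.min() >= 16 * (1 - c.omega) - 3 * c.gamma * 16 - 20
                # all responses within the (noisy) run window: check via gaps
                assert t.responses.max() - t.responses.min() <= 2 * c.omega * 16 * 2.5

    def test_degenerate_noise_gives_exact_window(self, rng):
        c = cfg_for("exp1_8to4", gamma=0.0, eta=0.0, r_low=0.0, r_high=5.0)
        t = ps.sample_trial(16.0, "probe", 64.0, 16.0, c, rng, meta=_meta())
        lo, hi = 16 * (1 - c.omega), 16 * (1 + c.omega)
        assert np.all((t.responses >= lo) & (t.responses <= hi))

    def test_mean_count_matches_poisson_expectation(self, rng):
        # analytic oracle: with gamma = eta = 0 and r_low = 0, the count is
        # Poisson with mean r_high * 2 * omega * pt = 16.8
        c = cfg_for("exp1_8to4", gamma=0.0, eta=0.0, r_low=0.0,
                    r_high=1.5, omega=0.35)
        n = 10_000
        counts = [
            ps.sample_trial(16.0, "probe", 64.0, 16.0, c, rng, meta=_meta()).n_responses
            for _ in range(n)
        ]
        expected = 1.5 * 2 * 0.35 * 16.0
        assert np.mean(counts) == pytest.approx(expected, rel=0.01)

    def test_fi_trial_ends_at_first_response_past_criterion(self, rng):
        c = cfg_for("exp1_8to4")
        for _ in range(100):
            t = ps.sample_trial(8.0, "fi", None, 8.0, c, rng, meta=_meta())
            assert t.reinforced_time >= 8.0
            assert t.responses[-1] == pytest.approx(t.reinforced_time)
            inside = (t.responses > 8.0 + 1e-9) & (t.responses < t.reinforced_time - 1e-9)
            assert not inside.any()


class TestSimulate:
    def test_same_seed_reproduces_byte_identical_datasets(self):
        kw = dict(seed=3, n_subjects=2, sessions=1, trials_per_session=30)
        a = ps.simulate_design("exp1_8to4", **kw)
        b = ps.simulate_design("exp1_8to4", **kw)
        assert a == b

    def test_change_phase_contains_only_the_changed_cue(self, small_dataset):
        # 16-to-32: the unchanged cue is withheld until testing
        assert small_dataset.cues("change") == ["long"]
        assert set(small_dataset.cues("train")) == {"short", "long"}
        assert set(small_dataset.cues("test")) == {"short", "long"}

    def test_probe_fraction_matches_binomial_expectation(self):
        ds = ps.simulate_design("exp1_8to4", seed=11, n_subjects=2,
                                sessions=5, trials_per_session=1000)
        train = ds.select(phase="train")
        frac = sum(t.trial_type == "probe" for t in train) / len(train)
        assert frac == pytest.approx(0.30, abs=0.01)

    def test_test_phase_probe_only_cue_share(self):
        ds = ps.simulate_design("exp1_16to32", seed=5, n_subjects=2,
                                sessions=4, trials_per_session=500)
        test = ds.select(phase="test")
        short = [t for t in test if t.cue_id == "short"]
        assert all(t.trial_type == "probe" for t in short)
        assert len(short) / len(test) == pytest.approx(0.20, abs=0.02)

    def test_simulated_output_validates(self):
        for seed in (0, 1, 2):
            ds = ps.simulate_design("exp3_change", seed=seed, n_subjects=2,
                                    sessions=1, trials_per_session=40)
            assert ps.validate_dataset(ds) == []


class TestScalarProperty:
    def test_midpoint_cv_constant_across_intervals(self):
        # CV(run midpoints) is gamma at every peak time by construction;
        # checked empirically at Monte-Carlo scale
        c = cfg_for("exp1_8to4", gamma=0.15)
        rng = np.random.default_rng(99)
        cvs = []
        for pt in (8.0, 16.0, 32.0):
            m, _ = sample_run_window(pt, c, rng, size=5000)
            cvs.append(m.std(ddof=1) / m.mean())
        assert max(cvs) / min(cvs) < 1.06
        assert np.allclose(cvs, 0.15, atol=0.01)

    def test_tau_zero_test_equals_train_distribution_in_law(self):
        # with tau = 0 the unshifted cue's effective peak time is identical
        # at train and test, so identical RNG streams give identical trials
        c = cfg_for("exp1_16to32", tau=0.0)
        pt_train = ps.effective_peak_time("short", "train", "A", c.plan, c)
        pt_test = ps.effective_peak_time("short", "test", "A", c.plan, c)
        assert pt_train == pt_test
        r1 = np.random.default_rng(42)
        r2 = np.random.default_rng(42)
        t1 = ps.sample_trial(pt_train, "probe", 64.0, 8.0, c, r1, meta=_meta())
        t2 = ps.sample_trial(pt_test, "probe", 64.0, 8.0, c, r2, meta=_meta())
        assert np.array_equal(t1.responses, t2.responses)


def _meta():
    return dict(subject_id="s01", group="g", context="A", phase="train",
                session=1, trial_index=1, cue_id="c")


def test_subject_bias_fixed_across_phases():
    c = cfg_for("exp1_8to4", subject_bias_cv=0.2)
    subs = make_subjects(c)
    assert len(subs) == c.n_subjects
    for s in subs:
        assert set(s.bias) == {"short", "long"}
        assert all(b > 0 for b in s.bias.values())
    # same seed -> same biases
    subs2 = make_subjects(c)
    assert all(s1.bias == s2.bias for s1, s2 in zip(subs, subs2))


def test_simconfig_rejects_bad_parameters():
    plan = plan_experiment("exp1_8to4")
    with pytest.raises(ValueError):
        SimConfig(plan=plan, r_low=1.0, r_high=0.5)
    with pytest.raises(ValueError):
        SimConfig(plan=plan, omega=1.5)
    with pytest.raises(ValueError):
        SimConfig(plan=plan, context_attenuation=2.0)
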