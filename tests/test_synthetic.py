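"""Generator behavior: determinism, marginals, planted temporal structure."""

import numpy as np
import pandas as pd
import pytest

import memtrace as mt
from memtrace.calibration import alpha_to_binary_correlation, binary_correlation
from memtrace.synthetic import _ou_at_times, generate_session, simulate_responses


def _rng(seed):
    return np.random.default_rng(seed)


class TestSession:
    def test_clip_count_matches_interval_expectation(self):
        cfg = mt.experiment_i(seed=1)
        sess = generate_session(cfg, _rng(1), "x")
        expected = cfg.session_duration_s / cfg.interval_mean_s
        assert abs(len(sess.clip_ids) - expected) < 4 * np.sqrt(expected)

    def test_annotation_prevalence(self):
        cfg = mt.experiment_i(seed=2)
        cfg.feature_spec["faces_present"] = mt.binary_feature(0.6)
        sess = generate_session(cfg, _rng(2), "x")
        ann = sess.annotations
        faces = ann[ann["feature_name"] == "faces_present"]
        prev = (faces["feature_value"] == "yes").mean()
        assert prev == pytest.approx(0.6, abs=0.05)

    def test_zero_cv_signal_uncorrelated_with_familiarity(self):
        cfg = mt.experiment_i(seed=3, cv_signal=0.0)
        sess = generate_session(cfg, _rng(3), "x")
        r = np.corrcoef(sess.cv_features["f0"], sess.persistent)[0, 1]
        assert abs(r) < 0.05 * np.sqrt(500 / len(sess.clip_ids)) + 0.05

    def test_planted_cv_direction_tracks_familiarity(self):
        cfg = mt.experiment_i(seed=4, cv_signal=0.6)
        sess = generate_session(cfg, _rng(4), "x")
        r = np.corrcoef(sess.cv_features["f0"], sess.persistent)[0, 1]
        assert r > 0.4

    def test_ou_autocovariance_is_exponential(self):
        """The latent temporal process has exp(-dt/tau) autocorrelation at
        irregular sampling times (checked against many replicate paths)."""
        tau = 20.0
        rng = _rng(5)
        times = np.cumsum(rng.uniform(4, 10, size=60))
        paths = np.array([_ou_at_times(times, tau, _rng(100 + i)) for i in range(4000)])
        for i, j in [(0, 1), (0, 5), (10, 20), (30, 55)]:
            want = np.exp(-abs(times[j] - times[i]) / tau)
            got = np.corrcoef(paths[:, i], paths[:, j])[0, 1]
            assert got == pytest.approx(want, abs=0.05)


class TestResponses:
    def test_chance_subject(self):
        """d' = 0 with median criterion: percent correct and yes-rate ~ 50%."""
        cfg = mt.experiment_i(
            seed=6, d_prime_gen=0.0, d_prime_sd=0.0, criterion_gen=0.0,
            criterion_sd=0.0, session_duration_s=1500.0,
        )
        sess = generate_session(cfg, _rng(6), "t")
        donor = generate_session(cfg, _rng(7), "f")
        trials = simulate_responses(sess, donor, cfg, _rng(8), "s0")
        first = mt.StudyTable(trials=trials).first_presentations()
        assert first["correct"].mean() == pytest.approx(0.5, abs=0.035)
        assert (first["response"] == "yes").mean() == pytest.approx(0.5, abs=0.035)

    def test_dprime_recovery_single_subject(self):
        """A d'=0.72 generating subject yields a d' estimate near 0.72."""
        cfg = mt.experiment_ii(
            seed=9, d_prime_gen=0.72, d_prime_sd=0.0, criterion_sd=0.0,
            session_duration_s=3000.0, n_repeats=10,
        )
        sess = generate_session(cfg, _rng(9), "t")
        donor = generate_session(cfg, _rng(10), "f")
        trials = simulate_responses(sess, donor, cfg, _rng(11), "s0")
        summ = mt.summarize_subject(trials)
        assert summ.d_prime == pytest.approx(0.72, abs=0.22)

    def test_correctness_lag_correlation_decays_exponentially(self):
        """Dichotomized-process oracle: the binary lag correlation of target
        correctness follows the dichotomized exp(-dt/tau) latent curve."""
        cfg = mt.experiment_i(seed=12, session_duration_s=20000.0,
                              d_prime_sd=0.0, criterion_sd=0.0, n_repeats=5)
        w_g = cfg.variance_budget()["w_g"]
        p = cfg.expected_hit_rate
        sess = generate_session(cfg, _rng(12), "t")
        donor = generate_session(cfg, _rng(13), "f")
        trials = simulate_responses(sess, donor, cfg, _rng(14), "s0")
        first = mt.StudyTable(trials=trials).first_presentations()
        tgt = first[first["trial_type"] == "target"].sort_values("encode_time_s")
        t = tgt["encode_time_s"].to_numpy()
        c = tgt["correct"].to_numpy(dtype=float)
        lag = t[None, :] - t[:, None]
        for lo, hi in [(5, 15), (15, 30), (30, 60), (60, 120)]:
            iu, ju = np.nonzero((lag > lo) & (lag <= hi))
            emp = np.corrcoef(c[iu], c[ju])[0, 1]
            mid = lag[iu, ju].mean()
            want = binary_correlation(w_g * np.exp(-mid / cfg.tau_gen_s), p)
            assert emp == pytest.approx(want, abs=0.04)

    def test_repeat_agreement_close_to_target(self, small_cohort):
        pairs = small_cohort.repeat_pairs()
        # 4 subjects x 20 pairs: coarse binomial tolerance
        assert pairs["agree"].mean() == pytest.approx(0.781, abs=0.12)

    def test_session_too_short_for_repeats(self):
        cfg = mt.experiment_i(seed=15, session_duration_s=120.0, n_repeats=25)
        sess = generate_session(cfg, _rng(15), "t")
        donor = generate_session(cfg, _rng(16), "f")
        with pytest.raises(mt.CalibrationError, match="repeat"):
            simulate_responses(sess, donor, cfg, _rng(17), "s0")


class TestCohort:
    def test_same_config_same_seed_identical(self):
        cfg = dict(n_subjects=2, session_duration_s=400.0, n_repeats=5,
                   cv_dim=4, seed=77)
        a = mt.build_cohort(mt.experiment_i(**cfg))
        b = mt.build_cohort(mt.experiment_i(**cfg))
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.cv_features, b.cv_features)

    def test_subject_seed_derivation_is_stable(self):
        ss = mt.subject_seed(123, 5)
        assert ss.entropy == 123 and ss.spawn_key == (5,)

    def test_single_subject_cohort_is_balanced(self):
        cfg = mt.experiment_i(n_subjects=1, session_duration_s=400.0,
                              n_repeats=5, cv_dim=4, seed=21)
        study = mt.build_cohort(cfg)
        rep = mt.validate_balance(study)
        assert rep["balanced"].all()

    def test_cohort_mean_accuracy_near_configured_expectation(self):
        cfg = mt.experiment_i(n_subjects=16, session_duration_s=900.0,
                              n_repeats=10, cv_dim=4, seed=22)
        study = mt.build_cohort(cfg)
        pc = mt.summarize_subjects(study)["percent_correct"].mean()
        assert pc == pytest.approx(cfg.expected_percent_correct, abs=2.0)

    def test_conditional_probability_identity(self):
        """P(C=1 | C'=1) = p + rho_C (1-p), the identity linking the binary
        correlation to the conditional curve."""
        from memtrace.calibration import conditional_given_correct
        p, rho_c = 0.557, alpha_to_binary_correlation(0.32, 0.557)
        p11 = p * p + rho_c * p * (1 - p)
        assert conditional_given_correct(p, rho_c) == pytest.approx(p11 / p)
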