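"""Unit and property tests for the retrieval race simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lv05abc.retrieval import (
    CONDITIONS,
    ConditionSchedule,
    LV05Config,
    ParticipantParams,
    ScheduleError,
    cue_weights_from_ratio,
    expected_effect_quadrature,
    expected_latency_quadrature,
    mean_activations,
    predict_summaries,
    simulate_retrieval_trials,
)


class TestCueWeights:
    @pytest.mark.parametrize(
        "cw, total, expected",
        [
            (1.0, 1.0, (0.5, 0.5)),
            (3.0, 1.0, (0.75, 0.25)),
            (4.0, 2.0, (1.6, 0.4)),
        ],
    )
    def test_known_splits(self, cw, total, expected):
        assert cue_weights_from_ratio(cw, total) == pytest.approx(expected)

    @pytest.mark.parametrize("cw, total", [(0.5, 1.0), (0.0, 1.0), (2.0, 0.0), (2.0, -1.0)])
    def test_domain_errors_name_offender(self, cw, total):
        with pytest.raises(ValueError, match=r"CW|W_total"):
            cue_weights_from_ratio(cw, total)

    @given(
        cw=st.floats(min_value=1.0, max_value=50.0),
        total=st.floats(min_value=1e-3, max_value=100.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_ratio_and_budget_conserved(self, cw, total):
        w_s, w_n = cue_weights_from_ratio(cw, total)
        assert w_s + w_n == pytest.approx(total, rel=1e-12)
        assert w_s / w_n == pytest.approx(cw, rel=1e-9)


class TestSchedule:
    def test_match_layout(self):
        mm = ConditionSchedule.for_condition("multiple_match")
        sm = ConditionSchedule.for_condition("single_match")
        # target: structural cue only, in both conditions
        assert mm.match_matrix[0].tolist() == [1, 0]
        assert sm.match_matrix[0].tolist() == [1, 0]
        # distractor: number cue only in multiple_match
        assert mm.match_matrix[1].tolist() == [0, 1]
        assert sm.match_matrix[1].tolist() == [0, 0]

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ScheduleError):
            ConditionSchedule.for_condition("no_such_condition")
        with pytest.raises(ScheduleError):
            ConditionSchedule("single_match", np.array([[1, 0], [0, 1]]))
        with pytest.raises(ScheduleError):
            ConditionSchedule("multiple_match", np.array([[1, 0, 0], [0, 1, 0]]))


class TestTrials:
    def test_zero_noise_target_always_wins(self):
        cfg = LV05Config(sigma=0.0)
        p = ParticipantParams(LF=0.2, CW=2.0)
        trials = simulate_retrieval_trials(
            p, cfg, ConditionSchedule.for_condition("multiple_match"), 10, seed=0
        )
        w_s, _ = cue_weights_from_ratio(2.0, cfg.W_total)
        assert all(t.winner == "target" for t in trials)
        assert np.allclose(trials.rt, 0.2 * np.exp(-w_s * cfg.S_assoc))

    def test_symmetric_race_is_fair(self):
        cfg = LV05Config(sigma=0.25)
        p = ParticipantParams(LF=0.2, CW=1.0)
        trials = simulate_retrieval_trials(
            p, cfg, ConditionSchedule.for_condition("multiple_match"), 100_000, seed=7
        )
        frac = np.mean(trials.winner == "distractor")
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(100_000))

    def test_single_match_distractor_win_probability(self):
        # P(distractor wins) = Phi(-Delta / (sigma*sqrt(2))) for activation
        # gap Delta; high-precision normal-CDF oracle
        cfg = LV05Config(sigma=0.25, S_assoc=1.0, B_base=0.0, W_total=1.0)
        p = ParticipantParams(LF=0.2, CW=1.0)
        n = 200_000
        trials = simulate_retrieval_trials(
            p, cfg, ConditionSchedule.for_condition("single_match"), n, seed=11
        )
        frac = np.mean(trials.winner == "distractor")
        expected = stats.norm.cdf(-0.5 / (0.25 * np.sqrt(2)))
        assert expected == pytest.approx(0.0786, abs=5e-4)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n))

    def test_seed_reproducibility_and_empty_error(self):
        cfg = LV05Config()
        p = ParticipantParams(LF=0.2, CW=1.5)
        sched = ConditionSchedule.for_condition("multiple_match")
        a = simulate_retrieval_trials(p, cfg, sched, 50, seed=3)
        b = simulate_retrieval_trials(p, cfg, sched, 50, seed=3)
        assert np.array_equal(a.rt, b.rt) and np.array_equal(a.winner, b.winner)
        with pytest.raises(ValueError):
            simulate_retrieval_trials(p, cfg, sched, 0, seed=3)

    def test_threshold_flagging_keeps_trials(self):
        cfg = LV05Config(sigma=0.25, threshold_enabled=True, threshold=0.5)
        p = ParticipantParams(LF=0.2, CW=1.0)
        trials = simulate_retrieval_trials(
            p, cfg, ConditionSchedule.for_condition("single_match"), 2000, seed=5
        )
        assert len(trials) == 2000  # flagged, not dropped
        assert trials.below_threshold.any()
        A_win = np.maximum(trials.A_target, trials.A_distractor)
        assert np.array_equal(trials.below_threshold, A_win < 0.5)


class TestSummaries:
    @pytest.mark.parametrize("cw", [1.0, 2.0, 4.0])
    def test_zero_noise_null_effect(self, cw):
        cfg = LV05Config(sigma=0.0, n_trials=500)
        s = predict_summaries(ParticipantParams(LF=0.3, CW=cw), cfg, seed=1)
        assert s.effect_ms == 0.0

    def test_doubling_lf_doubles_summaries_exactly(self):
        cfg = LV05Config(n_trials=5000)
        s1 = predict_summaries(ParticipantParams(LF=0.15, CW=1.5), cfg, seed=42)
        s2 = predict_summaries(ParticipantParams(LF=0.30, CW=1.5), cfg, seed=42)
        assert s2.effect_ms == 2.0 * s1.effect_ms
        assert s2.mean_rt_ms == 2.0 * s1.mean_rt_ms

    def test_mc_matches_quadrature_oracle(self):
        cfg = LV05Config(n_trials=100_000)
        p = ParticipantParams(LF=0.2, CW=1.0)
        s = predict_summaries(p, cfg, seed=2024)
        oracle = expected_effect_quadrature(p, cfg)
        assert s.effect_ms == pytest.approx(oracle, abs=3 * s.se_effect_ms)


class TestQuadrature:
    def test_closed_form_zero_noise(self):
        cfg = LV05Config(sigma=0.0, S_assoc=1.0, W_total=1.0, f=1.0)
        p = ParticipantParams(LF=0.2, CW=2.0)
        val = expected_latency_quadrature(
            p, cfg, ConditionSchedule.for_condition("multiple_match")
        )
        assert val == pytest.approx(0.2 * np.exp(-2.0 / 3.0), rel=1e-12)

    def test_tiny_noise_approaches_deterministic_limit(self):
        cfg = LV05Config(sigma=1e-9)
        p = ParticipantParams(LF=0.25, CW=3.0)
        sched = ConditionSchedule.for_condition("single_match")
        a = mean_activations(3.0, cfg, sched).max()
        assert expected_latency_quadrature(p, cfg, sched) == pytest.approx(
            0.25 * np.exp(-a), rel=1e-6
        )

    @pytest.mark.parametrize("cw", [1.0, 2.0, 4.0])
    @pytest.mark.parametrize("cond", CONDITIONS)
    def test_agrees_with_monte_carlo(self, cw, cond):
        cfg = LV05Config(sigma=0.25, n_trials=100_000)
        p = ParticipantParams(LF=0.2, CW=cw)
        sched = ConditionSchedule.for_condition(cond)
        trials = simulate_retrieval_trials(p, cfg, sched, cfg.n_trials, seed=9)
        mc_mean = trials.rt.mean()
        mc_se = trials.rt.std(ddof=1) / np.sqrt(cfg.n_trials)
        assert expected_latency_quadrature(p, cfg, sched) == pytest.approx(
            mc_mean, abs=3 * mc_se
        )


def test_facilitation_is_negative_and_attenuates_with_cue_weighting():
    cfg = LV05Config(sigma=0.25)
    effects = [
        expected_effect_quadrature(ParticipantParams(LF=0.2, CW=cw), cfg)
        for cw in (1.0, 1.5, 2.0, 3.0, 4.0)
    ]
    assert effects[0] < 0
    assert all(abs(a) >= abs(b) for a, b in zip(effects, effects[1:]))
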