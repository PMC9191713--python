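import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import explorepredict as ep
from explorepredict.learners import (FREE_PARAMS, MODELS, Learner,
                                     log_choice_probabilities, update_omega)
from reference_impl import OracleModel


def make_params(**kw):
    return ep.ModelParams(**kw)


class TestUpdateRules:
    def test_zero_rate_leaves_table_unchanged(self):
        t = np.full((3, 3), 1 / 3)
        assert np.array_equal(ep.update_ss(t, 0, 1, 0.0), t)

    def test_full_rate_gives_indicator_row(self):
        t = np.full((3, 3), 1 / 3)
        out = ep.update_ss(t, 2, 0, 1.0)
        assert np.allclose(out[2], [1.0, 0.0, 0.0])

    def test_half_rate_from_uniform(self):
        t = np.full((3, 3), 1 / 3)
        out = ep.update_ss(t, 0, 0, 0.5)
        assert np.allclose(out[0], [2 / 3, 1 / 6, 1 / 6])
        out2 = ep.update_sas(np.full((3, 3, 3), 1 / 3), 1, 2, 0, 0.5)
        assert np.allclose(out2[1, 2], [2 / 3, 1 / 6, 1 / 6])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2),
                              st.floats(0.0, 1.0)), min_size=1, max_size=40))
    def test_rows_stay_normalized_under_any_update_sequence(self, events):
        ss = np.full((3, 3), 1 / 3)
        for s, sn, alpha in events:
            ss = ep.update_ss(ss, s, sn, alpha)
        assert np.allclose(ss.sum(axis=1), 1.0, atol=1e-9)
        assert (ss >= 0).all() and (ss <= 1).all()

    def test_omega_update_values(self):
        assert update_omega(0.5, 0.9, 0.3, 0.0) == 0.5
        assert update_omega(0.5, 0.9, 0.3, 1.0) == pytest.approx(0.6)
        assert update_omega(0.0, 0.9, 0.3, 0.5) == pytest.approx(0.3)


class TestArbitrator:
    def test_midpoint_and_flat_slope(self):
        assert ep.arbitrator(0.37, 12.0, 0.37) == pytest.approx(0.5)
        assert ep.arbitrator(0.9, 0.0, -0.4) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert ep.arbitrator(0.2, 10.0, 0.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), abs=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(0, 50),
           st.floats(-0.5, 0.5))
    def test_monotone_nondecreasing_in_omega(self, o1, o2, beta, bias):
        lo, hi = min(o1, o2), max(o1, o2)
        assert ep.arbitrator(lo, beta, bias) <= ep.arbitrator(hi, beta, bias)


class TestChoiceProbabilities:
    def test_zero_temperature_is_uniform(self):
        assert np.allclose(ep.choice_probabilities(np.array([0.9, 0.05, 0.05]), 0.0),
                           [1 / 3] * 3)

    def test_equal_predictions_stay_uniform(self):
        assert np.allclose(ep.choice_probabilities(np.full(3, 1 / 3), 7.3),
                           [1 / 3] * 3)

    def test_softmax_value(self):
        p = ep.choice_probabilities(np.array([0.8, 0.1, 0.1]), 3.0)
        e = [math.exp(3 * 0.8), math.exp(3 * 0.1), math.exp(3 * 0.1)]
        assert np.allclose(p, np.array(e) / sum(e))
        assert p[0] == pytest.approx(0.8033, abs=5e-4)
        assert np.allclose(np.exp(log_choice_probabilities(np.array([0.8, 0.1, 0.1]), 3.0)), p)


class TestInitialization:
    def test_learned_models_start_uniform(self):
        lrn = Learner("spectator", make_params(alpha=0.3, beta_choice=5))
        assert np.allclose(lrn.ss, 1 / 3)

    def test_task_set_tables_encode_rules(self, rules):
        lrn = Learner("task_set", make_params(beta_omega=5), rules)
        assert np.array_equal(lrn.ss[0], [0, 0, 1])   # volcano -> lighthouse
        assert np.array_equal(lrn.sas[1, 0], [0, 1, 0])  # pink -> palm from anywhere
        assert set(np.unique(lrn.ss)) == {0.0, 1.0}

    def test_zero_bias_initial_omega_weight_is_half(self, rules):
        lrn = Learner("task_set", make_params(beta_omega=20, bias_omega=0.0), rules)
        assert lrn.omega_weight == pytest.approx(0.5)

    def test_task_set_requires_rules(self):
        with pytest.raises(ValueError):
            Learner("task_set", make_params())


class TestPrediction:
    def _mixing_learner(self, rules, bias):
        lrn = Learner("lts", make_params(alpha=0.5, alpha_omega=0.2,
                                         beta_omega=1.0, bias_omega=bias,
                                         beta_choice=3.0))
        lrn.sas[0, 0] = np.array([1.0, 0.0, 0.0])
        lrn.ss[0] = np.array([0.0, 1.0, 0.0])
        return lrn

    def test_pure_actor_and_pure_spectator_limits(self, rules):
        lrn = self._mixing_learner(rules, bias=-1e9)  # omega weight -> 1
        assert np.allclose(lrn.predict(0, 0), [1, 0, 0])
        lrn = self._mixing_learner(rules, bias=1e9)   # omega weight -> 0
        assert np.allclose(lrn.predict(0, 0), [0, 1, 0])

    def test_even_mixture(self, rules):
        lrn = self._mixing_learner(rules, bias=0.0)   # omega = 0 -> weight 0.5
        assert np.allclose(lrn.predict(0, 0), [0.5, 0.5, 0.0])

    def test_lts_with_saturated_weight_tracks_actor_exactly(self, rules):
        events = [(0, 0, 1), (1, 2, 2), (2, 1, 0), (0, 2, 2), (2, 0, 1)]
        lts = Learner("lts", make_params(alpha=0.4, alpha_omega=0.3,
                                         beta_omega=1.0, bias_omega=-1e9,
                                         beta_choice=2.0))
        actor = Learner("actor", make_params(alpha=0.4, beta_choice=2.0))
        spect = Learner("spectator", make_params(alpha=0.4, beta_choice=2.0))
        lts0 = Learner("lts", make_params(alpha=0.4, alpha_omega=0.3,
                                          beta_omega=1.0, bias_omega=1e9,
                                          beta_choice=2.0))
        for s, a, sn in events:
            for m in (lts, actor, spect, lts0):
                m.observe({"kind": "explore", "s": s, "a": a, "s_next": sn})
        for s in range(3):
            for a in range(3):
                assert np.allclose(lts.predict(s, a), actor.predict(s, a), atol=1e-12)
                assert np.allclose(lts0.predict(s, a), spect.predict(s, a), atol=1e-12)

    def test_actor_max_variant_renormalizes(self, rules):
        lrn = Learner("lts", make_params(alpha=0.5, alpha_omega=0.2,
                                         beta_omega=1.0, beta_choice=3.0),
                      eq5_actor_max=True)
        lrn.sas[1, 0] = np.array([0.8, 0.1, 0.1])
        pred = lrn.predict(0, 0)
        assert pred.sum() == pytest.approx(1.0, abs=1e-12)


class TestObserve:
    def test_condition_events_change_nothing(self, rules):
        lrn = Learner("lts", make_params(alpha=0.4, alpha_omega=0.2,
                                         beta_omega=5.0, beta_choice=2.0))
        ss, sas, om = lrn.ss.copy(), lrn.sas.copy(), lrn.omega_raw
        lrn.observe({"kind": "condition_pred"})
        lrn.observe({"kind": "condition_feedback", "condition": 1})
        assert np.array_equal(lrn.ss, ss) and np.array_equal(lrn.sas, sas)
        assert lrn.omega_raw == om

    def test_task_set_tables_frozen_after_events(self, rules):
        lrn = Learner("task_set", make_params(alpha_omega=0.4, beta_omega=10,
                                              beta_choice=3), rules)
        for s, a, sn in [(0, 1, 0), (0, 0, 1), (1, 2, 2), (2, 1, 1)]:
            lrn.observe({"kind": "explore", "s": s, "a": a, "s_next": sn})
        assert set(np.unique(lrn.ss)) == {0.0, 1.0}
        assert set(np.unique(lrn.sas)) == {0.0, 1.0}
        assert lrn.omega_raw != 0.0  # but the controllability evidence moved

    def test_malformed_event_rejected(self):
        lrn = Learner("spectator", make_params(alpha=0.2, beta_choice=1))
        with pytest.raises(ValueError):
            lrn.observe({"s": 0, "a": 1, "s_next": 2})


class TestOracleEquivalence:
    """The learner must replay identically to the brute-force reference."""

    @pytest.mark.parametrize("model_id,params", [
        ("spectator", dict(alpha=0.37, beta_choice=4.2)),
        ("actor", dict(alpha=0.51, beta_choice=2.8)),
        ("lts", dict(alpha=0.33, alpha_omega=0.21, beta_omega=9.5,
                     bias_omega=0.07, beta_choice=5.5)),
        ("task_set", dict(alpha_omega=0.44, beta_omega=14.0,
                          bias_omega=-0.1, beta_choice=7.0)),
    ])
    def test_toy_replay_matches_reference(self, rules, toy_event_records,
                                          model_id, params):
        full = {"alpha": 0.0, "alpha_omega": 0.0, "beta_omega": 0.0,
                "bias_omega": 0.0, "beta_choice": 1.0, **params}
        lrn = Learner(model_id, ep.ModelParams(**full), rules)
        oracle = OracleModel(model_id, full, rules.color_map, rules.route)
        for rec in toy_event_records:
            if rec.trial_type == "explore":
                lrn.observe({"kind": "explore", "s": rec.departure,
                             "a": rec.choice, "s_next": rec.outcome})
                oracle.learn(rec.departure, rec.choice, rec.outcome)
            else:
                got = lrn.predict(rec.departure, rec.queried_plane)
                want = oracle.predict(rec.departure, rec.queried_plane)
                assert np.allclose(got, want, atol=1e-12)
                assert np.allclose(ep.choice_probabilities(got, full["beta_choice"]),
                                   oracle.choice_probs(want), atol=1e-12)
                if rec.feedback:
                    correct = rec.choice == rec.outcome
                    lrn.observe({"kind": "prediction_feedback", "s": rec.departure,
                                 "a": rec.queried_plane, "s_next": rec.outcome,
                                 "choice": rec.choice, "correct": correct})
                    oracle.feedback(rec.departure, rec.queried_plane,
                                    rec.outcome, rec.choice, correct)
            assert abs(lrn.omega_raw - oracle.omega) < 1e-12
            assert np.allclose(lrn.ss, [[oracle.ss[(s, sn)] for sn in range(3)]
                                        for s in range(3)], atol=1e-12)


class TestConditionReadout:
    def test_threshold_and_tie_break(self):
        assert ep.condition_readout(0.9) == ep.CONTROLLABLE
        assert ep.condition_readout(0.5) == ep.UNCONTROLLABLE
        assert ep.condition_readout(0.1) == ep.UNCONTROLLABLE

    def test_models_without_arbitrator_refuse(self):
        lrn = Learner("actor", make_params(alpha=0.3, beta_choice=2))
        with pytest.raises(ValueError):
            lrn.condition_readout()

    def test_omega_sign_tracks_condition_in_deterministic_blocks(self, rules):
        params = make_params(alpha_omega=0.3, beta_omega=30.0,
                             bias_omega=0.0, beta_choice=5.0)
        rng = np.random.default_rng(0)
        ctrl = Learner("task_set", params, rules)
        state = 0
        for _ in range(60):  # always the diagnostic action, controllable rules
            a = ep.diagnostic_plane(state, rules)
            nxt = rules.color_map[a]
            ctrl.observe({"kind": "explore", "s": state, "a": a, "s_next": nxt})
            state = nxt
        assert ctrl.omega_raw > 0
        assert ctrl.condition_readout() == ep.CONTROLLABLE

        unctrl = Learner("task_set", params, rules)
        state = 0
        for _ in range(60):  # uncontrollable: route regardless of action
            a = int(rng.choice(ep.offered_planes(state, rules)))
            nxt = rules.route[state]
            unctrl.observe({"kind": "explore", "s": state, "a": a, "s_next": nxt})
            state = nxt
        assert unctrl.omega_raw <= 0
        assert unctrl.condition_readout() == ep.UNCONTROLLABLE
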