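import numpy as np
import pytest

import explorepredict as ep


@pytest.fixture(scope="session")
def rules():
    return ep.make_rules()


class ScriptedConditionAgent:
    """Test helper: knows the schedule, predicts rule destinations exactly."""

    def __init__(self, plan, rules):
        self.plan = plan
        self.rules = rules
        self.n_explore_seen = 0

    def _condition(self):
        i = min(self.n_explore_seen, self.plan.n_explore - 1)
        return self.plan.condition_of_trial(i)

    def choose_explore(self, state, offered):
        self.n_explore_seen += 1
        return offered[0]

    def predict_state(self, state, plane):
        # condition at probe time = condition of the last exploratory trial
        cond = self.plan.condition_of_trial(self.n_explore_seen - 1)
        return ep.nominal_destination(state, plane, cond, self.rules)

    def predict_condition(self):
        return self.plan.condition_of_trial(self.n_explore_seen - 1)

    def observe(self, event):
        pass


class UniformAgent:
    """Test helper: uniform-random responses everywhere."""

    def __init__(self, rng):
        self.rng = rng

    def choose_explore(self, state, offered):
        return offered[int(self.rng.integers(2))]

    def predict_state(self, state, plane):
        return int(self.rng.integers(3))

    def predict_condition(self):
        return int(self.rng.integers(2))

    def observe(self, event):
        pass


@pytest.fixture
def scripted_agent_cls():
    return ScriptedConditionAgent


@pytest.fixture
def uniform_agent_cls():
    return UniformAgent


@pytest.fixture(scope="session")
def ts_session(rules):
    """One Task Set agent's simulated main session (shared, read-only)."""
    spec = ep.AgentSpec(
        agent_id="ts0", model_id="task_set",
        params=ep.ModelParams(alpha_omega=0.3, beta_omega=10.0,
                              bias_omega=0.0, beta_choice=8.0),
        policy="epsilon_diagnostic", p_diag=0.6, lapse=0.0, seed=7)
    return ep.simulate_agent(spec, rules).session


@pytest.fixture(scope="session")
def toy_event_records(rules):
    """A 10-event toy stream mixing exploration and reinforced predictions."""
    from explorepredict.task_env import TrialRecord

    def explore(i, s, a, sn):
        return TrialRecord(i, "main", 0, 0, 1, "explore", s,
                           ep.offered_planes(s, rules), None, a, sn, None,
                           a == ep.diagnostic_plane(s, rules))

    def pred(i, s, plane, choice, outcome, fb):
        return TrialRecord(i, "main", 0, 0, 1, "state_pred", s,
                           ep.offered_planes(s, rules), plane, choice,
                           outcome if fb else None, fb, None)

    return [
        explore(0, 0, 2, 0),      # volcano, orange -> volcano (off-rule)
        explore(1, 0, 0, 1),      # volcano, pink -> palm
        pred(2, 1, 1, 0, 0, True),    # palm, green: predict volcano, correct
        pred(3, 1, 2, 2, None, False),
        explore(4, 1, 2, 2),      # palm, orange -> lighthouse
        explore(5, 2, 1, 0),      # lighthouse, green -> volcano
        pred(6, 0, 0, 1, 2, True),    # volcano, pink: predict palm, wrong (saw lighthouse)
        explore(7, 0, 2, 2),
        pred(8, 2, 0, 1, 1, True),    # lighthouse, pink: predict palm, correct
        explore(9, 2, 0, 1),
    ]
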