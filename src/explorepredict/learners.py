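"""Trial-by-trial learning models of controllability estimation.

Four models predict the upcoming island on state-prediction probes:

* **Spectator** — learns first-order transition probabilities P(s'|s) by a
  delta rule; assumes the environment is uncontrollable.
* **Actor** — learns action-conditional probabilities P(s'|s,a); assumes
  the environment is controllable.
* **Learned Transition Structure (LTS)** — learns both tables and tracks a
  controllability estimate Ω, the running average of the Actor-minus-
  Spectator predictive advantage for realized transitions.  A sigmoid of Ω
  (the arbitrator ω) mixes the two components' predictions.
* **Task Set** — same arbitration, but the component tables are frozen 0/1
  encodings of the instructed rules (first-order learning rate fixed at 0),
  formalizing hypothesis testing over the two instructed task sets.

Update rules (per observed transition s, a → s'):

    P(s'|s)   ← P(s'|s)   + α (1 − P(s'|s)),    others × (1 − α)
    P(s'|s,a) ← P(s'|s,a) + α (1 − P(s'|s,a)),  others × (1 − α)
    Ω ← Ω + α_Ω (P(s'|s,a) − P(s'|s) − Ω)       (pre-update predictions)
    ω = 1 / (1 + exp(−β_Ω (Ω − bias_Ω)))

State-prediction distributions are ω·actor-term + (1 − ω)·spectator-term
for the arbitration models, and response probabilities are a softmax of the
predicted distribution with inverse temperature β_choice.

Model variables are updated after every exploratory trial and after state
predictions that end with feedback; nothing updates on unreinforced
predictions or condition predictions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .task_env import (CONTROLLABLE, N_ACTIONS, N_STATES, UNCONTROLLABLE,
                       TaskRules)

MODELS = ("spectator", "actor", "lts", "task_set")

#: free parameters of each model, in canonical order
FREE_PARAMS = {
    "spectator": ("alpha", "beta_choice"),
    "actor": ("alpha", "beta_choice"),
    "lts": ("alpha", "alpha_omega", "beta_omega", "bias_omega", "beta_choice"),
    "task_set": ("alpha_omega", "beta_omega", "bias_omega", "beta_choice"),
}

FEEDBACK_MODES = ("asymmetric", "full_observation", "correct_only")


@dataclass
class ModelParams:
    """Free parameters; fields unused by a given model are ignored.

    alpha        first-order learning rate in [0, 1] (0 for Task Set)
    alpha_omega  second-order learning rate in [0, 1]
    beta_omega   arbitrator sigmoid slope, >= 0
    bias_omega   arbitrator threshold on Ω (real)
    beta_choice  softmax inverse temperature, >= 0
    """

    alpha: float = 0.0
    alpha_omega: float = 0.0
    beta_omega: float = 0.0
    bias_omega: float = 0.0
    beta_choice: float = 1.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def n_free_params(model_id: str) -> int:
    return len(FREE_PARAMS[model_id])


def update_ss(table: np.ndarray, s: int, s_next: int, alpha: float) -> np.ndarray:
    """Delta-rule update of a first-order transition table (returns a copy).

    The observed entry moves toward 1 with rate ``alpha``; the unobserved
    entries are multiplied by (1 − alpha), which is the delta rule toward 0
    and preserves the row sum exactly.
    """
    out = table.copy()
    row = out[s]
    p = row[s_next]
    row *= 1.0 - alpha
    row[s_next] = p + alpha * (1.0 - p)
    return out


def update_sas(table: np.ndarray, s: int, a: int, s_next: int, alpha: float) -> np.ndarray:
    """Delta-rule update of the (s, a) row of an action-conditional table."""
    out = table.copy()
    row = out[s, a]
    p = row[s_next]
    row *= 1.0 - alpha
    row[s_next] = p + alpha * (1.0 - p)
    return out


def update_omega(omega: float, p_sas: float, p_ss: float, alpha_omega: float) -> float:
    """Move Ω toward the Actor-minus-Spectator prediction difference."""
    return omega + alpha_omega * (p_sas - p_ss - omega)


def arbitrator(omega_raw: float, beta_omega: float, bias_omega: float) -> float:
    """Sigmoid transform of Ω into the arbitration weight ω ∈ (0, 1)."""
    z = beta_omega * (omega_raw - bias_omega)
    if z < -700.0:  # avoid exp overflow; sigmoid is 0/1 to double precision
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def choice_probabilities(pred: np.ndarray, beta_choice: float) -> np.ndarray:
    """Softmax over the three islands applied to predicted probabilities."""
    z = beta_choice * np.asarray(pred, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def log_choice_probabilities(pred: np.ndarray, beta_choice: float) -> np.ndarray:
    z = beta_choice * np.asarray(pred, dtype=float)
    z = z - z.max()
    return z - np.log(np.exp(z).sum())


def condition_readout(omega_weight: float) -> int:
    """Binary condition response: controllable iff ω > 0.5 (ties → uncontrollable)."""
    return CONTROLLABLE if omega_weight > 0.5 else UNCONTROLLABLE


class Learner:
    """Reference implementation of one model's evolving state.

    Parameters
    ----------
    model_id : one of :data:`MODELS`.
    params : ModelParams
    rules : TaskRules, required for ``task_set`` (frozen 0/1 tables).
    eq5_actor_max : if True, the arbitration actor-term is the elementwise
        maximum of P(s'|·, a) over departure states (the as-printed reading
        of the mixing equation), with the mixture renormalized; the default
        uses the current departure state's row, under which the mixture sums
        to 1 without renormalization.  For Task Set the two readings
        coincide because the color rule is state-independent.
    feedback_mode : how a reinforced state prediction updates the learner.
        "asymmetric" (default): correct feedback is a full observation of
        the realized transition; incorrect feedback multiplicatively
        decrements the predicted island only (no Ω update, as no realized
        state is revealed).  "full_observation": the realized outcome is
        always observed.  "correct_only": incorrect feedback is ignored.
    """

    def __init__(self, model_id: str, params: ModelParams,
                 rules: Optional[TaskRules] = None, *,
                 eq5_actor_max: bool = False,
                 feedback_mode: str = "asymmetric",
                 record_trace: bool = False):
        if model_id not in MODELS:
            raise ValueError(f"unknown model {model_id!r}")
        if feedback_mode not in FEEDBACK_MODES:
            raise ValueError(f"unknown feedback mode {feedback_mode!r}")
        if model_id == "task_set" and rules is None:
            raise ValueError("task_set requires task rules")
        self.model_id = model_id
        self.params = params
        self.rules = rules
        self.eq5_actor_max = eq5_actor_max
        self.feedback_mode = feedback_mode
        self.record_trace = record_trace
        self.trace: list[dict] = []

        if model_id == "task_set":
            self.ss = np.zeros((N_STATES, N_STATES))
            self.sas = np.zeros((N_STATES, N_ACTIONS, N_STATES))
            for s in range(N_STATES):
                self.ss[s, rules.route[s]] = 1.0
            for s in range(N_STATES):
                for a in range(N_ACTIONS):
                    self.sas[s, a, rules.color_map[a]] = 1.0
        else:
            self.ss = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
            self.sas = np.full((N_STATES, N_ACTIONS, N_STATES), 1.0 / N_STATES)
        self.omega_raw = 0.0

    # -- parameters ----------------------------------------------------
    @property
    def alpha(self) -> float:
        # first-order learning rate is fixed at 0 for the Task Set model
        return 0.0 if self.model_id == "task_set" else self.params.alpha

    @property
    def omega_weight(self) -> float:
        """Current arbitration weight ω (arbitration models only)."""
        if self.model_id not in ("lts", "task_set"):
            raise ValueError(f"{self.model_id} has no arbitrator")
        return arbitrator(self.omega_raw, self.params.beta_omega,
                          self.params.bias_omega)

    # -- prediction ----------------------------------------------------
    def predict(self, s: int, a: int) -> np.ndarray:
        """Predicted distribution over next islands for query (s, a)."""
        if self.model_id == "spectator":
            return self.ss[s].copy()
        if self.model_id == "actor":
            return self.sas[s, a].copy()
        w = self.omega_weight
        if self.eq5_actor_max:
            actor_term = self.sas[:, a, :].max(axis=0)
        else:
            actor_term = self.sas[s, a]
        pred = w * actor_term + (1.0 - w) * self.ss[s]
        if self.eq5_actor_max:
            pred = pred / pred.sum()
        return pred

    def condition_readout(self) -> int:
        return condition_readout(self.omega_weight)

    # -- learning ------------------------------------------------------
    def _observe_transition(self, s: int, a: int, s_next: int) -> None:
        if self.model_id in ("lts", "task_set"):
            p_sas = self.sas[s, a, s_next]
            p_ss = self.ss[s, s_next]
            self.omega_raw = update_omega(self.omega_raw, p_sas, p_ss,
                                          self.params.alpha_omega)
        if self.model_id in ("spectator", "lts"):
            self.ss = update_ss(self.ss, s, s_next, self.alpha)
        if self.model_id in ("actor", "lts"):
            self.sas = update_sas(self.sas, s, a, s_next, self.alpha)

    def _decrement(self, s: int, a: int, island: int) -> None:
        """Multiplicatively decrement ``island`` and renormalize (incorrect feedback)."""
        if self.model_id == "task_set":
            return
        alpha = self.alpha
        if self.model_id in ("spectator", "lts"):
            row = self.ss[s].copy()
            row[island] *= 1.0 - alpha
            self.ss[s] = row / row.sum()
        if self.model_id in ("actor", "lts"):
            row = self.sas[s, a].copy()
            row[island] *= 1.0 - alpha
            self.sas[s, a] = row / row.sum()

    def observe(self, event: dict) -> None:
        """Apply the model's update rule for one task event."""
        kind = event.get("kind")
        if kind == "explore":
            self._observe_transition(event["s"], event["a"], event["s_next"])
        elif kind == "prediction_feedback":
            if self.feedback_mode == "full_observation":
                self._observe_transition(event["s"], event["a"], event["s_next"])
            elif event["correct"]:
                self._observe_transition(event["s"], event["a"], event["s_next"])
            elif self.feedback_mode == "asymmetric":
                self._decrement(event["s"], event["a"], event["choice"])
        elif kind in ("condition_pred", "condition_feedback"):
            return  # no update rule applies
        else:
            if kind is None:
                raise ValueError(f"malformed event: {event!r}")
            return
        if self.record_trace:
            entry = {"kind": kind, "omega_raw": self.omega_raw}
            if self.model_id in ("lts", "task_set"):
                entry["omega"] = self.omega_weight
            self.trace.append(entry)


def replay_session(learner: Learner, session) -> dict:
    """Replay a logged session through a learner (reference likelihood path).

    Returns per-state-prediction log-likelihoods of the logged choices, the
    total negative log-likelihood (nats), and ω at each condition-prediction
    trial (NaN for models without an arbitrator).  The learner is mutated.
    """
    logps: list[float] = []
    omegas: list[float] = []
    pred_index: list[int] = []
    for rec in session.records:
        if rec.trial_type == "explore":
            learner.observe({"kind": "explore", "s": rec.departure,
                             "a": rec.choice, "s_next": rec.outcome})
        elif rec.trial_type == "state_pred":
            pred = learner.predict(rec.departure, rec.queried_plane)
            logp = log_choice_probabilities(pred, learner.params.beta_choice)
            logps.append(float(logp[rec.choice]))
            pred_index.append(rec.index)
            if rec.feedback:
                learner.observe({"kind": "prediction_feedback",
                                 "s": rec.departure, "a": rec.queried_plane,
                                 "s_next": rec.outcome, "choice": rec.choice,
                                 "correct": rec.choice == rec.outcome})
        elif rec.trial_type == "condition_pred":
            if learner.model_id in ("lts", "task_set"):
                omegas.append(learner.omega_weight)
            else:
                omegas.append(float("nan"))
    return {"logp": np.array(logps), "pred_index": np.array(pred_index),
            "nll": -float(np.sum(logps)), "omega": np.array(omegas)}
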