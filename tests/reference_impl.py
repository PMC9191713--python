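"""Independent brute-force reference of the learning equations.

Deliberately written in plain Python (dicts of floats, explicit loops,
no shared code with the package) so it can serve as an oracle for the
package's learner and likelihood implementations.
"""
import math

STATES = (0, 1, 2)
ACTIONS = (0, 1, 2)


class OracleModel:
    def __init__(self, model_id, params, color_map=None, route=None,
                 feedback_mode="asymmetric"):
        self.model_id = model_id
        self.p = dict(params)
        self.feedback_mode = feedback_mode
        if model_id == "task_set":
            self.ss = {(s, sn): (1.0 if route[s] == sn else 0.0)
                       for s in STATES for sn in STATES}
            self.sas = {(s, a, sn): (1.0 if color_map[a] == sn else 0.0)
                        for s in STATES for a in ACTIONS for sn in STATES}
            self.p["alpha"] = 0.0
        else:
            self.ss = {(s, sn): 1.0 / 3.0 for s in STATES for sn in STATES}
            self.sas = {(s, a, sn): 1.0 / 3.0
                        for s in STATES for a in ACTIONS for sn in STATES}
        self.omega = 0.0

    # Eq 4
    def omega_weight(self):
        return 1.0 / (1.0 + math.exp(-self.p["beta_omega"] *
                                     (self.omega - self.p["bias_omega"])))

    # Eq 5 (default actor-term = current departure state's row)
    def predict(self, s, a):
        if self.model_id == "spectator":
            return [self.ss[(s, sn)] for sn in STATES]
        if self.model_id == "actor":
            return [self.sas[(s, a, sn)] for sn in STATES]
        w = self.omega_weight()
        return [w * self.sas[(s, a, sn)] + (1.0 - w) * self.ss[(s, sn)]
                for sn in STATES]

    # Eq 6 with the denominator summing over all three islands
    def choice_probs(self, pred):
        beta = self.p["beta_choice"]
        exps = [math.exp(beta * q) for q in pred]
        tot = sum(exps)
        return [e / tot for e in exps]

    # Eqs 1-3 on a full observation of (s, a) -> s_next
    def learn(self, s, a, s_next):
        alpha = self.p["alpha"]
        if self.model_id in ("lts", "task_set"):
            delta = self.sas[(s, a, s_next)] - self.ss[(s, s_next)] - self.omega
            self.omega = self.omega + self.p["alpha_omega"] * delta
        if self.model_id in ("spectator", "lts"):
            for sn in STATES:
                if sn == s_next:
                    self.ss[(s, sn)] = self.ss[(s, sn)] + alpha * (1.0 - self.ss[(s, sn)])
                else:
                    self.ss[(s, sn)] = self.ss[(s, sn)] * (1.0 - alpha)
        if self.model_id in ("actor", "lts"):
            for sn in STATES:
                if sn == s_next:
                    self.sas[(s, a, sn)] = self.sas[(s, a, sn)] + alpha * (1.0 - self.sas[(s, a, sn)])
                else:
                    self.sas[(s, a, sn)] = self.sas[(s, a, sn)] * (1.0 - alpha)

    def feedback(self, s, a, s_next, choice, correct):
        if self.feedback_mode == "full_observation" or correct:
            self.learn(s, a, s_next)
        elif self.feedback_mode == "asymmetric" and self.model_id != "task_set":
            alpha = self.p["alpha"]
            if self.model_id in ("spectator", "lts"):
                self.ss[(s, choice)] *= 1.0 - alpha
                tot = sum(self.ss[(s, sn)] for sn in STATES)
                for sn in STATES:
                    self.ss[(s, sn)] /= tot
            if self.model_id in ("actor", "lts"):
                self.sas[(s, a, choice)] *= 1.0 - alpha
                tot = sum(self.sas[(s, a, sn)] for sn in STATES)
                for sn in STATES:
                    self.sas[(s, a, sn)] /= tot


def oracle_nll(model_id, params, records, color_map, route,
               feedback_mode="asymmetric"):
    """Replay a session's records; -sum log p(logged island) over state preds."""
    model = OracleModel(model_id, params, color_map, route, feedback_mode)
    nll = 0.0
    for rec in records:
        if rec.trial_type == "explore":
            model.learn(rec.departure, rec.choice, rec.outcome)
        elif rec.trial_type == "state_pred":
            probs = model.choice_probs(model.predict(rec.departure, rec.queried_plane))
            nll -= math.log(probs[rec.choice])
            if rec.feedback:
                model.feedback(rec.departure, rec.queried_plane, rec.outcome,
                               rec.choice, rec.choice == rec.outcome)
    return nll
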