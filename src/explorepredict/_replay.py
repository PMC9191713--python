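"""Compiled likelihood replay.

Model fitting evaluates the session likelihood thousands of times per
agent, so the trial-by-trial replay is compiled with numba.  The readable
reference path lives in :func:`explorepredict.learners.replay_session`; the
test suite asserts that the two agree to near machine precision on every
model.  Sessions are encoded once into flat integer arrays and the kernel
is reused across parameter proposals.
"""
from __future__ import annotations

import numpy as np
from numba import njit

MODEL_CODE = {"spectator": 0, "actor": 1, "lts": 2, "task_set": 3}
FEEDBACK_CODE = {"asymmetric": 0, "full_observation": 1, "correct_only": 2}

EXPLORE, STATE_PRED = 0, 1


def encode_session(session) -> dict:
    """Flatten a session's model-relevant events into arrays for the kernel.

    Condition predictions are dropped (they trigger no update and do not
    enter the likelihood).
    """
    etype, s_arr, a_arr, snext, choice, fb = [], [], [], [], [], []
    for rec in session.records:
        if rec.trial_type == "explore":
            etype.append(EXPLORE)
            s_arr.append(rec.departure)
            a_arr.append(rec.choice)
            snext.append(rec.outcome)
            choice.append(-1)
            fb.append(0)
        elif rec.trial_type == "state_pred":
            etype.append(STATE_PRED)
            s_arr.append(rec.departure)
            a_arr.append(rec.queried_plane)
            snext.append(-1 if rec.outcome is None else rec.outcome)
            choice.append(rec.choice)
            fb.append(1 if rec.feedback else 0)
    return {
        "etype": np.array(etype, dtype=np.int64),
        "s": np.array(s_arr, dtype=np.int64),
        "a": np.array(a_arr, dtype=np.int64),
        "s_next": np.array(snext, dtype=np.int64),
        "choice": np.array(choice, dtype=np.int64),
        "feedback": np.array(fb, dtype=np.int64),
        "color_map": np.array(session.rules.color_map, dtype=np.int64),
        "route": np.array(session.rules.route, dtype=np.int64),
    }


@njit(cache=True)
def replay_nll(model, alpha, alpha_omega, beta_omega, bias_omega, beta_choice,
               color_map, route, etype, s_arr, a_arr, snext, choice, feedback,
               eq5_actor_max, feedback_mode):  # pragma: no cover - exercised via wrapper
    """Negative log-likelihood of the logged state predictions (nats)."""
    ss = np.full((3, 3), 1.0 / 3.0)
    sas = np.full((3, 3, 3), 1.0 / 3.0)
    if model == 3:  # task_set: frozen 0/1 tables, alpha forced to 0
        ss[:, :] = 0.0
        sas[:, :, :] = 0.0
        for s in range(3):
            ss[s, route[s]] = 1.0
        for s in range(3):
            for a in range(3):
                sas[s, a, color_map[a]] = 1.0
        alpha = 0.0
    omega = 0.0
    nll = 0.0
    pred = np.empty(3)
    for t in range(etype.shape[0]):
        s = s_arr[t]
        a = a_arr[t]
        if etype[t] == 1:
            # likelihood of the logged island choice
            if model == 0:
                for i in range(3):
                    pred[i] = ss[s, i]
            elif model == 1:
                for i in range(3):
                    pred[i] = sas[s, a, i]
            else:
                w = 1.0 / (1.0 + np.exp(-beta_omega * (omega - bias_omega)))
                if eq5_actor_max == 1:
                    tot = 0.0
                    for i in range(3):
                        m = sas[0, a, i]
                        if sas[1, a, i] > m:
                            m = sas[1, a, i]
                        if sas[2, a, i] > m:
                            m = sas[2, a, i]
                        pred[i] = w * m + (1.0 - w) * ss[s, i]
                        tot += pred[i]
                    for i in range(3):
                        pred[i] /= tot
                else:
                    for i in range(3):
                        pred[i] = w * sas[s, a, i] + (1.0 - w) * ss[s, i]
            zmax = beta_choice * pred[0]
            for i in range(1, 3):
                if beta_choice * pred[i] > zmax:
                    zmax = beta_choice * pred[i]
            denom = 0.0
            for i in range(3):
                denom += np.exp(beta_choice * pred[i] - zmax)
            nll -= beta_choice * pred[choice[t]] - zmax - np.log(denom)

        # learning step
        full_obs = False
        decrement = False
        if etype[t] == 0:
            full_obs = True
        elif feedback[t] == 1:
            correct = choice[t] == snext[t]
            if feedback_mode == 1 or correct:
                full_obs = True
            elif feedback_mode == 0:
                decrement = True
        if full_obs:
            sn = snext[t]
            if model >= 2:
                omega += alpha_omega * (sas[s, a, sn] - ss[s, sn] - omega)
            if model == 0 or model == 2:
                p = ss[s, sn]
                for i in range(3):
                    ss[s, i] *= 1.0 - alpha
                ss[s, sn] = p + alpha * (1.0 - p)
            if model == 1 or model == 2:
                p = sas[s, a, sn]
                for i in range(3):
                    sas[s, a, i] *= 1.0 - alpha
                sas[s, a, sn] = p + alpha * (1.0 - p)
        elif decrement and model != 3:
            c = choice[t]
            if model == 0 or model == 2:
                ss[s, c] *= 1.0 - alpha
                tot = ss[s, 0] + ss[s, 1] + ss[s, 2]
                for i in range(3):
                    ss[s, i] /= tot
            if model == 1 or model == 2:
                sas[s, a, c] *= 1.0 - alpha
                tot = sas[s, a, 0] + sas[s, a, 1] + sas[s, a, 2]
                for i in range(3):
                    sas[s, a, i] /= tot
    return nll


def nll_from_encoded(model_id: str, params, enc: dict, *,
                     eq5_actor_max: bool = False,
                     feedback_mode: str = "asymmetric") -> float:
    """Evaluate the kernel for native-space parameters on an encoded session."""
    return float(replay_nll(
        MODEL_CODE[model_id], params.alpha, params.alpha_omega,
        params.beta_omega, params.bias_omega, params.beta_choice,
        enc["color_map"], enc["route"], enc["etype"], enc["s"], enc["a"],
        enc["s_next"], enc["choice"], enc["feedback"],
        1 if eq5_actor_max else 0, FEEDBACK_CODE[feedback_mode]))
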