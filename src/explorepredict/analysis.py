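"""Derived behavioral statistics for Explore-and-Predict sessions.

Accuracy scoring, diagnostic-choice proportions, state–action mutual
information, reversal-aligned accuracy profiles, the diagnostic-vs-random
policy simulation experiment, the median-split correlation contrast, and
the ω-vs-condition-prediction read-out check.

Scoring convention: analysis-level accuracy is judged against the
*nominal* (rule-consistent) destination under the true current condition,
whereas in-task feedback during a session used a sampled realized outcome.
The two roles are deliberately separate — feedback shows the participant a
realized flight, while accuracy asks whether they knew the rule.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .cohort import AgentSpec, ParamDists, SimResult, simulate_agent
from .learners import MODELS, ModelParams
from .task_env import (CONTROLLABLE, ScheduleConfig, SessionData, TaskRules,
                       UNCONTROLLABLE, make_rules, nominal_destination)

SLOPE_CAP = 25.0  # |logistic slope| cap under (quasi-)separation


@dataclass
class BehaviorSummary:
    """Per-agent behavioral summary statistics."""

    state_accuracy: float
    state_accuracy_by_condition: dict
    condition_accuracy: float
    diagnostic_proportion: float
    diagnostic_by_window: np.ndarray      # one value per probe window
    mutual_information: float             # bits
    state_acc_by_sets_since_reversal: pd.Series
    cond_acc_by_sets_since_reversal: pd.Series
    n_explore: int
    n_state_pred: int
    n_condition_pred: int


def _sets_since_reversal(session: SessionData) -> dict[int, int]:
    """Probe-set count since the last condition switch, keyed by record index.

    Bin 0 is the first probe set after a switch (or the first of the
    session).  Valid for schedules whose switches align with probe-set
    boundaries, which :func:`~explorepredict.task_env.build_schedule`
    guarantees.
    """
    out = {}
    set_counter = -1
    prev_cond = None
    for rec in session.records:
        if rec.trial_type == "explore":
            if prev_cond is not None and rec.condition != prev_cond:
                set_counter = -1
            prev_cond = rec.condition
        elif rec.trial_type == "state_pred":
            out[rec.index] = set_counter + 1
        elif rec.trial_type == "condition_pred":
            out[rec.index] = set_counter + 1
            set_counter += 1
    return out


def score_session(session: SessionData,
                  rules: Optional[TaskRules] = None) -> BehaviorSummary:
    """Score one session's probes and exploration."""
    rules = rules or session.rules
    explore = session.of_type("explore")
    state_pred = session.of_type("state_pred")
    cond_pred = session.of_type("condition_pred")

    state_correct = np.array(
        [r.choice == nominal_destination(r.departure, r.queried_plane,
                                         r.condition, rules)
         for r in state_pred], dtype=float)
    cond_correct = np.array([r.choice == r.condition for r in cond_pred],
                            dtype=float)
    by_cond = {}
    for cond, label in ((UNCONTROLLABLE, "uncontrollable"),
                        (CONTROLLABLE, "controllable")):
        mask = np.array([r.condition == cond for r in state_pred])
        by_cond[label] = float(state_correct[mask].mean()) if mask.any() else float("nan")

    diag = np.array([r.diagnostic_chosen for r in explore], dtype=float)
    period = session.plan.probe_period if session.plan is not None else 6
    n_windows = len(explore) // period
    windows = diag[:n_windows * period].reshape(n_windows, period).mean(axis=1)

    ssr = _sets_since_reversal(session)
    state_bins = pd.Series([ssr[r.index] for r in state_pred])
    cond_bins = pd.Series([ssr[r.index] for r in cond_pred])
    state_prof = pd.Series(state_correct).groupby(state_bins).mean()
    cond_prof = pd.Series(cond_correct).groupby(cond_bins).mean()

    return BehaviorSummary(
        state_accuracy=float(state_correct.mean()),
        state_accuracy_by_condition=by_cond,
        condition_accuracy=float(cond_correct.mean()),
        diagnostic_proportion=float(diag.mean()),
        diagnostic_by_window=windows,
        mutual_information=mutual_information(session),
        state_acc_by_sets_since_reversal=state_prof,
        cond_acc_by_sets_since_reversal=cond_prof,
        n_explore=len(explore),
        n_state_pred=len(state_pred),
        n_condition_pred=len(cond_pred),
    )


def mutual_information(session: SessionData) -> float:
    """Plug-in mutual information I(S; A) over exploratory trials, in bits.

    Empirical joint of (departure island, chosen plane); zero-count cells
    contribute 0; no bias correction.
    """
    explore = session.of_type("explore")
    if not explore:
        raise ValueError("session has no exploratory trials")
    s = [r.departure for r in explore]
    a = [r.choice for r in explore]
    return float(mutual_info_score(s, a) / math.log(2.0))


def summaries_frame(results: list[SimResult]) -> pd.DataFrame:
    """Tidy per-agent summary table for a simulated cohort."""
    rows = []
    for res in results:
        summ = score_session(res.session)
        rows.append({
            "agent_id": res.spec.agent_id,
            "model_id": res.spec.model_id,
            "age": res.spec.age,
            "p_diag": res.spec.p_diag,
            "state_accuracy": summ.state_accuracy,
            "condition_accuracy": summ.condition_accuracy,
            "diagnostic_proportion": summ.diagnostic_proportion,
            "mutual_information": summ.mutual_information,
        })
    return pd.DataFrame(rows)


def reversal_align(sessions: list[SessionData]) -> pd.DataFrame:
    """Mean probe accuracy by probe sets since the last condition switch."""
    state_profiles, cond_profiles = [], []
    for sess in sessions:
        summ = score_session(sess)
        state_profiles.append(summ.state_acc_by_sets_since_reversal)
        cond_profiles.append(summ.cond_acc_by_sets_since_reversal)
    state = pd.concat(state_profiles, axis=1).mean(axis=1)
    cond = pd.concat(cond_profiles, axis=1).mean(axis=1)
    return pd.DataFrame({"state_accuracy": state, "condition_accuracy": cond,
                         }).rename_axis("sets_since_reversal")


def fig4_experiment(gen_dists: Optional[ParamDists] = None,
                    n_per_cell: int = 20,
                    schedule_config: Optional[ScheduleConfig] = None,
                    seed: int = 0, lapse: float = 0.0) -> pd.DataFrame:
    """Condition-prediction accuracy by model class and exploration policy.

    Simulates ``n_per_cell`` agents per (model, policy) cell with policy in
    {diagnostic, random} and returns cell means with dispersion.  Fully
    diagnostic exploration helps only an agent that can test the instructed
    rules (Task Set); for the experience-driven models it starves the
    action-conditional statistics of variety.
    """
    gen_dists = gen_dists or ParamDists()
    rules = make_rules()
    rows = []
    for m_idx, model_id in enumerate(MODELS):
        for p_idx, policy in enumerate(("diagnostic", "random")):
            accs = []
            for i in range(n_per_cell):
                child = np.random.SeedSequence((seed, m_idx, p_idx, i))
                prng = np.random.default_rng(child.spawn(1)[0])
                params = gen_dists.sample(model_id, prng)
                spec = AgentSpec(agent_id=f"{model_id}-{policy}-{i}",
                                 model_id=model_id, params=params,
                                 policy=policy, lapse=lapse,
                                 seed=i)
                res = simulate_agent(spec, rules, schedule_config,
                                     seed_seq=child)
                accs.append(score_session(res.session).condition_accuracy)
            accs = np.array(accs)
            rows.append({"model_id": model_id, "policy": policy,
                         "mean_accuracy": float(accs.mean()),
                         "sd": float(accs.std(ddof=1)),
                         "n": n_per_cell})
    return pd.DataFrame(rows)


def median_split_contrast(summaries: pd.DataFrame,
                          covariate: str = "age",
                          split_on: str = "diagnostic_proportion",
                          outcome: str = "condition_accuracy") -> dict:
    """Fisher r-to-z contrast of covariate–accuracy correlations.

    Agents are split at the median of ``split_on``; within each half the
    Pearson correlation of ``outcome`` with ``covariate`` is computed and
    the two correlations are compared with the two-sample Fisher z test
    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)).
    """
    if summaries[covariate].nunique() < 2:
        raise ValueError("covariate is constant")
    med = summaries[split_on].median()
    high = summaries[summaries[split_on] > med]
    low = summaries[summaries[split_on] <= med]
    if len(high) < 4 or len(low) < 4:
        raise ValueError("need at least 4 agents per half")
    r_high = float(stats.pearsonr(high[covariate], high[outcome])[0])
    r_low = float(stats.pearsonr(low[covariate], low[outcome])[0])
    z, p = fisher_r_contrast(r_high, len(high), r_low, len(low))
    return {"r_high": r_high, "r_low": r_low, "n_high": len(high),
            "n_low": len(low), "z": z, "p": p}


def fisher_r_contrast(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample Fisher r-to-z contrast; returns (z, two-sided p)."""
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def omega_condition_check(results: list[SimResult]) -> dict:
    """Per-agent logistic slope of condition predictions on ω, plus group test.

    For each agent, fits a univariate logistic regression of the binary
    condition prediction (controllable = 1) on the arbitration weight ω at
    each condition-prediction trial, then runs a one-sample t-test of the
    slopes against zero.  Slopes are capped at ±25 under (quasi-)separation;
    agents with constant ω are excluded with a warning.
    """
    import statsmodels.api as sm

    slopes = []
    excluded = []
    for res in results:
        w = np.asarray(res.omega_at_condition_pred, dtype=float)
        y = np.array([r.choice for r in res.session.of_type("condition_pred")],
                     dtype=float)
        if len(w) != len(y):
            raise ValueError("ω trace does not align with condition predictions")
        if np.ptp(w) < 1e-12:
            excluded.append(res.spec.agent_id)
            continue
        X = sm.add_constant((w - w.mean()) / (w.std() + 1e-12))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            slope = float(fit.params[1])
        except Exception:
            # separation: sign from the empirical association, capped magnitude
            slope = math.copysign(SLOPE_CAP, np.corrcoef(w, y)[0, 1])
        if not np.isfinite(slope):
            slope = math.copysign(SLOPE_CAP, np.corrcoef(w, y)[0, 1])
        slopes.append(max(-SLOPE_CAP, min(SLOPE_CAP, slope)))
    if excluded:
        warnings.warn(f"excluded agents with constant ω: {excluded}")
    slopes = np.array(slopes)
    t, p = stats.ttest_1samp(slopes, 0.0)
    return {"slopes": slopes, "mean_slope": float(slopes.mean()),
            "t": float(t), "p": float(p), "df": len(slopes) - 1,
            "excluded": excluded}
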