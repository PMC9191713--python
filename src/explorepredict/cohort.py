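"""Synthetic participants for the Explore-and-Predict task.

Agents are instances of the four learning models equipped with an
exploration policy (how often they pick the condition-diagnostic plane), a
lapse rate mixing uniform responses into the probes, and an age-like
covariate.  The default cohort emulates the study's between-subject
structure: 90 agents in three equal age bands (8–12, 13–17, 18–25), a
model-class mixture shifting toward the inferential Task Set strategy with
age, and a diagnostic-choice propensity rising with age (0.40 → 0.75,
bracketing the 40% vs 71% halves of the study's median split).

The age covariate is purely synthetic: it drives the configured monotone
links and nothing else.

Randomness is split hierarchically: each agent receives an independent
child of the cohort seed keyed by its index, so per-agent results are
invariant to cohort size.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .learners import (FREE_PARAMS, MODELS, Learner, ModelParams, arbitrator,
                       choice_probabilities, condition_readout, update_omega)
from .task_env import (N_STATES, ScheduleConfig, SessionData, TaskRules,
                       build_schedule, diagnostic_plane, make_rules,
                       run_session)

POLICIES = ("random", "diagnostic", "epsilon_diagnostic")

# fixed auxiliary condition-readout tracker for Spectator/Actor agents
AUX_ALPHA_OMEGA = 0.2
AUX_BETA_OMEGA = 20.0
AUX_BIAS = 0.0


@dataclass(frozen=True)
class AgentSpec:
    """One synthetic participant."""

    agent_id: str
    model_id: str
    params: ModelParams
    policy: str = "epsilon_diagnostic"
    p_diag: float = 0.5
    lapse: float = 0.0
    age: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if not 0.0 <= self.p_diag <= 1.0:
            raise ValueError("p_diag must lie in [0, 1]")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


class ParamDists:
    """Generating distributions for model parameters.

    Defaults: α, α_Ω ~ Beta(2, 4); β_Ω ~ LogNormal(ln 10, 0.5);
    bias_Ω ~ Normal(0, 0.15); β_choice ~ LogNormal(ln 8, 0.5).  The study's
    fitted posteriors are only shown graphically, so these are configurable
    stand-ins chosen to give moderately noisy but informative behavior.
    """

    def __init__(self, **overrides: Callable[[np.random.Generator], float]):
        self.samplers: dict[str, Callable] = {
            "alpha": lambda rng: rng.beta(2.0, 4.0),
            "alpha_omega": lambda rng: rng.beta(2.0, 4.0),
            "beta_omega": lambda rng: rng.lognormal(math.log(10.0), 0.5),
            "bias_omega": lambda rng: rng.normal(0.0, 0.15),
            "beta_choice": lambda rng: rng.lognormal(math.log(8.0), 0.5),
        }
        self.samplers.update(overrides)

    def sample(self, model_id: str, rng: np.random.Generator) -> ModelParams:
        kwargs = {name: float(self.samplers[name](rng))
                  for name in FREE_PARAMS[model_id]}
        return ModelParams(**kwargs)


class LearnerAgent:
    """Wraps a learner with an exploration policy and probe response rules.

    Exploratory choices pick the diagnostic plane with probability
    ``p_diag`` ("random" → 0.5, "diagnostic" → 1).  State predictions are
    sampled from the softmax of the learner's predicted distribution, and
    condition predictions threshold the arbitration weight ω; both are
    replaced by a uniform guess with probability ``lapse``.

    Spectator and Actor have no arbitrator, so an auxiliary Ω-tracker
    (fixed α_Ω = 0.2, β_Ω = 20, bias 0) runs alongside for condition
    responses only, fed by the agent's own learned component prediction and
    a uniform 1/3 for the component it does not learn.
    """

    def __init__(self, spec: AgentSpec, rules: TaskRules,
                 rng: np.random.Generator, **learner_kwargs):
        self.spec = spec
        self.rules = rules
        self.rng = rng
        self.learner = Learner(spec.model_id, spec.params, rules,
                               **learner_kwargs)
        self.aux_omega = 0.0
        self.omega_at_condition_pred: list[float] = []
        if spec.policy == "random":
            self._p_diag = 0.5
        elif spec.policy == "diagnostic":
            self._p_diag = 1.0
        else:
            self._p_diag = spec.p_diag

    # -- agent protocol ------------------------------------------------
    def choose_explore(self, state: int, offered) -> int:
        diag = diagnostic_plane(state, self.rules)
        other = offered[0] if offered[1] == diag else offered[1]
        return diag if self.rng.random() < self._p_diag else other

    def predict_state(self, state: int, plane: int) -> int:
        if self.spec.lapse > 0.0 and self.rng.random() < self.spec.lapse:
            return int(self.rng.integers(N_STATES))
        probs = choice_probabilities(self.learner.predict(state, plane),
                                     self.spec.params.beta_choice)
        return int(self.rng.choice(N_STATES, p=probs))

    def _omega_weight(self) -> float:
        if self.spec.model_id in ("lts", "task_set"):
            return self.learner.omega_weight
        return arbitrator(self.aux_omega, AUX_BETA_OMEGA, AUX_BIAS)

    def predict_condition(self) -> int:
        w = self._omega_weight()
        self.omega_at_condition_pred.append(w)
        if self.spec.lapse > 0.0 and self.rng.random() < self.spec.lapse:
            return int(self.rng.integers(2))
        return condition_readout(w)

    def observe(self, event: dict) -> None:
        # auxiliary tracker consumes pre-update component predictions
        if self.spec.model_id in ("spectator", "actor") and "s_next" in event:
            is_obs = event["kind"] == "explore" or event.get("correct", False)
            if is_obs:
                s, a, sn = event["s"], event["a"], event["s_next"]
                if self.spec.model_id == "spectator":
                    p_sas, p_ss = 1.0 / 3.0, self.learner.ss[s, sn]
                else:
                    p_sas, p_ss = self.learner.sas[s, a, sn], 1.0 / 3.0
                self.aux_omega = update_omega(self.aux_omega, p_sas, p_ss,
                                              AUX_ALPHA_OMEGA)
        self.learner.observe(event)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator configuration (defaults emulate the study design)."""

    n_agents: int = 90
    age_bands: tuple = ((8.0, 12.0), (13.0, 17.0), (18.0, 25.0))
    age_range: tuple[float, float] = (8.0, 25.0)
    # Task Set mixture weight at the youngest / oldest age
    ts_weight: tuple[float, float] = (0.6, 0.95)
    # Spectator's share of the non-Task-Set remainder, youngest → oldest;
    # Actor and LTS split what is left equally
    spectator_share: tuple[float, float] = (0.6, 0.2)
    p_diag: tuple[float, float] = (0.4, 0.75)
    lapse: float = 0.05
    param_dists: ParamDists = field(default_factory=ParamDists)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0


def _lerp(age: float, lo_hi: tuple[float, float], age_range) -> float:
    a0, a1 = age_range
    t = min(max((age - a0) / (a1 - a0), 0.0), 1.0)
    return lo_hi[0] + t * (lo_hi[1] - lo_hi[0])


def mixture_weights(age: float, config: CohortConfig) -> np.ndarray:
    """Model-class probabilities (spectator, actor, lts, task_set) at an age."""
    ts = _lerp(age, config.ts_weight, config.age_range)
    rem = 1.0 - ts
    spec = rem * _lerp(age, config.spectator_share, config.age_range)
    other = (rem - spec) / 2.0
    w = np.array([spec, other, other, ts])
    return w / w.sum()


def draw_cohort(config: Optional[CohortConfig] = None,
                rng: Optional[np.random.Generator] = None) -> list[AgentSpec]:
    """Draw a reproducible cohort of agent specifications."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    agent_seeds = root.spawn(config.n_agents)
    if rng is None:
        rng = np.random.default_rng(root.spawn(1)[0])
    n_bands = len(config.age_bands)
    if config.n_agents % n_bands != 0:
        raise ValueError("n_agents must divide evenly across age bands")
    per_band = config.n_agents // n_bands
    specs = []
    i = 0
    for lo, hi in config.age_bands:
        for _ in range(per_band):
            sub = np.random.default_rng(agent_seeds[i])
            age = float(sub.uniform(lo, hi))
            w = mixture_weights(age, config)
            model_id = MODELS[int(sub.choice(len(MODELS), p=w))]
            params = config.param_dists.sample(model_id, sub)
            specs.append(AgentSpec(
                agent_id=f"agent{i:03d}", model_id=model_id, params=params,
                policy="epsilon_diagnostic",
                p_diag=_lerp(age, config.p_diag, config.age_range),
                lapse=config.lapse, age=age, seed=config.seed * 1000 + i))
            i += 1
    return specs


@dataclass
class SimResult:
    """One simulated agent: its spec, session log, and ω probe trace."""

    spec: AgentSpec
    session: SessionData
    omega_at_condition_pred: np.ndarray


def simulate_agent(spec: AgentSpec, rules: TaskRules,
                   schedule_config: Optional[ScheduleConfig] = None,
                   seed_seq: Optional[np.random.SeedSequence] = None,
                   **learner_kwargs) -> SimResult:
    """Simulate one agent through one freshly scheduled main session."""
    schedule_config = schedule_config or ScheduleConfig()
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(spec.seed)
    sched_rng, env_rng, agent_rng = (np.random.default_rng(s)
                                     for s in ss.spawn(3))
    plan = build_schedule(schedule_config, rng=sched_rng)
    agent = LearnerAgent(spec, rules, agent_rng, **learner_kwargs)
    session = run_session(agent, plan, rules, env_rng)
    session.meta.update(agent_id=spec.agent_id, model_id=spec.model_id,
                        age=spec.age, seed=spec.seed)
    return SimResult(spec, session,
                     np.array(agent.omega_at_condition_pred))


def simulate_cohort(specs: list[AgentSpec],
                    rules: Optional[TaskRules] = None,
                    schedule_config: Optional[ScheduleConfig] = None,
                    **learner_kwargs) -> list[SimResult]:
    """Simulate every agent; per-agent streams derive from each spec's seed."""
    rules = rules or make_rules()
    return [simulate_agent(spec, rules, schedule_config, **learner_kwargs)
            for spec in specs]
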