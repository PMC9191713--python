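"""Explore-and-Predict task environment.

The task is a covert-reversal paradigm probing controllability detection.
A plane departs from one of three islands (volcano, palm, lighthouse) and a
participant picks one of two colored planes (pink, green, orange; the color
mapping to the departure island itself is never offered).  In the
*controllable* condition the chosen color determines the destination via a
fixed color→island map; in the *uncontrollable* condition the plane follows
a fixed 3-cycle route irrespective of the choice.  Conditions alternate
covertly across 12 blocks (11 switches) of a 360-exploratory-trial session;
after every 6 exploratory trials a probe set asks for two state predictions
and one condition prediction.  Transitions are probabilistic: the
rule-consistent destination occurs with the run's fidelity (0.9 / 0.8 /
0.9 / 0.8 across the four runs), each off-rule island with the remaining
mass split evenly.

States, actions and conditions are represented internally as integers
0..2 / 0..2 / {0 = uncontrollable, 1 = controllable}; label tuples below
give the canonical names used in exported files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ISLANDS = ("volcano", "palm", "lighthouse")
PLANES = ("pink", "green", "orange")
CONDITIONS = ("uncontrollable", "controllable")

UNCONTROLLABLE = 0
CONTROLLABLE = 1

N_STATES = 3
N_ACTIONS = 3

#: canonical color map: pink→palm, green→volcano, orange→lighthouse
DEFAULT_COLOR_MAP = (1, 0, 2)
#: canonical route cycle: volcano→lighthouse→palm→volcano
DEFAULT_ROUTE = (2, 0, 1)

#: canonical multiset of block lengths (each appears twice, shuffled per seed)
DEFAULT_BLOCK_MULTISET = (18, 24, 30, 30, 36, 42)

RUN_FIDELITIES = (0.9, 0.8, 0.9, 0.8)


@dataclass(frozen=True)
class TaskRules:
    """The two transition rules: color map (controllable) and route cycle."""

    color_map: tuple[int, int, int] = DEFAULT_COLOR_MAP
    route: tuple[int, int, int] = DEFAULT_ROUTE


def _as_index_tuple(mapping, keys, values) -> tuple[int, int, int]:
    """Convert a {label: label} dict or an int sequence to an index tuple."""
    if isinstance(mapping, dict):
        out = [None] * 3
        for k, v in mapping.items():
            out[keys.index(k)] = values.index(v)
        if any(o is None for o in out):
            raise ValueError("mapping must cover all three keys")
        return tuple(out)
    return tuple(int(x) for x in mapping)


def make_rules(color_map=None, route=None) -> TaskRules:
    """Build task rules, defaulting to the canonical instructed rules.

    ``color_map`` maps plane colors to islands (must be a bijection);
    ``route`` maps each island to the next island on the route (must be a
    single 3-cycle, hence fixed-point free).
    """
    cm = DEFAULT_COLOR_MAP if color_map is None else _as_index_tuple(color_map, PLANES, ISLANDS)
    rt = DEFAULT_ROUTE if route is None else _as_index_tuple(route, ISLANDS, ISLANDS)
    if sorted(cm) != [0, 1, 2]:
        raise ValueError("color_map must be a bijection from planes to islands")
    if sorted(rt) != [0, 1, 2]:
        raise ValueError("route must be a permutation of the islands")
    if any(rt[s] == s for s in range(N_STATES)):
        raise ValueError("route must be a 3-cycle with no fixed point")
    return TaskRules(color_map=cm, route=rt)


def offered_planes(state: int, rules: TaskRules) -> tuple[int, int]:
    """The two planes offered on a trial: the colors not mapping to ``state``.

    Returned in canonical color order; display order is randomized by the
    session runner.
    """
    return tuple(c for c in range(N_ACTIONS) if rules.color_map[c] != state)


def diagnostic_plane(state: int, rules: TaskRules) -> int:
    """The offered plane whose color destination differs from the route.

    Exactly one of the two offered planes satisfies this: choosing it leads
    to different islands under the two conditions, so only its outcome can
    discriminate the current condition.
    """
    cands = [c for c in offered_planes(state, rules) if rules.color_map[c] != rules.route[state]]
    assert len(cands) == 1
    return cands[0]


def nominal_destination(state: int, action: int, condition: int, rules: TaskRules) -> int:
    """Rule-consistent destination: color map if controllable, route if not."""
    if condition == CONTROLLABLE:
        return rules.color_map[action]
    return rules.route[state]


def sample_transition(state: int, action: int, condition: int, fidelity: float,
                      rules: TaskRules, rng: np.random.Generator) -> int:
    """Sample the realized destination at the given transition fidelity.

    The nominal destination occurs with probability ``fidelity``; each of
    the two off-rule islands with probability ``(1 - fidelity) / 2``.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    nominal = nominal_destination(state, action, condition, rules)
    u = rng.random()
    if u < fidelity:
        return nominal
    others = [s for s in range(N_STATES) if s != nominal]
    return others[0] if u < fidelity + (1.0 - fidelity) / 2.0 else others[1]


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration for :func:`build_schedule`."""

    block_multiset: tuple[int, ...] = DEFAULT_BLOCK_MULTISET
    probe_period: int = 6
    start_condition: Optional[int] = None  # None → random per seed
    start_state: Optional[int] = None      # None → random per seed
    run_lengths: tuple[int, int, int, int] = (90, 90, 90, 90)
    sample_run_lengths: bool = False
    run_fidelity: tuple[float, float, float, float] = RUN_FIDELITIES


@dataclass(frozen=True)
class SchedulePlan:
    """Block/run/probe layout of one session."""

    block_lengths: tuple[int, ...]
    block_conditions: tuple[int, ...]
    run_lengths: tuple[int, ...]
    run_fidelity: tuple[float, ...]
    probe_period: int
    start_state: int
    seed: Optional[int]
    phase: str = "main"            # "main" or "train"
    feedback_all: bool = False     # training: feedback on every prediction
    condition_visible: bool = False

    @property
    def n_explore(self) -> int:
        return sum(self.block_lengths)

    @property
    def n_probe_sets(self) -> int:
        return self.n_explore // self.probe_period

    def condition_of_trial(self, i: int) -> int:
        """Condition of exploratory trial ``i`` (0-indexed)."""
        acc = 0
        for length, cond in zip(self.block_lengths, self.block_conditions):
            acc += length
            if i < acc:
                return cond
        raise IndexError(i)

    def block_of_trial(self, i: int) -> int:
        acc = 0
        for b, length in enumerate(self.block_lengths):
            acc += length
            if i < acc:
                return b
        raise IndexError(i)

    def run_of_trial(self, i: int) -> int:
        acc = 0
        for r, length in enumerate(self.run_lengths):
            acc += length
            if i < acc:
                return r
        raise IndexError(i)

    def fidelity_of_trial(self, i: int) -> float:
        return self.run_fidelity[self.run_of_trial(i)]


def _sample_run_lengths(total: int, rng: np.random.Generator,
                        lo: int = 72, hi: int = 108, step: int = 6) -> tuple[int, ...]:
    """Sample 4 run lengths in [lo, hi], multiples of ``step``, summing to total."""
    lengths = []
    remaining = total
    for k in range(4, 1, -1):
        lo_i = max(lo, remaining - (k - 1) * hi)
        hi_i = min(hi, remaining - (k - 1) * lo)
        choices = np.arange(lo_i, hi_i + 1, step)
        pick = int(rng.choice(choices))
        lengths.append(pick)
        remaining -= pick
    lengths.append(remaining)
    return tuple(lengths)


def build_schedule(config: Optional[ScheduleConfig] = None, rng=None, seed: Optional[int] = None) -> SchedulePlan:
    """Build a seeded main-session schedule.

    The 12 block lengths are the configured multiset repeated twice and
    shuffled; conditions strictly alternate from a (possibly random) start
    condition, so switches always fall on probe-set boundaries because all
    block lengths are multiples of the probe period.
    """
    config = config or ScheduleConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    multiset = tuple(config.block_multiset)
    if any(b % config.probe_period != 0 for b in multiset):
        raise ValueError("block lengths must be multiples of the probe period")
    if any(not 18 <= b <= 42 for b in multiset):
        raise ValueError("block lengths must lie in [18, 42]")
    blocks = list(multiset) * 2
    if sum(blocks) != 360:
        raise ValueError("block multiset must sum to 180 (two repetitions -> 360)")
    perm = rng.permutation(len(blocks))
    blocks = tuple(blocks[i] for i in perm)
    start_cond = (int(rng.integers(2)) if config.start_condition is None
                  else int(config.start_condition))
    conditions = tuple((start_cond + b) % 2 for b in range(len(blocks)))
    if config.sample_run_lengths:
        run_lengths = _sample_run_lengths(360, rng)
    else:
        run_lengths = tuple(config.run_lengths)
    if sum(run_lengths) != 360 or any(not 72 <= r <= 108 for r in run_lengths):
        raise ValueError("run lengths must lie in [72, 108] and sum to 360")
    start_state = (int(rng.integers(N_STATES)) if config.start_state is None
                   else int(config.start_state))
    return SchedulePlan(
        block_lengths=blocks,
        block_conditions=conditions,
        run_lengths=run_lengths,
        run_fidelity=tuple(config.run_fidelity),
        probe_period=config.probe_period,
        start_state=start_state,
        seed=seed,
    )


def build_training_schedule(config: Optional[ScheduleConfig] = None,
                            rng=None, seed: Optional[int] = None) -> SchedulePlan:
    """Training phase: 48 deterministic exploratory trials, 8 probe sets.

    The condition is announced to the agent, feedback is given on every
    prediction, and the two conditions each occupy 24 trials.
    """
    config = config or ScheduleConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    start_cond = (int(rng.integers(2)) if config.start_condition is None
                  else int(config.start_condition))
    start_state = (int(rng.integers(N_STATES)) if config.start_state is None
                   else int(config.start_state))
    return SchedulePlan(
        block_lengths=(24, 24),
        block_conditions=(start_cond, 1 - start_cond),
        run_lengths=(48,),
        run_fidelity=(1.0,),
        probe_period=config.probe_period,
        start_state=start_state,
        seed=seed,
        phase="train",
        feedback_all=True,
        condition_visible=True,
    )


@dataclass
class TrialRecord:
    """One row of a session log (0-indexed in memory, 1-indexed on disk)."""

    index: int
    phase: str
    run: int                 # 0-indexed run
    block: int               # 0-indexed block
    condition: int
    trial_type: str          # explore | state_pred | condition_pred
    departure: int
    offered: tuple[int, int]         # display order
    queried_plane: Optional[int]     # state_pred only
    choice: int                      # plane / island / condition by trial type
    outcome: Optional[int]           # realized island when one was sampled
    feedback: Optional[bool]
    diagnostic_chosen: Optional[bool]


@dataclass
class SessionData:
    """An ordered trial log plus the schedule and rules that produced it."""

    records: list[TrialRecord]
    rules: TaskRules
    plan: Optional[SchedulePlan] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, trial_type: str) -> list[TrialRecord]:
        return [r for r in self.records if r.trial_type == trial_type]


def run_session(agent, plan: SchedulePlan, rules: TaskRules,
                rng: np.random.Generator) -> SessionData:
    """Run one agent through a scheduled session.

    The agent must expose ``choose_explore(state, offered)``,
    ``predict_state(state, plane)``, ``predict_condition()`` and
    ``observe(event)``.  Exploration resumes from the last exploratory
    outcome; probes query the current island's two offered planes in random
    order, and exactly one of the two state predictions per probe set is
    reinforced (all of them during training).  Reinforced predictions are
    judged against a freshly sampled environment outcome.
    """
    records: list[TrialRecord] = []
    state = plan.start_state
    idx = 0
    for i in range(plan.n_explore):
        cond = plan.condition_of_trial(i)
        fid = plan.fidelity_of_trial(i)
        run = plan.run_of_trial(i)
        block = plan.block_of_trial(i)
        offered = offered_planes(state, rules)
        if rng.random() < 0.5:
            offered = (offered[1], offered[0])
        choice = agent.choose_explore(state, offered)
        if choice not in offered:
            raise ValueError(f"agent chose unoffered plane {choice} from {offered}")
        outcome = sample_transition(state, choice, cond, fid, rules, rng)
        diag = choice == diagnostic_plane(state, rules)
        records.append(TrialRecord(idx, plan.phase, run, block, cond, "explore",
                                   state, offered, None, choice, outcome, None, diag))
        idx += 1
        event = {"kind": "explore", "s": state, "a": choice, "s_next": outcome}
        if plan.condition_visible:
            event["condition"] = cond
        agent.observe(event)
        state = outcome

        if (i + 1) % plan.probe_period == 0:
            planes = offered_planes(state, rules)
            if rng.random() < 0.5:
                planes = (planes[1], planes[0])
            reinforced = int(rng.integers(2))
            for j, plane in enumerate(planes):
                pred = agent.predict_state(state, plane)
                give_fb = plan.feedback_all or j == reinforced
                if give_fb:
                    sampled = sample_transition(state, plane, cond, fid, rules, rng)
                    correct = pred == sampled
                    records.append(TrialRecord(idx, plan.phase, run, block, cond,
                                               "state_pred", state, planes, plane,
                                               pred, sampled, True, None))
                    agent.observe({"kind": "prediction_feedback", "s": state,
                                   "a": plane, "s_next": sampled, "choice": pred,
                                   "correct": correct})
                else:
                    records.append(TrialRecord(idx, plan.phase, run, block, cond,
                                               "state_pred", state, planes, plane,
                                               pred, None, False, None))
                idx += 1
            cpred = agent.predict_condition()
            records.append(TrialRecord(idx, plan.phase, run, block, cond,
                                       "condition_pred", state, planes, None,
                                       cpred, None, plan.feedback_all, None))
            idx += 1
            if plan.condition_visible:
                agent.observe({"kind": "condition_feedback", "condition": cond})
    return SessionData(records=records, rules=rules, plan=plan,
                       meta={"seed": plan.seed, "phase": plan.phase})
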