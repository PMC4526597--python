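"""Generative hybrid model-based/model-free agents for the two-step task.

An agent mixes two valuation systems with a weight ``w``: a model-free
cache updated by temporal-difference learning from reward history, and a
model-based system that combines the (known) 70/30 transition structure
with learned second-stage values *and the current incentive value of each
coin*.  Setting w=0 yields a pure model-free agent, w=1 a pure model-based
one.  Because only the model-based branch consults incentive values,
devaluation can redirect behavior exactly to the extent that the agent is
model-based -- the mechanism the whole package exists to exercise.

Respond/withhold behavior in the Exp 1 test phase follows an explicit
generative rule: the engagement value is the best available hybrid action
value converted to currency, minus the 1-cent response cost, pushed
through a logistic with gain ``beta_resp`` and offset ``resp_bias``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import sigmoid
from .task import (TaskConfig, build_phase_schedule, make_reward_walks,
                   sample_transition, _as_rng)

#: initial value of all cached action/state values (midpoint of the
#: reward-probability range; neutral with 0/1 rewards)
Q_INIT = 0.5

TRIAL_COLUMNS = ["subject", "game", "trial", "phase", "action", "transition",
                 "second_state", "reward", "devalued_game"]


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of one simulated subject.

    alpha      learning rate, [0, 1]
    beta       softmax inverse temperature, >= 0
    w          model-based weight, [0, 1]
    pi         perseveration (stickiness) strength, unbounded
    beta_resp  respond/withhold gain on the dollar-valued engage signal
    resp_bias  respond/withhold offset
    lam        eligibility: weight of terminal reward in the first-stage
               model-free target (1 = pure terminal-reward credit)
    """

    alpha: float
    beta: float
    w: float
    pi: float = 0.0
    beta_resp: float = 50.0
    resp_bias: float = -1.7
    lam: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.beta_resp < 0.0:
            raise ValueError("beta_resp must be non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")

    def replace(self, **changes) -> "AgentParams":
        return dataclasses.replace(self, **changes)


@dataclass
class AgentState:
    """Mutable internal state of an agent while playing the task."""

    q_mf: np.ndarray         # (n_games, 2)
    v2: np.ndarray           # (n_states,)
    outcome_value: np.ndarray  # (n_states,) 1 valued, 0 devalued
    last_action: np.ndarray  # (n_games,) int, -1 before the first choice

    @classmethod
    def initial(cls, config: TaskConfig) -> "AgentState":
        return cls(
            q_mf=np.full((config.n_games, 2), Q_INIT),
            v2=np.full(config.n_states, Q_INIT),
            outcome_value=np.ones(config.n_states),
            last_action=np.full(config.n_games, -1, dtype=np.int64),
        )

    def copy(self) -> "AgentState":
        return AgentState(self.q_mf.copy(), self.v2.copy(),
                          self.outcome_value.copy(), self.last_action.copy())

    def devalue(self, config: TaskConfig) -> None:
        """Apply the devaluation event: zero the devalued coin's incentive.

        Nothing else in the agent changes -- the cached model-free values
        are untouched, which is what makes habits possible.
        """
        for s in config.devalued_states():
            self.outcome_value[config.state_index(s)] = 0.0


def mf_update(state: AgentState, game: int, action: int, second_state: int,
              reward, params: AgentParams) -> AgentState:
    """Delta-rule update of Q_mf and V2 after an observed outcome (in place).

    Q_mf(game, action) moves toward the eligibility-weighted target and
    V2(second_state) toward the reward.  Hidden feedback (reward None/NaN)
    is a no-op by contract: nothing may be learned from outcomes that were
    never shown.
    """
    if reward is None or (isinstance(reward, float) and math.isnan(reward)):
        return state
    if reward not in (0, 1):
        raise ValueError("observed reward must be 0 or 1")
    _kernel.value_update(state.q_mf, state.v2, game, action, second_state,
                         float(reward), params.alpha, params.lam)
    return state


def mb_values(state: AgentState, game: int, config: TaskConfig) -> tuple[float, float]:
    """Model-based values of (left, right), incentive-weighted."""
    return _kernel.mb_action_values(state.v2, state.outcome_value, game,
                                    config.p_common)


def choice_probability(state: AgentState, params: AgentParams, game: int,
                       config: TaskConfig) -> float:
    """P(choose left) under the hybrid softmax with perseveration."""
    x = _kernel.choice_logit(state.q_mf, state.v2, state.outcome_value,
                             state.last_action, game, params.w, params.beta,
                             params.pi, config.p_common)
    return sigmoid(x)

def choose(state: AgentState, params: AgentParams, game: int,
           config: TaskConfig, rng) -> int:
    """Sample a first-stage action (0 left, 1 right)."""
    rng = _as_rng(rng)
    return 0 if rng.random() < choice_probability(state, params, game, config) else 1


def engage_value(state: AgentState, params: AgentParams, game: int,
                 config: TaskConfig) -> float:
    """Net dollar value of responding at all in ``game``.

    E = max_a [w*Q_mb(a) + (1-w)*Q_mf(a)] * reward_value - response_cost.
    The model-based branch carries the incentive values, so devaluation
    zeroes it; the cached model-free branch is untouchable by devaluation.
    """
    q0_mb, q1_mb = mb_values(state, game, config)
    q0 = params.w * q0_mb + (1.0 - params.w) * state.q_mf[game, 0]
    q1 = params.w * q1_mb + (1.0 - params.w) * state.q_mf[game, 1]
    return max(q0, q1) * config.reward_value - config.response_cost


def respond_probability(state: AgentState, params: AgentParams, game: int,
                        config: TaskConfig) -> float:
    """P(respond) in the Exp 1 respond/withhold phases."""
    e = engage_value(state, params, game, config)
    return sigmoid(params.beta_resp * e + params.resp_bias)


def respond_decision(state: AgentState, params: AgentParams, game: int,
                     config: TaskConfig, rng) -> bool:
    rng = _as_rng(rng)
    return rng.random() < respond_probability(state, params, game, config)


def _expected_deval_sensitivity(state: AgentState, params: AgentParams,
                                config: TaskConfig) -> float:
    """Model-implied devaluation sensitivity at test time.

    Exp 1: (n_test/2) * [P(respond | valued) - P(respond | devalued)].
    Exp 2: probability of choosing the action whose common destination is
    the still-valued state.
    """
    if config.experiment == "exp1":
        dev = config.game_index(config.devalued_target)
        val = 1 - dev
        per_game = config.n_test // config.n_games
        return per_game * (respond_probability(state, params, val, config)
                           - respond_probability(state, params, dev, config))
    p_left = choice_probability(state, params, 0, config)
    dev_state = config.state_index(config.devalued_target)
    # action 0's common destination is state 0 (single_A)
    return p_left if dev_state == 1 else 1.0 - p_left


def simulate_subject(params: AgentParams, config: TaskConfig, seed,
                     subject_id: str = "s0",
                     test_params: AgentParams | None = None,
                     omission_rate: float = 0.0,
                     consumption_probs: tuple[float, float] = (0.55, 0.06),
                     ) -> pd.DataFrame:
    """Play one subject through the full session and return the trial log.

    Training choices use ``params``; the post-training phases (no-feedback,
    test) use ``test_params`` if given -- passing an independently drawn
    parameter set there produces "null" cohorts in which devaluation-test
    behavior is unrelated to the training-phase parameters.  ``omission_rate``
    injects random response lapses into Exp 1 training (humans miss trials;
    simulated agents default to none).  The consumption display is logged as
    two ``phase='consumption'`` rows whose ``reward`` field holds the number
    of coins (of 10) collected per type, with collection probabilities
    ``consumption_probs = (valued, devalued)``.

    The log's ``attrs`` carry the model-implied expected devaluation
    sensitivity (``expected_deval_sensitivity``) for ground-truth tables.
    """
    rng = _as_rng(seed)
    test_p = params if test_params is None else test_params
    walks = make_reward_walks(config, rng)
    schedule = build_phase_schedule(config, rng)
    state = AgentState.initial(config)
    devalued_games = ({config.devalued_target} if config.experiment == "exp1"
                      else set())
    dev_states = set(config.devalued_states())
    rows: list[tuple] = []
    devalued_applied = False
    expected = None

    for st in schedule:
        g = config.game_index(st.game)
        if st.phase == "test" and not devalued_applied:
            state.devalue(config)
            expected = _expected_deval_sensitivity(state, test_p, config)
            devalued_applied = True

        if st.phase == "training":
            if config.experiment == "exp1" and omission_rate > 0 \
                    and rng.random() < omission_rate:
                rows.append((subject_id, st.game, st.trial, st.phase, "none",
                             "none", "none", math.nan,
                             st.game in devalued_games))
                continue
            a = choose(state, params, g, config, rng)
            action = "left" if a == 0 else "right"
            second, label = sample_transition(action, st.game, config, rng)
            if st.stabilized:
                p_r = config.stabilized_prob(second)
            else:
                p_r = walks[second][st.game_trial]
            r = 1.0 if rng.random() < p_r else 0.0
            mf_update(state, g, a, config.state_index(second), r, params)
            state.last_action[g] = a
            dev_flag = (st.game in devalued_games
                        or (config.experiment == "exp2" and second in dev_states))
            rows.append((subject_id, st.game, st.trial, st.phase, action,
                         label, second, r, dev_flag))
            continue

        # no-feedback and test phases: first stage only, outcomes hidden
        if config.experiment == "exp1":
            respond = respond_decision(state, test_p, g, config, rng)
            if respond:
                a = choose(state, test_p, g, config, rng)
                action = "left" if a == 0 else "right"
                state.last_action[g] = a
            else:
                action = "none"
            dev_flag = st.game in devalued_games
        else:
            a = choose(state, test_p, g, config, rng)
            action = "left" if a == 0 else "right"
            state.last_action[g] = a
            dest = config.common_destination(st.game, action)
            dev_flag = dest in dev_states
        rows.append((subject_id, st.game, st.trial, st.phase, action, "none",
                     "none", math.nan, dev_flag))

    # consumption display: 10 coins of each type, collected independently
    q_v, q_d = consumption_probs
    n_valued = int(rng.binomial(10, q_v))
    n_devalued = int(rng.binomial(10, q_d))
    t = schedule[-1].trial + 1
    game0 = config.games[0]
    rows.append((subject_id, game0, t, "consumption", "none", "none", "none",
                 float(n_valued), False))
    rows.append((subject_id, game0, t + 1, "consumption", "none", "none",
                 "none", float(n_devalued), True))

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["expected_deval_sensitivity"] = expected
    df.attrs["params"] = params
    return df


@dataclass(frozen=True)
class CohortSpec:
    """Distributions of agent parameters across a simulated cohort.

    Defaults describe a heterogeneous cohort spanning the model-based /
    model-free continuum: w uniform on [0, 1] (the quantity under study),
    learning rates centered at .5, softmax temperatures around 5, mild
    perseveration, and a fixed respond/withhold rule whose gain/offset are
    set so that fully model-based agents withhold almost all devalued
    responding while model-free agents keep responding everywhere.

    ``link`` controls how test-phase behavior relates to the training
    parameters: "respond" (the declared generative rule, so devaluation
    sensitivity rises with w) or "null" (test behavior driven by an
    independently drawn w; no true association).
    """

    alpha: Callable[[np.random.Generator], float] = \
        field(default=lambda rng: float(rng.beta(5.0, 5.0)))
    beta: Callable[[np.random.Generator], float] = \
        field(default=lambda rng: float(rng.lognormal(math.log(5.0), 0.3)))
    w: Callable[[np.random.Generator], float] = \
        field(default=lambda rng: float(rng.uniform(0.0, 1.0)))
    pi: Callable[[np.random.Generator], float] = \
        field(default=lambda rng: float(rng.normal(0.2, 0.15)))
    beta_resp: float = 50.0
    resp_bias: float = -1.7
    lam: float = 1.0
    link: str = "respond"
    omission_rate: float = 0.0

    def sample(self, rng: np.random.Generator) -> AgentParams:
        return AgentParams(alpha=min(max(self.alpha(rng), 0.0), 1.0),
                           beta=max(self.beta(rng), 0.0),
                           w=min(max(self.w(rng), 0.0), 1.0),
                           pi=self.pi(rng),
                           beta_resp=self.beta_resp,
                           resp_bias=self.resp_bias,
                           lam=self.lam)


@dataclass
class Cohort:
    """Simulated cohort: concatenated trial logs plus the ground truth."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    config: TaskConfig


TRUTH_COLUMNS = ["subject", "alpha", "beta", "w", "pi", "beta_resp",
                 "resp_bias", "deval_sensitivity_true"]


def generate_cohort(n_subjects: int, spec: CohortSpec | None = None,
                    config: TaskConfig | None = None, seed=0) -> Cohort:
    """Simulate ``n_subjects`` independent agents through the task.

    The devalued coin is counterbalanced across subjects (alternating).
    Returns the pooled trial log and a ground-truth table including each
    subject's model-implied expected devaluation sensitivity.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec = spec or CohortSpec()
    config = config or TaskConfig.exp1()
    rng = _as_rng(seed)
    targets = (config.games if config.experiment == "exp1"
               else config.state_names)
    logs, truth_rows = [], []
    for i in range(n_subjects):
        sid = f"s{i:03d}"
        params = spec.sample(rng)
        test_params = params
        if spec.link == "null":
            test_params = params.replace(w=float(rng.uniform(0.0, 1.0)))
        cfg_i = config.replace(devalued_target=targets[i % 2])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        df = simulate_subject(params, cfg_i, sub_seed, subject_id=sid,
                              test_params=None if spec.link == "respond" else test_params,
                              omission_rate=spec.omission_rate)
        logs.append(df)
        truth_rows.append((sid, params.alpha, params.beta, params.w,
                           params.pi, params.beta_resp, params.resp_bias,
                           df.attrs["expected_deval_sensitivity"]))
    trials = pd.concat(logs, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Cohort(trials=trials, truth=truth, config=config)
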