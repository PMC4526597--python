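"""Agent tests: update rules, valuation, choice, respond rule, cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

import habitlearn as hl
from habitlearn.agents import (AgentState, choice_probability, engage_value,
                               mb_values, mf_update, respond_probability)


@pytest.fixture
def state(exp1_config) -> AgentState:
    return AgentState.initial(exp1_config)


class TestMFUpdate:
    def test_delta_rule_arithmetic(self, exp1_config, state):
        state.q_mf[:] = 0.0
        params = hl.AgentParams(alpha=0.5, beta=1.0, w=0.0)
        mf_update(state, 0, 0, 0, reward=1, params=params)
        assert state.q_mf[0, 0] == pytest.approx(0.5)
        assert state.q_mf[0, 1] == 0.0 and np.all(state.q_mf[1] == 0.0)

    def test_zero_learning_rate_is_inert(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.0, beta=1.0, w=0.5)
        before = state.copy()
        for r in (0, 1):
            mf_update(state, 1, 1, 3, reward=r, params=params)
        assert np.array_equal(state.q_mf, before.q_mf)
        assert np.array_equal(state.v2, before.v2)

    def test_hidden_feedback_is_noop(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.7, beta=1.0, w=0.5)
        before = state.copy()
        mf_update(state, 0, 0, 0, reward=None, params=params)
        mf_update(state, 0, 0, 0, reward=math.nan, params=params)
        assert np.array_equal(state.q_mf, before.q_mf)
        assert np.array_equal(state.v2, before.v2)

    def test_v2_tracks_reward_probability(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.1, beta=1.0, w=0.0)
        rng = np.random.default_rng(0)
        vals = []
        for t in range(10000):
            r = int(rng.random() < 0.65)
            mf_update(state, 0, 0, 0, reward=r, params=params)
            if t > 1000:
                vals.append(state.v2[0])
        assert np.mean(vals) == pytest.approx(0.65, abs=0.02)


class TestMBValues:
    def test_direct_expectation(self, exp1_config, state):
        state.v2[0], state.v2[1] = 0.6, 0.2
        q = mb_values(state, 0, exp1_config)
        assert q[0] == pytest.approx(0.7 * 0.6 + 0.3 * 0.2)  # 0.48
        assert q[1] == pytest.approx(0.7 * 0.2 + 0.3 * 0.6)  # 0.32

    def test_devaluation_reverses_preference(self, exp1_config, state):
        state.v2[0], state.v2[1] = 0.6, 0.2
        state.outcome_value[0] = 0.0   # devalue the richer state's coin
        q = mb_values(state, 0, exp1_config)
        assert q[0] == pytest.approx(0.3 * 0.2)  # 0.06
        assert q[1] == pytest.approx(0.7 * 0.2)  # 0.14
        assert q[1] > q[0]

    def test_symmetric_transition_gives_equal_values(self, state):
        cfg = hl.TaskConfig.exp1(p_common=0.5)
        state.v2[0], state.v2[1] = 0.9, 0.1
        q = mb_values(state, 0, cfg)
        assert q[0] == pytest.approx(q[1])


class TestChoose:
    def test_flat_softmax(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.5, beta=0.0, w=0.5, pi=0.0)
        assert choice_probability(state, params, 0, exp1_config) == 0.5

    def test_perseveration_dominance(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.5, beta=2.0, w=0.5, pi=50.0)
        state.last_action[0] = 1
        assert choice_probability(state, params, 0, exp1_config) < 1e-6

    def test_softmax_closed_form(self, exp1_config, state):
        # w=1, beta=10, Q_mb=(0.48, 0.32): P(left)=1/(1+exp(-1.6))
        state.v2[0], state.v2[1] = 0.6, 0.2
        params = hl.AgentParams(alpha=0.5, beta=10.0, w=1.0, pi=0.0)
        p = choice_probability(state, params, 0, exp1_config)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-10 * 0.16)),
                                  abs=1e-12)
        assert p == pytest.approx(0.832, abs=5e-4)


class TestRespondRule:
    def test_model_based_agent_withholds_when_devalued(self, exp1_config,
                                                       state):
        params = hl.AgentParams(alpha=0.5, beta=5.0, w=1.0,
                                beta_resp=500.0, resp_bias=0.0)
        state.devalue(exp1_config)
        dev = exp1_config.game_index("gold")
        assert respond_probability(state, params, dev, exp1_config) < 0.01
        # engage value reduces to the response cost alone
        assert engage_value(state, params, dev, exp1_config) == \
            pytest.approx(-exp1_config.response_cost)

    def test_model_free_agent_blind_to_devaluation(self, exp1_config, state):
        params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.0)
        state.q_mf[:] = [[0.7, 0.2], [0.4, 0.6]]
        before = [respond_probability(state, params, g, exp1_config)
                  for g in range(2)]
        state.devalue(exp1_config)
        after = [respond_probability(state, params, g, exp1_config)
                 for g in range(2)]
        assert before == after

    def test_devalue_touches_only_outcome_value(self, exp1_config, state):
        before = state.copy()
        state.devalue(exp1_config)
        assert np.array_equal(state.q_mf, before.q_mf)
        assert np.array_equal(state.v2, before.v2)
        assert np.array_equal(state.last_action, before.last_action)
        assert state.outcome_value[0] == 0.0 and state.outcome_value[2] == 1.0


class TestSimulateSubject:
    def test_seeded_determinism(self, exp1_config):
        params = hl.AgentParams(alpha=0.4, beta=4.0, w=0.6, pi=0.1)
        a = hl.simulate_subject(params, exp1_config, seed=5)
        b = hl.simulate_subject(params, exp1_config, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_log_structure(self, hybrid_subject, exp1_config):
        df = hybrid_subject
        counts = df["phase"].value_counts()
        assert counts["training"] == 200 and counts["test"] == 20
        assert counts["nofeedback"] == 4 and counts["consumption"] == 2
        hidden = df[df["phase"].isin(["nofeedback", "test"])]
        assert hidden["reward"].isna().all()
        assert (hidden["transition"] == "none").all()
        train = df[df["phase"] == "training"]
        assert set(train["reward"].unique()) <= {0.0, 1.0}
        # common transition iff the majority destination was reached
        for _, row in train.head(50).iterrows():
            dest = exp1_config.common_destination(row["game"], row["action"])
            assert (row["transition"] == "common") == \
                (row["second_state"] == dest)

    def test_exp2_test_has_no_withholding(self, exp2_config):
        params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5)
        df = hl.simulate_subject(params, exp2_config, seed=2)
        test = df[df["phase"] == "test"]
        assert len(test) == 10
        assert (test["action"] != "none").all()

    def test_omission_rate_injects_lapses(self, exp1_config):
        params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5)
        df = hl.simulate_subject(params, exp1_config, seed=3,
                                 omission_rate=0.3)
        train = df[df["phase"] == "training"]
        assert 30 < (train["action"] == "none").sum() < 90

    def test_deval_sensitivity_monotone_in_w(self, exp1_config):
        # model-implied sensitivity averaged over seeds, on a w grid
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for w in grid:
            params = hl.AgentParams(alpha=0.5, beta=5.0, w=w, pi=0.2)
            vals = [hl.simulate_subject(params, exp1_config, seed=s)
                    .attrs["expected_deval_sensitivity"] for s in range(12)]
            means.append(np.mean(vals))
        assert all(b >= a - 0.5 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 3.0


class TestCohort:
    def test_ground_truth_table(self, small_cohort):
        truth = small_cohort.truth
        assert len(truth) == 20
        assert truth["alpha"].between(0, 1).all()
        assert truth["w"].between(0, 1).all()
        assert (truth["beta"] >= 0).all()
        assert truth["subject"].is_unique

    def test_devalued_coin_counterbalanced(self, small_cohort):
        trials = small_cohort.trials
        dev_games = (trials[trials["devalued_game"]
                            & (trials["phase"] == "test")]
                     .groupby("subject")["game"].first())
        assert set(dev_games.unique()) == {"gold", "silver"}

    def test_too_small_cohort_rejected(self, exp1_config):
        with pytest.raises(ValueError):
            hl.generate_cohort(1, config=exp1_config, seed=0)

    def test_null_link_breaks_w_deval_coupling(self, exp1_config):
        from scipy.stats import spearmanr
        spec = hl.CohortSpec(link="null")
        cohort = hl.generate_cohort(60, spec=spec, config=exp1_config,
                                    seed=5)
        rho = spearmanr(cohort.truth["w"],
                        cohort.truth["deval_sensitivity_true"])[0]
        assert abs(rho) < 0.3
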