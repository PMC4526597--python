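"""Likelihood, MLE and hierarchical-fit tests.

The three-trial likelihood oracle below is written out by hand,
independently of the package's kernel, so the two can disagree.
"""

import math

import numpy as np
import pandas as pd
import pytest

import habitlearn as hl
from habitlearn import _kernel
from habitlearn.fitting import prepare_trials


@pytest.fixture(scope="module")
def prepared(exp1_config):
    params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5, pi=0.2)
    df = hl.simulate_subject(params, exp1_config, seed=1)
    return prepare_trials(df, exp1_config)


class TestHybridNLL:
    def test_flat_policy_equals_t_ln2(self, prepared, exp1_config):
        nll = hl.hybrid_nll((0.5, 0.0, 0.5, 0.0), prepared, exp1_config)
        assert nll == pytest.approx(200 * math.log(2), abs=1e-9)

    def test_single_trial_symmetric_values(self, exp1_config):
        arrs = (np.array([0]), np.array([0]), np.array([0]),
                np.array([1.0]))
        nll = hl.hybrid_nll((0.3, 4.0, 1.0, 0.0), arrs, exp1_config)
        assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_three_trial_hand_oracle(self, exp1_config):
        """Exhaustive hand computation of a 3-trial sequence.

        Single game; actions L, L, R; second states A, B, B; rewards
        1, 0, 1; alpha=.5, beta=2, w=.6, pi=.3, p=.7; values start at .5.
        """
        alpha, beta, w, pi, p = 0.5, 2.0, 0.6, 0.3, 0.7

        def softmax_left(q_l, q_r, bonus_l):
            x = beta * (q_l - q_r) + bonus_l
            return 1.0 / (1.0 + math.exp(-x))

        qmf = {"L": 0.5, "R": 0.5}
        v2 = {"A": 0.5, "B": 0.5}
        nll = 0.0
        # trial 1: L chosen, lands A (common), r=1; values all equal
        qmb_l = p * v2["A"] + (1 - p) * v2["B"]
        qmb_r = p * v2["B"] + (1 - p) * v2["A"]
        p_l = softmax_left(w * qmb_l + (1 - w) * qmf["L"],
                           w * qmb_r + (1 - w) * qmf["R"], 0.0)
        nll -= math.log(p_l)
        qmf["L"] += alpha * (1.0 - qmf["L"])
        v2["A"] += alpha * (1.0 - v2["A"])
        # trial 2: L chosen (stay bonus +pi), lands B (rare), r=0
        qmb_l = p * v2["A"] + (1 - p) * v2["B"]
        qmb_r = p * v2["B"] + (1 - p) * v2["A"]
        p_l = softmax_left(w * qmb_l + (1 - w) * qmf["L"],
                           w * qmb_r + (1 - w) * qmf["R"], pi)
        nll -= math.log(p_l)
        qmf["L"] += alpha * (0.0 - qmf["L"])
        v2["B"] += alpha * (0.0 - v2["B"])
        # trial 3: R chosen (stay bonus on L), lands B, r=1
        qmb_l = p * v2["A"] + (1 - p) * v2["B"]
        qmb_r = p * v2["B"] + (1 - p) * v2["A"]
        p_l = softmax_left(w * qmb_l + (1 - w) * qmf["L"],
                           w * qmb_r + (1 - w) * qmf["R"], pi)
        nll -= math.log(1.0 - p_l)

        arrs = (np.zeros(3, dtype=np.int64),
                np.array([0, 0, 1], dtype=np.int64),
                np.array([0, 1, 1], dtype=np.int64),
                np.array([1.0, 0.0, 1.0]))
        got = hl.hybrid_nll(
            hl.AgentParams(alpha=alpha, beta=beta, w=w, pi=pi),
            arrs, exp1_config)
        assert got == pytest.approx(nll, abs=1e-10)

    def test_hidden_feedback_contributes_choice_only(self, exp1_config):
        # same choices, hidden rewards: NLL differs from observed case and
        # equals the no-update prediction
        arrs_hidden = (np.zeros(2, dtype=np.int64),
                       np.array([0, 0], dtype=np.int64),
                       np.zeros(2, dtype=np.int64),
                       np.array([-1.0, -1.0]))
        nll = hl.hybrid_nll((0.9, 3.0, 0.0, 0.0), arrs_hidden, exp1_config)
        # without updates both trials are 50/50
        assert nll == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_out_of_bounds_params_rejected(self, prepared, exp1_config):
        with pytest.raises(ValueError):
            hl.hybrid_nll((1.5, 5.0, 0.5, 0.0), prepared, exp1_config)
        with pytest.raises(ValueError):
            hl.hybrid_nll((0.5, -1.0, 0.5, 0.0), prepared, exp1_config)

    def test_empty_data_rejected(self, exp1_config):
        empty = (np.empty(0, dtype=np.int64),) * 3 + (np.empty(0),)
        with pytest.raises(ValueError):
            hl.hybrid_nll((0.5, 5.0, 0.5, 0.0), empty, exp1_config)

    def test_game_relabelling_invariance(self, exp1_config):
        """Swapping the two games' labels leaves the likelihood unchanged."""
        params = hl.AgentParams(alpha=0.4, beta=4.0, w=0.7, pi=0.1)
        df = hl.simulate_subject(params, exp1_config, seed=6)
        swapped = df.copy()
        swapped["game"] = df["game"].map({"gold": "silver",
                                          "silver": "gold"})
        swapped["second_state"] = df["second_state"].map(
            lambda s: s.replace("gold", "TMP").replace("silver", "gold")
            .replace("TMP", "silver"))
        a = hl.hybrid_nll(params, df, exp1_config)
        b = hl.hybrid_nll(params, swapped, exp1_config)
        assert a == pytest.approx(b, abs=1e-9)

    def test_kernel_python_fallback_matches_numba(self, prepared,
                                                  exp1_config):
        if not _kernel.HAVE_NUMBA:
            pytest.skip("numba not installed; only one path exists")
        args = prepared + (2, 4, 0.5, 5.0, 0.5, 0.2, 1.0, 0.7, 0.5)
        jitted = float(_kernel.nll_core(*args))
        plain = float(_kernel.nll_core.py_func(*args))
        assert jitted == pytest.approx(plain, abs=1e-12)

    def test_entropy_rate_consistency(self, exp1_config):
        """Mean per-trial NLL at the generating parameters approaches the
        policy's entropy rate."""
        params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5, pi=0.2)
        cfg = exp1_config.replace(n_training=4000)
        ent, nll_total, n = 0.0, 0.0, 0
        for seed in range(3):
            df = hl.simulate_subject(params, cfg, seed=seed)
            arrs = prepare_trials(df, cfg)
            nll_total += hl.hybrid_nll(params, arrs, cfg)
            n += len(arrs[0])
            # entropy rate by replaying the same kernel's probabilities
            from habitlearn.agents import AgentState, choice_probability
            state = AgentState.initial(cfg)
            train = df[df["phase"] == "training"]
            for _, row in train.iterrows():
                g = cfg.game_index(row["game"])
                p = choice_probability(state, params, g, cfg)
                ent -= p * math.log(p) + (1 - p) * math.log(1 - p)
                a = 0 if row["action"] == "left" else 1
                from habitlearn.agents import mf_update
                mf_update(state, g, a, cfg.state_index(row["second_state"]),
                          row["reward"], params)
                state.last_action[g] = a
        assert nll_total / n == pytest.approx(ent / n, rel=0.05)


class TestMLE:
    def test_truth_never_beaten_by_more_than_tol(self, prepared,
                                                 exp1_config):
        truth = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5, pi=0.2)
        fit = hl.fit_mle(prepared, exp1_config, n_restarts=5, seed=2)
        assert fit.nll <= hl.hybrid_nll(truth, prepared, exp1_config) + 1e-6

    def test_deterministic_given_seed(self, prepared, exp1_config):
        a = hl.fit_mle(prepared, exp1_config, n_restarts=4, seed=3)
        b = hl.fit_mle(prepared, exp1_config, n_restarts=4, seed=3)
        assert a.params == b.params and a.nll == b.nll

    def test_recovers_w_on_long_series(self, exp1_config):
        cfg = exp1_config.replace(n_training=1000)
        truth = hl.AgentParams(alpha=0.5, beta=5.0, w=0.8, pi=0.2)
        df = hl.simulate_subject(truth, cfg, seed=8)
        fit = hl.fit_mle(df, cfg, n_restarts=8, seed=8)
        assert fit.params.w == pytest.approx(0.8, abs=0.15)


class TestHierarchical:
    def test_too_few_subjects_rejected(self, exp1_config, small_cohort):
        few = small_cohort.trials[
            small_cohort.trials["subject"].isin([f"s{i:03d}"
                                                 for i in range(5)])]
        dz = pd.Series(np.linspace(-1, 1, 5),
                       index=[f"s{i:03d}" for i in range(5)])
        with pytest.raises(ValueError):
            hl.fit_hierarchical(few, dz, exp1_config)

    def test_smoke_and_diagnostics(self, exp1_config):
        cohort = hl.generate_cohort(12, config=exp1_config, seed=44)
        summ = hl.subject_summaries(cohort.trials, exp1_config)
        dz = pd.Series(hl.zscore(summ["deval_sensitivity"].to_numpy()),
                       index=summ["subject"])
        fit = hl.fit_hierarchical(cohort.trials, dz, exp1_config,
                                  profile="reduced", seed=1)
        assert set(fit.subjects.columns) >= {"alpha", "beta", "w", "pi"}
        assert fit.subjects["w"].between(0, 1).all()
        assert "rhat_b" in fit.diagnostics
        assert fit.b_ci[0] <= fit.b_median <= fit.b_ci[1]

    def test_degenerate_beta_leaves_w_uninformed(self, exp1_config):
        """With beta=0 the likelihood is flat in w: the posterior for w
        should stay wide rather than spuriously precise."""
        spec = hl.CohortSpec(beta=lambda rng: 0.0)
        cohort = hl.generate_cohort(12, spec=spec, config=exp1_config,
                                    seed=3)
        summ = hl.subject_summaries(cohort.trials, exp1_config)
        deval = summ["deval_sensitivity"].to_numpy(dtype=float)
        deval += np.linspace(0, 1e-3, len(deval))
        dz = pd.Series(hl.zscore(deval), index=summ["subject"])
        fit = hl.fit_hierarchical(cohort.trials, dz, exp1_config,
                                  profile="reduced", seed=2)
        w_draws = 1 / (1 + np.exp(-fit.draws.flat("theta")[:, :, 2]))
        assert w_draws.std(axis=0).mean() > 0.15


class TestRecovery:
    def test_report_structure(self):
        rep = hl.recover_parameters(8, 150, seed=5, n_restarts=3)
        assert len(rep.table) == 8
        assert set(rep.spearman) == {"alpha", "beta", "w", "pi"}
        assert all(np.isfinite(v) for v in rep.rmse.values())
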