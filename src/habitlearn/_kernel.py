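"""Shared hybrid-agent choice/update kernel.

The trial-by-trial equations live here, in one place, and are used both by
the generative simulator (:mod:`habitlearn.agents`) and by the choice
likelihood (:mod:`habitlearn.fitting`), so the two can never drift apart.

State layout (plain NumPy arrays, so the functions can be numba-compiled):

* ``qmf``  -- (n_games, 2) cached model-free first-stage action values
* ``v2``   -- (n_states,) learned second-stage state values; state ``2g`` is
  the common destination of action 0 (left) in game ``g``, state ``2g + 1``
  of action 1 (right)
* ``ov``   -- (n_states,) current incentive value of the coin produced by
  each second-stage state (1 valued, 0 devalued)
* ``last`` -- (n_games,) previous first-stage action per game, -1 if none

If numba is unavailable the same functions run as plain Python; a test
asserts the two paths agree bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def mb_action_values(v2, ov, g, p_common):
    """Prospective (model-based) values of the two first-stage actions.

    Q_mb(a) = p_common * ov(dest_a) * V2(dest_a)
            + (1 - p_common) * ov(alt_a) * V2(alt_a)

    Multiplying by the incentive value ``ov`` is what makes the model-based
    branch devaluation-sensitive.
    """
    s0 = 2 * g
    s1 = 2 * g + 1
    q0 = p_common * ov[s0] * v2[s0] + (1.0 - p_common) * ov[s1] * v2[s1]
    q1 = p_common * ov[s1] * v2[s1] + (1.0 - p_common) * ov[s0] * v2[s0]
    return q0, q1


@njit(cache=False)
def choice_logit(qmf, v2, ov, last, g, w, beta, pi, p_common):
    """Log-odds of choosing action 0 over action 1 in game ``g``.

    Net value is the w-weighted hybrid  Q = w*Q_mb + (1-w)*Q_mf; a
    perseveration bonus ``pi`` is added to the previously chosen action.
    """
    q0_mb, q1_mb = mb_action_values(v2, ov, g, p_common)
    q0 = w * q0_mb + (1.0 - w) * qmf[g, 0]
    q1 = w * q1_mb + (1.0 - w) * qmf[g, 1]
    x = beta * (q0 - q1)
    if last[g] == 0:
        x += pi
    elif last[g] == 1:
        x -= pi
    return x


@njit(cache=False)
def value_update(qmf, v2, g, action, state, reward, alpha, lam):
    """Delta-rule update after an observed (unhidden) outcome.

    The first-stage cache is driven by the terminal reward with eligibility
    ``lam`` (lam=1: pure terminal-reward credit; lam<1 blends the current
    second-stage value into the target).  V2 is updated toward the reward.
    """
    target = lam * reward + (1.0 - lam) * v2[state]
    qmf[g, action] += alpha * (target - qmf[g, action])
    v2[state] += alpha * (reward - v2[state])


@njit(cache=False)
def nll_core(games, actions, states, rewards, n_games, n_states,
             alpha, beta, w, pi, lam, p_common, q_init):
    """Negative log likelihood of a first-stage choice sequence.

    ``rewards[t] < 0`` marks hidden feedback: the trial contributes choice
    likelihood but triggers no value update.  Incentive values are all 1
    (pre-devaluation), matching the training phase the fit consumes.
    """
    qmf = np.full((n_games, 2), q_init)
    v2 = np.full(n_states, q_init)
    ov = np.ones(n_states)
    last = np.full(n_games, -1, dtype=np.int64)
    nll = 0.0
    for t in range(games.shape[0]):
        g = games[t]
        a = actions[t]
        x = choice_logit(qmf, v2, ov, last, g, w, beta, pi, p_common)
        # log P(a) with a numerically safe log-sigmoid
        z = x if a == 0 else -x
        if z > 0.0:
            nll += math.log1p(math.exp(-z))
        else:
            nll += -z + math.log1p(math.exp(z))
        r = rewards[t]
        if r >= 0.0:
            value_update(qmf, v2, g, a, states[t], r, alpha, lam)
        last[g] = a
    return nll


def sigmoid(x: float) -> float:
    """Numerically stable logistic function."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)
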