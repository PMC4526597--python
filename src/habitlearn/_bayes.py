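"""Adaptive Metropolis-within-Gibbs sampler for hierarchical models.

One generic model serves both hierarchical analyses in the package
(the Bayesian mixed-effects stay regression and the hierarchical RL fit):

    theta_i ~ Normal(A + (B * mask) * x_i,  Sigma),   i = 1..n subjects
    y_i | theta_i  via an arbitrary per-subject log likelihood
    A_k, B_k ~ Normal(0, tau^2)          (weakly informative, tau = 1.5)
    Sigma ~ Inverse-Wishart(K + 2, 0.5 I)

``x`` is the standardized between-subject covariate (devaluation
sensitivity); ``mask`` restricts which coordinates' group means may depend
on it.  Subject vectors are updated by adaptive random-walk Metropolis
(proposal shaped by the current Sigma, scale tuned toward ~30% acceptance
during warmup); (A, B) and Sigma have conjugate Gibbs updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

TAU = 1.5            # prior SD of the group-level means/slopes
ACCEPT_TARGET = 0.30


@dataclass
class HierDraws:
    """Posterior draws, stacked as (chain, draw, ...)."""

    theta: np.ndarray    # (C, D, n, K)
    A: np.ndarray        # (C, D, K)
    B: np.ndarray        # (C, D, K)  (unmasked coordinates identically 0)
    Sigma: np.ndarray    # (C, D, K, K)
    accept_rate: np.ndarray  # (n,) mean across chains, post-warmup
    mask: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def rhat_ess(self, name: str, index) -> tuple[float, float]:
        """Split-R-hat and bulk ESS for one scalar component."""
        import arviz as az

        arr = getattr(self, name)
        comp = arr[(slice(None), slice(None)) + tuple(np.atleast_1d(index))]
        data = az.convert_to_dataset({"x": comp})
        return (float(az.rhat(data)["x"].values),
                float(az.ess(data)["x"].values))


def sign_probability_p(draws: np.ndarray) -> float:
    """Doubled posterior probability of the minority sign.

    A Bayesian analogue of a two-sided p-value; floored at 2/(n draws).
    """
    n = len(draws)
    p_pos = (draws > 0).mean()
    return float(max(2 * min(p_pos, 1 - p_pos), 2.0 / n))


def _gibbs_group_mean(theta, x, mask, sigma_inv, rng):
    """Conjugate draw of (A, B_masked) given subject vectors and Sigma."""
    n, K = theta.shape
    m = int(mask.sum())
    P = K + m
    # design: mean_i = A + x_i * B_masked  ->  U_i = [I_K, x_i * E]
    E = np.zeros((K, m))
    E[np.where(mask)[0], np.arange(m)] = 1.0
    Lam = np.zeros((P, P))
    rhs = np.zeros(P)
    SE = sigma_inv @ E
    ESE = E.T @ SE
    sx, sx2 = float(x.sum()), float(x @ x)
    Lam[:K, :K] = n * sigma_inv
    Lam[:K, K:] = sx * SE
    Lam[K:, :K] = sx * SE.T
    Lam[K:, K:] = sx2 * ESE
    rhs[:K] = sigma_inv @ theta.sum(axis=0)
    rhs[K:] = SE.T @ (theta.T @ x)
    Lam[np.diag_indices(P)] += 1.0 / TAU**2
    chol = np.linalg.cholesky(Lam)
    mean = np.linalg.solve(Lam, rhs)
    z = rng.standard_normal(P)
    gamma = mean + np.linalg.solve(chol.T, z)
    A = gamma[:K]
    B = np.zeros(K)
    B[mask] = gamma[K:]
    return A, B


def sample_hierarchical(loglik: Sequence[Callable[[np.ndarray], float]],
                        x: np.ndarray,
                        mask: np.ndarray,
                        init_theta: np.ndarray,
                        n_warmup: int,
                        n_keep: int,
                        n_chains: int,
                        seed: int,
                        n_sweeps: int = 10) -> HierDraws:
    """Run the Gibbs/Metropolis sampler and return stacked draws.

    ``n_sweeps`` Metropolis passes over the subject vectors are made per
    Gibbs iteration; multiple sweeps decorrelate the group-level draws
    (which condition on the subject vectors) at modest cost.
    """
    n, K = init_theta.shape
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(x, dtype=float)
    nu0 = K + 2
    S0 = 0.5 * np.eye(K)

    chains_theta = np.empty((n_chains, n_keep, n, K))
    chains_A = np.empty((n_chains, n_keep, K))
    chains_B = np.empty((n_chains, n_keep, K))
    chains_Sigma = np.empty((n_chains, n_keep, K, K))
    acc_all = np.zeros(n)

    for c in range(n_chains):
        rng = np.random.default_rng((seed + 7919 * c) % 2**31)
        theta = init_theta + 0.05 * rng.standard_normal((n, K))
        ll = np.array([loglik[i](theta[i]) for i in range(n)])
        A = theta.mean(axis=0)
        B = np.zeros(K)
        resid = theta - A
        Sigma = np.cov(theta.T) + 0.1 * np.eye(K) if n > K else np.eye(K)
        log_s = np.full(n, np.log(0.4))
        acc_count = np.zeros(n)
        acc_window = np.zeros(n)

        for it in range(n_warmup + n_keep):
            Sigma_inv = np.linalg.inv(Sigma)
            chol_S = np.linalg.cholesky(Sigma)
            means = A + np.outer(x, B)
            # --- subject-level Metropolis updates -----------------------
            for _ in range(n_sweeps):
                z = rng.standard_normal((n, K))
                u = np.log(rng.random(n))
                for i in range(n):
                    prop = theta[i] + np.exp(log_s[i]) * (chol_S @ z[i])
                    r_old = theta[i] - means[i]
                    r_new = prop - means[i]
                    lp_old = ll[i] - 0.5 * r_old @ Sigma_inv @ r_old
                    lp_new = loglik[i](prop) - 0.5 * r_new @ Sigma_inv @ r_new
                    if lp_new - lp_old > u[i]:
                        theta[i] = prop
                        ll[i] = lp_new + 0.5 * r_new @ Sigma_inv @ r_new
                        acc_window[i] += 1
                        if it >= n_warmup:
                            acc_count[i] += 1
            if it < n_warmup and (it + 1) % 20 == 0:
                rate = acc_window / (20.0 * n_sweeps)
                kappa = min(0.5, 5.0 / np.sqrt(it + 1.0))
                log_s += kappa * (rate - ACCEPT_TARGET)
                acc_window[:] = 0.0
            # --- conjugate group updates --------------------------------
            A, B = _gibbs_group_mean(theta, x, mask, Sigma_inv, rng)
            resid = theta - (A + np.outer(x, B))
            S = S0 + resid.T @ resid
            Sigma = stats.invwishart.rvs(df=nu0 + n, scale=S,
                                         random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            if it >= n_warmup:
                d = it - n_warmup
                chains_theta[c, d] = theta
                chains_A[c, d] = A
                chains_B[c, d] = B
                chains_Sigma[c, d] = Sigma
        acc_all += acc_count / (n_keep * n_sweeps)
    return HierDraws(theta=chains_theta, A=chains_A, B=chains_B,
                     Sigma=chains_Sigma, accept_rate=acc_all / n_chains,
                     mask=mask)
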