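"""Trial-lagged stay-probability analyses.

The central design codes, for every training choice, whether the subject
repeated their previous choice *in the same game* (stay = 1) as a function
of that previous trial's reward (+1/-1) and transition type (common +1 /
rare -1).  A reward main effect is the model-free signature; the
reward x transition interaction is the model-based signature.  Adding
standardized devaluation sensitivity as a between-subject moderator tests
the package's headline structure: a positive three-way
reward x transition x devaluation term means model-based learners are the
devaluation-sensitive (non-habitual) ones.

Two engines fit the mixed-effects logistic model
``stay ~ reward * transition * deval + (1 + reward * transition | subject)``:
a fast two-stage approximation (per-subject ML with a Firth fallback, then
OLS of the per-subject coefficients on the devaluation score) and a
hierarchical Bayesian reference engine (full-covariance Gaussian random
effects, MCMC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._bayes import HierDraws, sample_hierarchical, sign_probability_p
from .metrics import zscore

WITHIN_TERMS = ("Intercept", "Reward", "Transition", "Reward:Transition")
DEVAL_TERMS = ("Devaluation", "Reward:Devaluation", "Transition:Devaluation",
               "Reward:Transition:Devaluation")
#: canonical fixed-effect order of the stay model
FIXED_TERMS = ("Intercept", "Reward", "Transition", "Reward:Transition",
               "Devaluation", "Reward:Devaluation", "Transition:Devaluation",
               "Reward:Transition:Devaluation")


def build_lagged_design(trials: pd.DataFrame) -> pd.DataFrame:
    """Lag training-phase choices within subject and game.

    Predictors come from the previous trial experienced *in the same game*
    (not the previous trial overall); the first responded trial of each
    game per subject is dropped, and non-response trials are excluded both
    as targets and as lag sources.  Codings: stay 1 / switch 0; previous
    reward +1 / -1; previous transition common +1 / rare -1.
    """
    t = trials[(trials["phase"] == "training") & (trials["action"] != "none")]
    if len(t) == 0:
        return pd.DataFrame(columns=["subject", "game", "stay", "prev_reward",
                                     "prev_transition"])
    t = t.sort_values(["subject", "game", "trial"], kind="stable")
    g = t.groupby(["subject", "game"], sort=False)
    prev_action = g["action"].shift(1)
    prev_reward = g["reward"].shift(1)
    prev_transition = g["transition"].shift(1)
    ok = prev_action.notna()
    out = pd.DataFrame({
        "subject": t.loc[ok, "subject"],
        "game": t.loc[ok, "game"],
        "stay": (t.loc[ok, "action"] == prev_action[ok]).astype(int),
        "prev_reward": np.where(prev_reward[ok] == 1, 1, -1),
        "prev_transition": np.where(prev_transition[ok] == "common", 1, -1),
    })
    return out.reset_index(drop=True)


def _design_matrix(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    r = sub["prev_reward"].to_numpy(dtype=float)
    tr = sub["prev_transition"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(r), r, tr, r * tr])
    y = sub["stay"].to_numpy(dtype=float)
    return X, y


def firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-prior (Firth) penalized logistic regression.

    Keeps per-subject coefficients finite under complete separation, which
    all-stay or all-switch subjects otherwise produce.  Returns
    (coefficients, standard errors from the penalized information).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # damp oversized Newton steps
        m = np.abs(step).max()
        if m > 5.0:
            step *= 5.0 / m
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def _fit_subject(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    """Per-subject logistic stay ~ reward * transition, Firth fallback."""
    X, y = _design_matrix(sub)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = res.params, res.bse
        if (res.mle_retvals.get("converged", False)
                and np.all(np.isfinite(se)) and np.abs(beta).max() < 8.0
                and se.max() < 20.0):
            return beta, se, "ml"
    except Exception:
        pass
    beta, se = firth_logit(X, y)
    return beta, se, "firth"


def per_subject_fits(design: pd.DataFrame) -> pd.DataFrame:
    """Independent per-subject logistic fits (deterministic).

    Subjects contributing fewer than two distinct predictor rows still get
    a (heavily penalized) Firth fit; subjects absent from the design are
    simply absent from the table.
    """
    rows = []
    for sid, sub in design.groupby("subject", sort=True):
        beta, se, method = _fit_subject(sub)
        rows.append({"subject": sid,
                     "intercept": beta[0], "reward": beta[1],
                     "transition": beta[2], "reward_x_transition": beta[3],
                     "se_intercept": se[0], "se_reward": se[1],
                     "se_transition": se[2], "se_reward_x_transition": se[3],
                     "method": method, "n_trials": len(sub)})
    return pd.DataFrame(rows)


@dataclass
class StayModelResult:
    """Fixed-effect table plus per-subject effects for one stay-model fit."""

    table: pd.DataFrame          # term, estimate, se, stat, p
    engine: str
    subject_betas: pd.DataFrame  # per-subject within-subject coefficients
    n_subjects: int
    n_obs: int
    diagnostics: dict = field(default_factory=dict)
    draws: HierDraws | None = None

    def coef(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if len(row) != 1:
            raise KeyError(term)
        return row.iloc[0]


def _align_deval(design: pd.DataFrame, deval_z: pd.Series) -> pd.Series:
    subjects = sorted(design["subject"].unique())
    missing = [s for s in subjects if s not in deval_z.index]
    if missing:
        raise ValueError(f"deval_z missing subjects: {missing[:5]}")
    z = deval_z.loc[subjects].astype(float)
    if abs(z.mean()) > 1e-8 or abs(z.std(ddof=1) - 1) > 1e-6:
        z = pd.Series(zscore(z.to_numpy()), index=z.index)
    return z


def fit_mixed_stay_model(design: pd.DataFrame, deval_z: pd.Series | None,
                         engine: str = "twostage", seed: int = 0,
                         n_warmup: int = 300, n_keep: int = 300,
                         n_chains: int = 2) -> StayModelResult:
    """Fit the devaluation-moderated (or basic) stay model.

    ``deval_z`` is a Series of devaluation sensitivities indexed by subject
    id (standardized internally if not already); pass ``None`` to fit the
    *basic* learning model without the between-subject moderator -- the
    model whose subject-level effects define the learning indices.  The
    two-stage engine is deterministic; the hierarchical engine is seeded
    MCMC and additionally reports split-R-hat diagnostics for every fixed
    term.
    """
    if design["subject"].nunique() < 2:
        raise ValueError("the mixed model needs at least 2 subjects")
    if deval_z is None:
        subjects = sorted(design["subject"].unique())
        z = pd.Series(np.zeros(len(subjects)), index=subjects)
        moderated = False
    else:
        z = _align_deval(design, deval_z)
        moderated = True
    if engine == "twostage":
        return _fit_twostage(design, z, moderated)
    if engine == "hier":
        return _fit_hier(design, z, seed, n_warmup, n_keep, n_chains,
                         moderated)
    raise ValueError(f"unknown engine {engine!r}")


def _dl_tau2(y: np.ndarray, se: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian-Laird between-subject variance for a meta-regression."""
    wts = 1.0 / se**2
    Xw = X * wts[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    resid = y - X @ coef
    q = float(wts @ resid**2)
    p = X.shape[1]
    trace = wts.sum() - np.trace(np.linalg.solve(X.T @ Xw, (Xw.T @ Xw)))
    if trace <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - p)) / trace)


def _fit_twostage(design: pd.DataFrame, z: pd.Series,
                  moderated: bool = True) -> StayModelResult:
    """Per-subject ML (Firth fallback) + weighted group-level regression.

    The group stage is a random-effects meta-regression: each subject's
    coefficient is weighted by 1/(se_i^2 + tau^2), with tau^2 estimated by
    the DerSimonian-Laird moment estimator per term.
    """
    betas = per_subject_fits(design)
    betas = betas.set_index("subject").loc[z.index].reset_index()
    cols = ["intercept", "reward", "transition", "reward_x_transition"]
    rows = []
    Xg = sm.add_constant(z.to_numpy()) if moderated \
        else np.ones((len(z), 1))
    for k, col in enumerate(cols):
        y = betas[col].to_numpy()
        se_i = np.clip(betas[f"se_{col}"].to_numpy(), 1e-3, None)
        tau2 = _dl_tau2(y, se_i, Xg)
        res = sm.WLS(y, Xg, weights=1.0 / (se_i**2 + tau2)).fit()
        rows.append({"term": WITHIN_TERMS[k], "estimate": res.params[0],
                     "se": res.bse[0], "stat": res.tvalues[0],
                     "p": res.pvalues[0]})
        if moderated:
            rows.append({"term": DEVAL_TERMS[k], "estimate": res.params[1],
                         "se": res.bse[1], "stat": res.tvalues[1],
                         "p": res.pvalues[1]})
    order = FIXED_TERMS if moderated else WITHIN_TERMS
    table = (pd.DataFrame(rows)
             .set_index("term").loc[list(order)].reset_index())
    return StayModelResult(table=table, engine="twostage",
                           subject_betas=betas,
                           n_subjects=len(betas), n_obs=len(design))


def _fit_hier(design: pd.DataFrame, z: pd.Series, seed: int,
              n_warmup: int, n_keep: int, n_chains: int,
              moderated: bool = True) -> StayModelResult:
    subjects = list(z.index)
    data = {sid: _design_matrix(sub)
            for sid, sub in design.groupby("subject", sort=True)}

    def make_ll(X, y):
        def ll(theta):
            eta = np.clip(X @ theta, -30, 30)
            return float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll

    lls = [make_ll(*data[s]) for s in subjects]
    init = per_subject_fits(design).set_index("subject").loc[subjects]
    init_theta = np.clip(init[["intercept", "reward", "transition",
                               "reward_x_transition"]].to_numpy(), -3, 3)
    mask = np.full(4, moderated)
    draws = sample_hierarchical(lls, z.to_numpy(), mask, init_theta,
                                n_warmup, n_keep, n_chains, seed)
    rows, diag = [], {}
    for k in range(4):
        sources = [(WITHIN_TERMS[k], draws.flat("A")[:, k])]
        if moderated:
            sources.append((DEVAL_TERMS[k], draws.flat("B")[:, k]))
        for name, arr in sources:
            rows.append({"term": name, "estimate": float(np.mean(arr)),
                         "se": float(np.std(arr, ddof=1)),
                         "stat": float(np.mean(arr) / np.std(arr, ddof=1)),
                         "p": sign_probability_p(arr)})
    for k, term in enumerate(WITHIN_TERMS):
        diag[f"rhat_{term}"] = draws.rhat_ess("A", k)[0]
    if moderated:
        for k, term in enumerate(DEVAL_TERMS):
            diag[f"rhat_{term}"] = draws.rhat_ess("B", k)[0]
    order = FIXED_TERMS if moderated else WITHIN_TERMS
    table = (pd.DataFrame(rows)
             .set_index("term").loc[list(order)].reset_index())
    theta_mean = draws.flat("theta").mean(axis=0)
    subject_betas = pd.DataFrame(theta_mean, columns=["intercept", "reward",
                                 "transition", "reward_x_transition"])
    subject_betas.insert(0, "subject", subjects)
    max_rhat = max(diag.values())
    return StayModelResult(table=table, engine="hier",
                           subject_betas=subject_betas,
                           n_subjects=len(subjects), n_obs=len(design),
                           diagnostics={**diag, "max_rhat": max_rhat,
                                        "converged": max_rhat < 1.1},
                           draws=draws)


def per_subject_indices(design: pd.DataFrame, method: str = "independent",
                        hier_result: StayModelResult | None = None,
                        ) -> pd.DataFrame:
    """Model-free and model-based indices per subject.

    The model-free index is each subject's reward coefficient and the
    model-based index their reward x transition coefficient, from either
    independent per-subject fits (``method='independent'``) or the
    hierarchical model's shrunken subject-level effects
    (``method='hierarchical'``, requires a fitted hier ``StayModelResult``).
    """
    if method == "independent":
        betas = per_subject_fits(design)
    elif method == "hierarchical":
        if hier_result is None or hier_result.engine != "hier":
            raise ValueError("hierarchical indices need a fitted hier model")
        betas = hier_result.subject_betas
    else:
        raise ValueError(f"unknown method {method!r}")
    out = betas[["subject", "intercept", "reward", "transition",
                 "reward_x_transition"]].copy()
    out = out.rename(columns={"reward": "mf_index",
                              "reward_x_transition": "mb_index"})
    out["method"] = method
    return out


def predict_devaluation(indices: pd.DataFrame, deval: pd.Series,
                        covariates: pd.DataFrame | None = None,
                        ) -> pd.DataFrame:
    """Linear model of devaluation sensitivity on the learning indices.

    Indices (and any covariates) are standardized before entry; each
    covariate also enters in interaction with the model-based index,
    mirroring the published covariate-adjusted models.  Returns a
    (term, estimate, se, stat, p) table with fit info in ``attrs``.
    """
    idx = indices.set_index("subject")
    subjects = [s for s in idx.index if s in deval.index]
    if len(subjects) < len(idx):
        missing = sorted(set(idx.index) - set(subjects))
        raise ValueError(f"deval missing subjects: {missing[:5]}")
    y = deval.loc[subjects].to_numpy(dtype=float)
    cols = {"Model-free index": zscore(idx.loc[subjects, "mf_index"]),
            "Model-based index": zscore(idx.loc[subjects, "mb_index"])}
    if covariates is not None:
        cv = covariates.set_index("subject") if "subject" in covariates \
            else covariates
        for name in cv.columns:
            v = zscore(cv.loc[subjects, name].to_numpy(dtype=float))
            cols[name] = v
            cols[f"{name} x Model-based index"] = v * cols["Model-based index"]
    X = np.column_stack([np.ones(len(y))] + list(cols.values()))
    names = ["Intercept"] + list(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame({"term": names, "estimate": res.params,
                          "se": res.bse, "stat": res.tvalues,
                          "p": res.pvalues})
    table.attrs["r2"] = float(res.rsquared)
    table.attrs["n"] = len(y)
    return table
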