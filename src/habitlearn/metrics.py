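"""Subject-level summaries, devaluation/consumption scores and QC filters.

Devaluation sensitivity is the behavioral anchor of every between-subject
analysis: in Exp 1 it is the number of test-phase responses toward the
still-valued coin minus responses toward the devalued coin (-10..10, with
10 = perfectly goal-directed, 0 = habitual); in Exp 2 it is the proportion
of forced test choices directed at the still-valued state.  Consumption
sensitivity (valued minus devalued coins collected, each of 10 available)
verifies that the devaluation manipulation itself worked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task import TaskConfig

EXCLUSION_MISSED = 0.10     # more than 10% missed trials
EXCLUSION_SAME_KEY = 0.90   # same key on more than 90% of responses
EXCLUSION_RT_SD = 2.0       # per-subject mean RT beyond +/-2 SD of cohort


def devaluation_sensitivity(test_trials: pd.DataFrame,
                            experiment: str) -> float:
    """Devaluation sensitivity from one subject's test-phase trials.

    Exp 1: count(respond, valued game) - count(respond, devalued game).
    Exp 2: fraction of test choices whose common destination is the
    still-valued state (the log's ``devalued_game`` flag marks choices of
    the devalued-associated action).
    """
    t = test_trials[test_trials["phase"] == "test"]
    if len(t) == 0:
        raise ValueError("no test-phase trials found")
    if experiment == "exp1":
        responded = t[t["action"] != "none"]
        n_valued = int((~responded["devalued_game"]).sum())
        n_devalued = int(responded["devalued_game"].sum())
        return float(n_valued - n_devalued)
    if experiment == "exp2":
        if (t["action"] == "none").any():
            raise ValueError("exp2 test trials are forced choices")
        return float((~t["devalued_game"]).mean())
    raise ValueError(f"unknown experiment {experiment!r}")


def consumption_sensitivity(consumption: pd.DataFrame | tuple[int, int]) -> float:
    """Valued minus devalued coins collected (each 0..10).

    Accepts either the two ``phase='consumption'`` log rows (the ``reward``
    field holds the count, ``devalued_game`` the coin type) or a plain
    ``(n_valued, n_devalued)`` pair.
    """
    if isinstance(consumption, pd.DataFrame):
        c = consumption[consumption["phase"] == "consumption"]
        if len(c) != 2:
            raise ValueError("expected exactly two consumption rows")
        n_valued = float(c.loc[~c["devalued_game"], "reward"].iloc[0])
        n_devalued = float(c.loc[c["devalued_game"], "reward"].iloc[0])
    else:
        n_valued, n_devalued = map(float, consumption)
    for n in (n_valued, n_devalued):
        if not 0 <= n <= 10:
            raise ValueError("collected counts must lie in 0..10")
    return float(n_valued - n_devalued)


def subject_summaries(trials: pd.DataFrame, config: TaskConfig) -> pd.DataFrame:
    """One summary row per subject (scores plus QC quantities)."""
    rows = []
    for sid, sub in trials.groupby("subject", sort=True):
        train = sub[sub["phase"] == "training"]
        n_missed = int((train["action"] == "none").sum())
        responded = train[train["action"] != "none"]
        if len(responded):
            same_key = responded["action"].value_counts().iloc[0] / len(responded)
        else:
            same_key = 1.0
        has_cons = (sub["phase"] == "consumption").any()
        rows.append({
            "subject": sid,
            "deval_sensitivity": devaluation_sensitivity(sub, config.experiment),
            "consumption_sensitivity":
                consumption_sensitivity(sub) if has_cons else np.nan,
            "n_missed": n_missed,
            "missed_fraction": n_missed / len(train) if len(train) else 1.0,
            "same_key_fraction": float(same_key),
        })
    return pd.DataFrame(rows)


def apply_exclusions(trials: pd.DataFrame, config: TaskConfig,
                     rt_summary: pd.DataFrame | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove subjects violating the a priori data-quality rules.

    Rules (all strict inequalities): missed more than 10% of training
    trials; same key on more than 90% of responded training trials; mean
    reaction time beyond +/-2 SD of the cohort mean (only if ``rt_summary``
    with columns subject, mean_rt is supplied -- simulated cohorts have no
    RTs).  Returns (retained trial log, exclusion report).  The filters are
    idempotent: a second pass removes nobody.
    """
    summ = subject_summaries(trials, config)
    reasons: dict[str, list[str]] = {s: [] for s in summ["subject"]}
    for _, row in summ.iterrows():
        if row["missed_fraction"] > EXCLUSION_MISSED:
            reasons[row["subject"]].append("missed")
        if row["same_key_fraction"] > EXCLUSION_SAME_KEY:
            reasons[row["subject"]].append("same_key")
    rt_flags: dict[str, bool] = {}
    if rt_summary is not None and len(rt_summary) >= 2:
        m = rt_summary["mean_rt"].mean()
        sd = rt_summary["mean_rt"].std(ddof=1)
        for _, r in rt_summary.iterrows():
            if sd > 0 and abs(r["mean_rt"] - m) > EXCLUSION_RT_SD * sd:
                reasons.setdefault(r["subject"], []).append("rt")
                rt_flags[r["subject"]] = True
    report = pd.DataFrame({
        "subject": summ["subject"],
        "excluded": [bool(reasons[s]) for s in summ["subject"]],
        "reason": [",".join(reasons[s]) for s in summ["subject"]],
        "rt_flag": [rt_flags.get(s, False) for s in summ["subject"]],
    })
    keep = set(report.loc[~report["excluded"], "subject"])
    if not keep:
        raise ValueError("all subjects excluded")
    retained = trials[trials["subject"].isin(keep)].reset_index(drop=True)
    return retained, report


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("z-scoring needs a 1-d vector with n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector (zero variance)")
    return (x - x.mean()) / sd


def paired_value_comparison(valued, devalued) -> dict:
    """Paired comparison of valued vs devalued consumption counts.

    Used as an in-silico manipulation check that devaluation shifted
    incentive value.  Returns the paired mean difference, t statistic,
    degrees of freedom and p-value.
    """
    v = np.asarray(valued, dtype=float)
    d = np.asarray(devalued, dtype=float)
    if v.shape != d.shape or v.ndim != 1:
        raise ValueError("valued/devalued must be equal-length vectors")
    if len(v) < 3:
        raise ValueError("paired comparison needs at least 3 subjects")
    diff = v - d
    if np.allclose(diff, diff[0]):
        # identical columns (or constant shift): t-test degenerates
        stat, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
    else:
        stat, p = stats.ttest_rel(v, d)
    return {"mean_diff": float(diff.mean()), "stat": float(stat),
            "df": len(v) - 1, "p": float(p)}


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and p-value."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
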