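"""End-to-end orchestration: simulate, filter, analyze, fit, manifest.

``run_pipeline`` chains the stages -- cohort simulation, exclusion
filters, behavioral metrics, the lagged stay regression with the
devaluation moderator, per-subject learning indices, the index linear
model and (optionally) an RL fit -- writing each product as CSV/JSON into
an artifact directory together with a run manifest.  A single global seed
expands deterministically into per-stage child seeds, so any stage can be
re-run in isolation; deterministic stages reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .agents import Cohort, CohortSpec, generate_cohort
from .fitting import fit_hierarchical, fit_mle, prepare_trials
from .io import write_config, write_trials
from .metrics import apply_exclusions, subject_summaries, zscore
from .stay import (build_lagged_design, fit_mixed_stay_model,
                   per_subject_indices, predict_devaluation)
from .task import TaskConfig


def child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed: (seed * 1009 + 9973 * stage) mod 2^31."""
    return (int(seed) * 1009 + 9973 * int(stage)) % (2**31 - 1)


def config_hash(config: TaskConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: TaskConfig, out_dir, seed: int = 0,
                 n_subjects: int = 90, cohort_spec: CohortSpec | None = None,
                 engine: str = "twostage", rl_fit: str | None = None,
                 profile: str = "reduced") -> dict:
    """Run the full simulate-analyze(-fit) pipeline into ``out_dir``.

    ``rl_fit`` may be None, "mle" or "hier".  Returns a dict with the
    in-memory results and the manifest.  Any stage failure aborts with the
    stage name; partial outputs written so far are preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort_spec or CohortSpec()
    manifest = {"config_hash": config_hash(config), "seed": int(seed),
                "package_version": __version__, "engine": engine,
                "rl_fit": rl_fit, "profile": profile,
                "n_subjects": int(n_subjects), "stages": {}, "files": []}
    results: dict = {"manifest": manifest}
    stage_idx = 0
    current = "setup"

    def record(name: str, t0: float, *files: str):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                    "seed": child_seed(seed, stage_idx)}
        manifest["files"].extend(files)

    try:
        current = "simulate"
        t0 = time.time()
        cohort = generate_cohort(n_subjects, spec=spec, config=config,
                                 seed=child_seed(seed, stage_idx))
        write_trials(cohort.trials, out / "trials.csv")
        cohort.truth.to_csv(out / "truth.csv", index=False)
        write_config(config, out / "config.json")
        record(current, t0, "trials.csv", "truth.csv", "config.json")
        results["cohort"] = cohort

        current = "exclusions"
        stage_idx += 1
        t0 = time.time()
        retained, report = apply_exclusions(cohort.trials, config)
        report.to_json(out / "exclusions.json", orient="records", indent=2)
        record(current, t0, "exclusions.json")
        results["exclusions"] = report

        current = "metrics"
        stage_idx += 1
        t0 = time.time()
        subjects = subject_summaries(retained, config)
        subjects.to_csv(out / "subjects.csv", index=False)
        record(current, t0, "subjects.csv")
        results["subjects"] = subjects

        current = "stay_regression"
        stage_idx += 1
        t0 = time.time()
        design = build_lagged_design(retained)
        deval = subjects.set_index("subject")["deval_sensitivity"]
        deval_z = pd.Series(zscore(deval.to_numpy()), index=deval.index)
        stay_fit = fit_mixed_stay_model(design, deval_z, engine=engine,
                                        seed=child_seed(seed, stage_idx))
        stay_fit.table.to_csv(out / "regression.csv", index=False)
        record(current, t0, "regression.csv")
        results["stay_fit"] = stay_fit

        current = "indices"
        stage_idx += 1
        t0 = time.time()
        indices = per_subject_indices(design)
        indices.to_csv(out / "indices.csv", index=False)
        linear = predict_devaluation(indices, deval)
        linear.to_csv(out / "linear_model.csv", index=False)
        record(current, t0, "indices.csv", "linear_model.csv")
        results["indices"] = indices
        results["linear_model"] = linear

        if rl_fit is not None:
            current = f"rl_fit_{rl_fit}"
            stage_idx += 1
            t0 = time.time()
            if rl_fit == "mle":
                rows = []
                for i, (sid, sub) in enumerate(
                        retained.groupby("subject", sort=True)):
                    f = fit_mle(prepare_trials(sub, config), config,
                                n_restarts=5,
                                seed=child_seed(seed, stage_idx) + i)
                    rows.append({"subject": sid, "alpha": f.params.alpha,
                                 "beta": f.params.beta, "w": f.params.w,
                                 "pi": f.params.pi, "nll": f.nll})
                fit_df = pd.DataFrame(rows)
                fit_df.to_csv(out / "fit_subjects.csv", index=False)
                payload = {"engine": "mle",
                           "mean_w": float(fit_df["w"].mean())}
                results["rl_fit"] = fit_df
            elif rl_fit == "hier":
                hier = fit_hierarchical(retained, deval_z, config,
                                        profile=profile,
                                        seed=child_seed(seed, stage_idx))
                hier.subjects.to_csv(out / "fit_subjects.csv", index=False)
                payload = {"engine": "hier", "b_median": hier.b_median,
                           "b_ci": list(hier.b_ci), "b_p": hier.b_p,
                           "diagnostics": hier.diagnostics,
                           "warning": hier.warning,
                           "group": hier.group.to_dict(orient="records")}
                results["rl_fit"] = hier
            else:
                raise ValueError(f"unknown rl_fit {rl_fit!r}")
            (out / "fit.json").write_text(json.dumps(payload, indent=2))
            record(current, t0, "fit_subjects.csv", "fit.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{current}': {exc}") \
            from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
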