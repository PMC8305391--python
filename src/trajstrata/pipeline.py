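"""End-to-end analysis pipeline.

Orchestrates the full trajectory-stratification workflow under one
master seed: obtain a cohort (simulated or read from disk), screen
covariates, scan the class number by BIC, run split-half stability
tests, produce unbiased cross-design class labels, summarize class
characteristics (membership coefficients with Wald tests), and evaluate
discharge-based prediction for the 2-, 3- and 4-class tasks. Every
artifact records the master seed and a configuration hash; a
machine-readable JSON summary and a short text report are written to
the output directory.

Stage seeds are derived from the master seed with fixed offsets so that
stages are reproducible independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cohort import Cohort, encode_covariates, read_cohort, screen_covariates, write_cohort
from .mixture import TrajectoryMixture, _prepare_arrays, bic_scan
from .prediction import CVPlan, build_features, evaluate, nested_cv_predict
from .simulate import GeneratorConfig, generate_cohort
from .validation import cross_design_labels, stability_test

log = logging.getLogger("trajstrata")

STAGE_SEED_OFFSETS = {
    "simulate": 0, "split": 101, "fit": 202, "stability": 303, "cv": 404,
}


@dataclass
class PipelineConfig:
    """Master configuration; all stage seeds derive from ``seed``."""

    mode: str = "simulate"                 # "simulate" | "read"
    cohort_path: str | None = None         # for mode="read"
    generator: GeneratorConfig | None = None
    class_range: tuple[int, ...] = (2, 3, 4, 5)
    prediction_tasks: tuple[int, ...] = (2, 3, 4)
    outcomes: tuple[str, ...] = ("total",)
    k_folds: int = 5
    n_starts: int = 10
    seed: int = 42
    out_dir: str = "trajstrata_report"
    run_stability: bool = True

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ClassCharacteristics:
    """Per-class sizes, covariate summaries, and membership coefficients
    vs the floor-level reference class with Wald standard errors."""

    sizes: pd.Series
    covariate_means: pd.DataFrame
    gamma_table: pd.DataFrame  # class, covariate, coef, se, z, p


def class_characteristics(fitted: TrajectoryMixture, cohort: Cohort,
                          labels: np.ndarray | None = None) -> ClassCharacteristics:
    """Summarize fitted classes: assigned sizes, per-class raw covariate
    means, and membership log-odds vs class 1 with Wald tests from the
    observed information of the membership submodel (descriptive,
    uncorrected for multiplicity)."""
    if labels is None:
        labels = fitted.labels_
    labels = np.asarray(labels)
    K = fitted.n_classes
    enc = encode_covariates(cohort.covariates)
    enc.index = cohort.covariates["subject_id"]
    sizes = pd.Series({k: int((labels == k).sum()) for k in range(1, K + 1)},
                      name="n")
    if sizes.sum() != cohort.n_subjects:
        raise ValueError("labels inconsistent with cohort size")
    means = enc.groupby(labels).mean()
    means.index.name = "class"

    # observed information of the posterior-weighted multinomial logit
    arr, _, _ = _prepare_arrays(cohort, fitted.feature_names_, fitted.degree,
                                fitted.outcome, fitted.center_, fitted.scale_)
    X = arr.X
    W = fitted.posterior_ if len(fitted.posterior_) == len(X) else None
    if W is None:
        W = np.eye(K)[labels - 1]
    gamma = fitted.gamma_
    eta = X @ gamma.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    p1 = X.shape[1]
    H = np.zeros(((K - 1) * p1, (K - 1) * p1))
    for a in range(1, K):
        for b in range(1, K):
            w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
            H[(a - 1) * p1:a * p1, (b - 1) * p1:b * p1] = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(K - 1, p1)

    names = ["intercept"] + list(fitted.feature_names_)
    rows = []
    for k in range(1, K):
        for j, name in enumerate(names):
            coef = gamma[k, j]
            s = se[k - 1, j]
            z = coef / s if s > 0 else np.nan
            rows.append({"class": k + 1, "covariate": name, "coef": coef,
                         "se": s, "z": z,
                         "p": float(2 * sstats.norm.sf(abs(z))) if np.isfinite(z) else np.nan})
    return ClassCharacteristics(sizes=sizes, covariate_means=means,
                                gamma_table=pd.DataFrame(rows))


@dataclass
class ReportBundle:
    """All pipeline artifacts plus provenance (seed, config hash)."""

    config: PipelineConfig
    config_hash: str
    bic_table: pd.DataFrame
    stability: list
    labels: dict[int, pd.DataFrame]
    characteristics: ClassCharacteristics
    eval_reports: dict[str, object]
    summary: dict


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; deterministic given ``config.seed``. Artifacts
    are written under ``config.out_dir``."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def stage(name):
        log.info("stage=%s seed=%s t=%.1fs", name, config.seed, time.time() - t_start)

    stage("cohort")
    if config.mode == "simulate":
        gen = config.generator or GeneratorConfig()
        cohort, truth = generate_cohort(gen, seed=config.stage_seed("simulate"))
        write_cohort(cohort, out / "cohort")
        truth.labels.to_csv(out / "cohort" / "truth.csv", index=False)
    elif config.mode == "read":
        if not config.cohort_path:
            raise ValueError("mode='read' requires cohort_path")
        cohort = read_cohort(config.cohort_path)
        truth = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    stage("screen")
    selected, screen_report = screen_covariates(cohort.covariates)
    screen_report.to_csv(out / "screening.csv", index=False)

    fit_kwargs = dict(membership_covariates=selected, n_starts=config.n_starts)

    stage("bic_scan")
    bic_table, models = bic_scan(cohort, class_range=config.class_range,
                                 seed=config.stage_seed("fit"),
                                 return_models=True, **fit_kwargs)
    bic_table.to_csv(out / "bic_scan.csv", index=False)
    k_best = int(bic_table.loc[bic_table["bic"].idxmin(), "K"])

    stability_rows = []
    if config.run_stability:
        stage("stability")
        for K in config.class_range:
            res = stability_test(cohort, K, seed=config.stage_seed("stability"),
                                 **fit_kwargs)
            stability_rows.append(res)
        pd.DataFrame([asdict(r) for r in stability_rows]).to_csv(
            out / "stability.csv", index=False)

    stage("cross_design")
    labels_by_task: dict[int, pd.DataFrame] = {}
    for K in config.prediction_tasks:
        cdl = cross_design_labels(cohort, K, seed=config.stage_seed("split"),
                                  **fit_kwargs)
        tab = cdl.table.copy()
        tab["config_hash"] = chash
        tab.to_csv(out / f"labels_K{K}.csv", index=False)
        labels_by_task[K] = cdl.table

    stage("characteristics")
    chars = class_characteristics(models[k_best], cohort)
    chars.gamma_table.to_csv(out / "class_coefficients.csv", index=False)
    chars.covariate_means.to_csv(out / "class_covariate_means.csv")

    stage("prediction")
    eval_reports: dict[str, object] = {}
    for outcome in config.outcomes:
        feats = build_features(cohort, outcome=outcome)
        for K, lab_table in labels_by_task.items():
            labels = lab_table.set_index("subject_id")["label"].reindex(feats.index)
            plan = CVPlan(k=config.k_folds, seed=config.stage_seed("cv"))
            preds = nested_cv_predict(feats, labels, plan)
            report = evaluate(preds, K=K, with_curves=True)
            key = f"{outcome}_K{K}"
            eval_reports[key] = report
            preds["config_hash"] = chash
            preds.to_csv(out / f"predictions_{key}.csv", index=False)
            for c, curve in report.roc_curves.items():
                curve.to_csv(out / f"roc_{key}_class{c}.csv", index=False)

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "selected_covariates": selected,
        "bic": {str(int(r.K)): {"loglik": r.loglik, "bic": r.bic,
                                "min_class_mean_max_posterior":
                                    r.min_class_mean_max_posterior}
                for r in bic_table.itertuples()},
        "k_best_by_bic": k_best,
        "stability": [{k: _jsonable(v) for k, v in asdict(r).items()}
                      for r in stability_rows],
        "class_sizes": {str(k): int(v) for k, v in chars.sizes.items()},
        "evaluation": {key: rep.to_dict() for key, rep in eval_reports.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    lines = [f"trajstrata pipeline report (seed={config.seed}, hash={chash})",
             f"subjects: {cohort.n_subjects}",
             f"BIC-selected K: {k_best}",
             "BIC scan:"]
    for r in bic_table.itertuples():
        lines.append(f"  K={int(r.K)}: loglik={r.loglik:.1f} BIC={r.bic:.1f} "
                     f"min class post={r.min_class_mean_max_posterior:.3f}")
    for key, rep in eval_reports.items():
        lines.append(f"prediction {key}: accuracy={rep.accuracy:.3f} "
                     f"precision={rep.precision_macro:.3f} kappa={rep.kappa:.3f}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    stage("done")
    return ReportBundle(config=config, config_hash=chash, bic_table=bic_table,
                        stability=stability_rows, labels=labels_by_task,
                        characteristics=chars, eval_reports=eval_reports,
                        summary=summary)
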