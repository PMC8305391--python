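"""Clustering-stability validation and cross-design class assignment.

Two procedures assess and exploit split-half structure:

* **Stability**: the cohort is randomized into two halves; a constrained
  model (one parameter set shared by both halves, i.e. the ordinary
  pooled fit) is compared with an unconstrained one (separate parameter
  sets per half, log-likelihoods summed) through a likelihood-ratio test
  with df equal to the parameter-count difference. A non-significant
  test indicates the class structure is stable across halves.

* **Cross design**: the model is fitted on half A and used to assign
  classes to half B, and vice versa, so every subject's label comes from
  a model that never saw that subject — an unbiased membership estimate
  subsequently used as ground truth for discharge-based prediction.

Class labels from independently fitted halves are harmonized by the
canonical ordering (ascending model-implied mean trajectory), shared with
:mod:`trajstrata.mixture`. Optimal posterior-overlap (Hungarian)
matching is available as a robustness alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .cohort import Cohort
from .mixture import TrajectoryMixture, _e_step, _prepare_arrays


@dataclass
class StabilityResult:
    """Likelihood-ratio comparison of pooled vs per-half parameter sets."""

    K: int
    loglik_constrained: float
    loglik_unconstrained: float
    lr_stat: float
    df: int
    p_value: float

    def __post_init__(self):
        if self.lr_stat < -1e-6:
            raise ValueError("nesting violated: unconstrained loglik below constrained")
        if self.df <= 0:
            raise ValueError("df must be positive")


def split_half(cohort: Cohort, seed: int) -> tuple[Cohort, Cohort]:
    """Randomize subjects into two disjoint halves of size ⌈N/2⌉ and ⌊N/2⌋
    (deterministic given ``seed``)."""
    n = cohort.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.array(cohort.subject_ids)
    n_a = (n + 1) // 2
    return cohort.subset(ids[perm[:n_a]]), cohort.subset(ids[perm[n_a:]])


def _half_loglik_under(model: TrajectoryMixture, cohort: Cohort) -> float:
    """Observed-data log-likelihood of ``cohort`` under a fitted model's
    frozen parameters (same standardization as at fit time)."""
    arr, _, _ = _prepare_arrays(cohort, model.feature_names_, model.degree,
                                model.outcome, model.center_, model.scale_)
    _, ll = _e_step(arr, model.params_)
    return ll


def stability_test(cohort: Cohort, K: int, seed: int = 0,
                   halves: tuple[Cohort, Cohort] | None = None,
                   **model_kwargs) -> StabilityResult:
    """Split-half constrained/unconstrained comparison for a K-class model.

    The constrained log-likelihood is the pooled fit's; the unconstrained
    one sums two per-half fits. To protect the nesting inequality against
    EM local optima, each half fit is floored at the pooled parameters'
    likelihood on that half (the pooled solution is always an admissible
    per-half parameter set). ``halves`` overrides the random split with an
    explicit pair of disjoint groups whose union is ``cohort``.
    """
    half_a, half_b = halves if halves is not None else split_half(cohort, seed)
    pooled = TrajectoryMixture(n_classes=K, seed=seed, **model_kwargs).fit(cohort)
    ll_con = pooled.loglik_

    ll_unc = 0.0
    for half in (half_a, half_b):
        m = TrajectoryMixture(n_classes=K, seed=seed, **model_kwargs).fit(half)
        ll_unc += max(m.loglik_, _half_loglik_under(pooled, half))
    lr = 2.0 * (ll_unc - ll_con)
    df = pooled.n_params_
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return StabilityResult(K=K, loglik_constrained=ll_con,
                           loglik_unconstrained=ll_unc,
                           lr_stat=lr, df=df, p_value=p)


def match_classes_hungarian(post_a: np.ndarray, post_b: np.ndarray) -> np.ndarray:
    """Permutation aligning the columns of two posterior matrices over the
    same subjects by maximal overlap (Hungarian assignment)."""
    overlap = post_a.T @ post_b
    _, cols = linear_sum_assignment(-overlap)
    return cols


@dataclass
class CrossDesignLabels:
    """Unbiased class label per subject: each comes from the model trained
    on the opposite half."""

    table: pd.DataFrame  # subject_id, half, label, p_class1..K
    model_a: TrajectoryMixture
    model_b: TrajectoryMixture

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("subject_id")["label"]


def cross_design_labels(cohort: Cohort, K: int, seed: int = 0,
                        **model_kwargs) -> CrossDesignLabels:
    """Fit on each half, assign the other half; labels harmonized through
    the canonical mean-trajectory ordering applied within each fit."""
    half_a, half_b = split_half(cohort, seed)
    model_a = TrajectoryMixture(n_classes=K, seed=seed, **model_kwargs).fit(half_a)
    model_b = TrajectoryMixture(n_classes=K, seed=seed, **model_kwargs).fit(half_b)

    rows = []
    for half_name, assignees, model in (("B", half_b, model_a), ("A", half_a, model_b)):
        post = model.predict_proba(assignees)
        labels = post.argmax(axis=1) + 1
        for i, sid in enumerate(assignees.subject_ids):
            row = {"subject_id": sid, "half": half_name, "label": int(labels[i])}
            row.update({f"p_class{k + 1}": post[i, k] for k in range(K)})
            rows.append(row)
    table = pd.DataFrame(rows)
    # restore cohort subject order
    order = {s: i for i, s in enumerate(cohort.subject_ids)}
    table = table.sort_values("subject_id", key=lambda s: s.map(order),
                              kind="stable").reset_index(drop=True)
    return CrossDesignLabels(table=table, model_a=model_a, model_b=model_b)
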