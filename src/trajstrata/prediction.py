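"""Single-subject prediction of the long-term trajectory class from data
available at first discharge.

Features use demographic and acute-phase clinical variables plus the
functional scores at first admission and discharge only — never any
follow-up — with the days of coma capped at the event-to-discharge
interval when the latter is shorter. The classifier is a multinomial
(softmax) logistic regression on z-standardized features with a small
ridge term; standardization statistics come from the training folds
only (they are part of the trained model).

Evaluation follows the study protocol: the cohort is randomized into
two halves, each split into k consecutive folds; each fold serves once
as an unseen validation set while the model is retrained on the
remaining folds of the same half; out-of-fold predictions from both
halves are joined before computing accuracy, macro precision, Cohen's
kappa, per-class one-vs-rest ROC AUC, and row-normalized confusion
matrices, plus the share of errors falling between canonically adjacent
classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score, cohen_kappa_score, confusion_matrix, precision_score,
    roc_auc_score, roc_curve,
)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import Cohort

#: ridge strength on standardized features (intercept unpenalized);
#: guarantees a well-posed fit under complete separation.
RIDGE_LAMBDA = 1e-4

FEATURE_COLUMNS = [
    "fim_admission", "fim_delta", "coma_capped", "age_at_event",
    "anoxic", "other_nontraumatic", "gender", "los_days", "dcn", "epilepsy",
]


def build_features(cohort: Cohort, outcome: str = "total") -> pd.DataFrame:
    """First-discharge feature table, one row per subject (indexed by
    subject_id): score at admission, discharge-minus-admission delta,
    capped coma days, age at event (months), etiology dummies, gender
    (F=1), length of stay, neurosurgery and epilepsy flags. Uses no
    information observed after first discharge."""
    ser = cohort.series
    adm = ser[ser["timepoint"] == "admission"].set_index("subject_id")[outcome]
    dis = ser[ser["timepoint"] == "discharge"].set_index("subject_id")[outcome]
    cov = cohort.covariates.set_index("subject_id")
    for sid in cov.index:
        if sid not in adm.index or sid not in dis.index:
            raise ValueError(f"subject {sid}: missing admission/discharge observation")
    feats = pd.DataFrame(index=cov.index)
    feats["fim_admission"] = adm.reindex(cov.index).astype(float)
    feats["fim_delta"] = dis.reindex(cov.index).astype(float) - feats["fim_admission"]
    feats["coma_capped"] = np.minimum(
        cov["coma_days"], cov["event_to_discharge_days"]).astype(float)
    feats["age_at_event"] = cov["age_at_event_months"].astype(float)
    feats["anoxic"] = (cov["etiology"] == "anoxic").astype(float)
    feats["other_nontraumatic"] = (cov["etiology"] == "other_nontraumatic").astype(float)
    feats["gender"] = (cov["gender"] == "F").astype(float)
    feats["los_days"] = cov["los_days"].astype(float)
    feats["dcn"] = cov["dcn"].astype(float)
    feats["epilepsy"] = cov["epilepsy"].astype(float)
    return feats


class DischargeClassifier:
    """Multinomial logistic regression over standardized discharge features.

    ``one_vs_rest=True`` switches to independent binary fits per class
    (normalized probabilities) as a robustness alternative.
    """

    def __init__(self, ridge_lambda: float = RIDGE_LAMBDA,
                 one_vs_rest: bool = False, max_iter: int = 2000):
        self.ridge_lambda = ridge_lambda
        self.one_vs_rest = one_vs_rest
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge_lambda": self.ridge_lambda,
                "one_vs_rest": self.one_vs_rest, "max_iter": self.max_iter}

    def set_params(self, **params) -> "DischargeClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "DischargeClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes in y")
        base = LogisticRegression(C=1.0 / self.ridge_lambda, max_iter=self.max_iter,
                                  tol=1e-8)
        est = OneVsRestClassifier(base) if self.one_vs_rest else base
        self.feature_names_ = list(X.columns)
        self.pipeline_ = Pipeline([("scale", StandardScaler()), ("logit", est)])
        self.pipeline_.fit(X.to_numpy(dtype=float), y)
        self.classes_ = self.pipeline_.named_steps["logit"].classes_
        return self

    def _check_X(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names_:
            missing = set(self.feature_names_) - set(X.columns)
            if missing:
                raise ValueError(f"feature schema mismatch: missing {sorted(missing)}")
            X = X[self.feature_names_]  # name-based binding
        return X.to_numpy(dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline_.predict_proba(self._check_X(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Binarize by maximal probability (ties to the lower class)."""
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def coefficients(self) -> pd.DataFrame:
        """Standardized-scale coefficients, classes x features."""
        logit = self.pipeline_.named_steps["logit"]
        if self.one_vs_rest:
            coef = np.vstack([e.coef_ for e in logit.estimators_])
        else:
            coef = logit.coef_
        return pd.DataFrame(coef, columns=self.feature_names_)


def fit_classifier(X: pd.DataFrame, y, **kwargs) -> DischargeClassifier:
    """Fit the discharge-feature classifier; see :class:`DischargeClassifier`."""
    return DischargeClassifier(**kwargs).fit(X, y)


def predict_probs(classifier: DischargeClassifier, X: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Probability matrix (rows sum to 1) and maximal-probability labels."""
    probs = classifier.predict_proba(X)
    return probs, classifier.classes_[probs.argmax(axis=1)]


def feature_importance(classifier: DischargeClassifier) -> pd.DataFrame:
    """Features ranked by the maximum absolute standardized coefficient
    across classes (ties broken alphabetically)."""
    coef = classifier.coefficients()
    score = coef.abs().max(axis=0)
    out = pd.DataFrame({"feature": score.index, "max_abs_coef": score.to_numpy()})
    out = out.sort_values(["max_abs_coef", "feature"],
                          ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


@dataclass
class CVPlan:
    """Fold scheme: within each randomized half, a seeded shuffle followed
    by k consecutive blocks; optional stratification by class."""

    k: int = 5
    seed: int = 0
    stratify: bool = False


def _half_folds(n: int, k: int, rng: np.random.Generator,
                y: np.ndarray | None) -> list[np.ndarray]:
    order = rng.permutation(n)
    if y is not None:  # stratified: round-robin classes over folds
        order = order[np.argsort(y[order], kind="stable")]
        return [order[f::k] for f in range(k)]
    return [chunk for chunk in np.array_split(order, k)]


def nested_cv_predict(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                      plan: CVPlan | None = None, **clf_kwargs) -> pd.DataFrame:
    """Out-of-fold predictions for every subject under the two-half,
    k-fold protocol; the returned table joins both halves.

    Columns: subject_id, true, pred, half, fold, p_class<k> for every
    class present in ``labels`` (probability 0 for classes absent from a
    training fold, with a warning).
    """
    plan = plan or CVPlan()
    y = pd.Series(np.asarray(labels), index=features.index)
    classes = np.sort(np.unique(y))
    rng = np.random.default_rng(plan.seed)
    n = len(features)
    perm = rng.permutation(n)
    n_a = (n + 1) // 2
    halves = {"A": perm[:n_a], "B": perm[n_a:]}

    rows = []
    for half_name, idx in halves.items():
        sub_y = y.iloc[idx].to_numpy()
        folds = _half_folds(len(idx), plan.k, rng, sub_y if plan.stratify else None)
        for f, fold_local in enumerate(folds):
            test_idx = idx[fold_local]
            train_idx = np.setdiff1d(idx, test_idx)
            y_train = y.iloc[train_idx]
            if len(np.unique(y_train)) < len(classes):
                warnings.warn(f"half {half_name} fold {f}: a class is absent "
                              "from the training set")
            clf = DischargeClassifier(**clf_kwargs).fit(features.iloc[train_idx], y_train)
            probs = clf.predict_proba(features.iloc[test_idx])
            full = np.zeros((len(test_idx), len(classes)))
            for j, c in enumerate(clf.classes_):
                full[:, np.searchsorted(classes, c)] = probs[:, j]
            pred = classes[full.argmax(axis=1)]
            for r, i_global in enumerate(test_idx):
                row = {"subject_id": features.index[i_global],
                       "true": int(y.iloc[i_global]), "pred": int(pred[r]),
                       "half": half_name, "fold": f}
                row.update({f"p_class{c}": full[r, j] for j, c in enumerate(classes)})
                rows.append(row)
    out = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(features.index)}
    return out.sort_values("subject_id", key=lambda s: s.map(order),
                           kind="stable").reset_index(drop=True)


@dataclass
class EvalReport:
    """Multi-class prediction metrics on joined out-of-fold results."""

    accuracy: float
    precision_macro: float
    kappa: float
    auc: dict[int, float]
    confusion_raw: np.ndarray
    confusion_normalized: np.ndarray
    n_correct: int
    n_total: int
    adjacency_error_share: float
    roc_curves: dict[int, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "kappa": self.kappa,
            "auc": {str(k): (None if v is None or np.isnan(v) else float(v))
                    for k, v in self.auc.items()},
            "confusion_raw": self.confusion_raw.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "adjacency_error_share": (None if np.isnan(self.adjacency_error_share)
                                      else float(self.adjacency_error_share)),
        }


def evaluate(predictions: pd.DataFrame, K: int | None = None,
             with_curves: bool = False) -> EvalReport:
    """Score a joined out-of-fold prediction table (as produced by
    :func:`nested_cv_predict`; needs columns true, pred and p_class<k>).

    AUC is one-vs-rest per class on that class's probability column (the
    Mann-Whitney rank statistic); classes absent from the truth get a
    missing AUC. The confusion matrix is row-normalized per true class;
    ``adjacency_error_share`` is the fraction of misclassified subjects
    whose predicted class is canonically adjacent to the true one.
    """
    true = predictions["true"].to_numpy()
    pred = predictions["pred"].to_numpy()
    if K is None:
        K = int(max(true.max(), pred.max()))
    classes = np.arange(1, K + 1)

    acc = float(accuracy_score(true, pred))
    prec = float(precision_score(true, pred, labels=classes, average="macro",
                                 zero_division=0))
    kappa = float(cohen_kappa_score(true, pred))
    raw = confusion_matrix(true, pred, labels=classes)
    with np.errstate(invalid="ignore"):
        norm = raw / raw.sum(axis=1, keepdims=True)
    norm = np.nan_to_num(norm, nan=0.0)

    auc: dict[int, float] = {}
    curves: dict[int, pd.DataFrame] = {}
    for c in classes:
        col = f"p_class{c}"
        y_bin = (true == c).astype(int)
        if col not in predictions.columns or y_bin.min() == y_bin.max():
            auc[int(c)] = float("nan")
            continue
        score = predictions[col].to_numpy()
        auc[int(c)] = float(roc_auc_score(y_bin, score))
        if with_curves:
            fpr, tpr, thr = roc_curve(y_bin, score)
            curves[int(c)] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    errors = true != pred
    adj = float(np.mean(np.abs(true[errors] - pred[errors]) == 1)) if errors.any() else float("nan")
    return EvalReport(accuracy=acc, precision_macro=prec, kappa=kappa, auc=auc,
                      confusion_raw=raw, confusion_normalized=norm,
                      n_correct=int((~errors).sum()), n_total=len(true),
                      adjacency_error_share=adj, roc_curves=curves)
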