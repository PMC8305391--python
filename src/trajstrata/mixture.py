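"""Joint latent-class growth model with informative dropout.

The model stratifies a longitudinal cohort into K unobserved classes via
three linked equations:

1. *Membership*: a multinomial-logit regression of class probability on
   baseline covariates, with class 1 as the reference (coefficients are
   log-odds vs the reference class, on z-standardized covariates).
2. *Trajectory*: within class k, the outcome at time t (years since
   admission; discharge at LOS/365.25) is Gaussian around a polynomial
   mean ``beta_k @ (1, t, ..., t^degree)`` with residual scale sigma
   (shared across classes by default).
3. *Service exit*: a class-specific discrete-time hazard over the seven
   yearly follow-up intervals; subjects who left the service (death,
   exit on recovery, opt-out) contribute the exit probability of their
   exit interval, while censored / still-enrolled subjects contribute
   survival terms only. Dropout is thereby informative about class.

Estimation is by multi-start EM (random Dirichlet responsibilities per
start), maximizing the observed-data log-likelihood

    sum_i log sum_k pi_k(x_i) * L_ik,

with missing follow-up visits simply omitted from the Gaussian term (no
imputation). Classes are relabeled a posteriori in ascending order of
the model-implied mean outcome over the follow-up window (equivalently,
for separated trajectories, at year 7), so class 1 is always the
floor-level ("non-responder") class and serves as the reference for the
membership coefficients. Model choice across K uses the Bayesian
Information Criterion, BIC = -2 loglik + n_params ln(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .cohort import (
    Cohort, DEFAULT_KEEP_PRIORITY, EVENT_REASONS, N_INTERVALS,
    TIMEPOINT_INDEX, TIMEPOINTS, encode_covariates,
)

DAYS_PER_YEAR = 365.25

HAZARD_FLOOR = 1e-6
DEGENERATE_MASS = 1e-8

#: default membership covariate set (the study's screened covariates, with
#: etiology expanded to dummies vs traumatic).
DEFAULT_MEMBERSHIP_COVARIATES = list(DEFAULT_KEEP_PRIORITY)


class DegenerateClassError(RuntimeError):
    """An EM start collapsed: some class lost all posterior mass."""


class ConvergenceError(RuntimeError):
    """No EM start converged."""


def time_basis(timepoint: str, los_days: int, degree: int = 2) -> np.ndarray:
    """Polynomial time basis ``(1, t, ..., t^degree)`` for a visit.

    Admission maps to t=0, discharge to t=LOS/365.25 years, and yearly
    follow-up Yk to t=k.
    """
    if timepoint not in TIMEPOINT_INDEX:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    idx = TIMEPOINT_INDEX[timepoint]
    if idx == 0:
        t = 0.0
    elif idx == 1:
        t = float(los_days) / DAYS_PER_YEAR
    else:
        t = float(idx - 1)
    return t ** np.arange(degree + 1, dtype=float)


def membership_probs(gamma: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class probabilities from membership coefficients.

    ``gamma`` is K x (p+1) with an all-zero reference first row (a
    (K-1) x (p+1) matrix of non-reference rows is also accepted); ``x``
    is a covariate vector or matrix including the leading intercept term.
    """
    gamma = np.asarray(gamma, dtype=float)
    x = np.asarray(x, dtype=float)
    one_dim = x.ndim == 1
    X = np.atleast_2d(x)
    if gamma.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: gamma has {gamma.shape[1]} columns, x has {X.shape[1]}")
    if not np.allclose(gamma[0], 0.0):
        gamma = np.vstack([np.zeros(gamma.shape[1]), gamma])
    eta = X @ gamma.T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if one_dim else p


@dataclass
class MixtureParams:
    """Parameter set of the fitted K-class joint model.

    ``gamma``: K x (p+1) membership log-odds (row 0 is the all-zero
    reference); ``beta``: K x (degree+1) trajectory coefficients;
    ``sigma``: residual SD (scalar, or length-K when class-specific);
    ``hazard``: K x 7 per-interval exit probabilities.
    """

    gamma: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray | float
    hazard: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    def sigma_vector(self) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if s.size == 1:
            s = np.full(self.n_classes, s[0])
        return s

    def validate(self) -> None:
        if not np.all(np.isfinite(self.gamma)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite parameter")
        if np.any(self.sigma_vector() <= 0):
            raise ValueError("sigma must be positive")
        if np.any((self.hazard <= 0) | (self.hazard >= 1)):
            raise ValueError("hazard entries must lie in (0, 1)")


@dataclass
class _Arrays:
    """Cohort unpacked into the flat arrays the EM iterates over."""

    subject_ids: list
    X: np.ndarray          # N x (p+1) membership design (intercept first)
    y: np.ndarray          # all observed outcome values, flattened
    subj: np.ndarray       # subject index per observation
    T: np.ndarray          # n_obs x (degree+1) time-basis rows
    S: np.ndarray          # N x 7 survived-interval indicators
    E: np.ndarray          # N x 7 exit-interval indicators

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _exit_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    n = cohort.n_subjects
    S = np.zeros((n, N_INTERVALS))
    E = np.zeros((n, N_INTERVALS))
    ext = cohort.exits.set_index("subject_id")
    for i, sid in enumerate(cohort.subject_ids):
        last_idx = TIMEPOINT_INDEX[ext.at[sid, "last_timepoint"]]
        n_surv = max(last_idx - 1, 0)  # intervals completed in service
        S[i, :n_surv] = 1.0
        if ext.at[sid, "reason"] in EVENT_REASONS and n_surv < N_INTERVALS:
            E[i, n_surv] = 1.0
    return S, E


def _prepare_arrays(
    cohort: Cohort,
    membership_covariates: list[str],
    degree: int,
    outcome: str,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[_Arrays, np.ndarray, np.ndarray]:
    """Flatten a cohort; returns (arrays, center, scale) where center/scale
    standardize the membership covariates (computed here unless given)."""
    enc = encode_covariates(cohort.covariates)
    missing = [c for c in membership_covariates if c not in enc.columns]
    if missing:
        raise ValueError(f"missing membership covariate(s): {missing}")
    Xc = enc[membership_covariates].to_numpy(dtype=float)
    if center is None:
        center = Xc.mean(axis=0)
        scale = Xc.std(axis=0, ddof=0)
        # leave 0/1 indicator columns on their natural scale
        for j, name in enumerate(membership_covariates):
            col = Xc[:, j]
            if set(np.unique(col)) <= {0.0, 1.0}:
                center[j], scale[j] = 0.0, 1.0
        scale[scale == 0] = 1.0
    Xs = (Xc - center) / scale
    X = np.column_stack([np.ones(len(Xs)), Xs])

    ser = cohort.series
    los = cohort.covariates.set_index("subject_id")["los_days"]
    sid_index = {s: i for i, s in enumerate(cohort.subject_ids)}
    subj = ser["subject_id"].map(sid_index).to_numpy()
    tp_idx = ser["timepoint"].map(TIMEPOINT_INDEX).to_numpy()
    t = np.where(tp_idx == 0, 0.0,
                 np.where(tp_idx == 1,
                          los.reindex(ser["subject_id"]).to_numpy() / DAYS_PER_YEAR,
                          tp_idx - 1.0))
    T = t[:, None] ** np.arange(degree + 1)
    y = ser[outcome].to_numpy(dtype=float)
    S, E = _exit_arrays(cohort)
    return _Arrays(list(cohort.subject_ids), X, y, subj, T, S, E), center, scale


def _log_membership(X: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    eta = X @ gamma.T
    return eta - logsumexp(eta, axis=1, keepdims=True)


def _class_loglik(arr: _Arrays, params: MixtureParams) -> np.ndarray:
    """N x K matrix of per-subject conditional log-likelihoods L_ik
    (Gaussian trajectory terms plus exit-process terms)."""
    sig = params.sigma_vector()
    mu = arr.T @ params.beta.T                       # n_obs x K
    resid2 = (arr.y[:, None] - mu) ** 2
    ll_obs = -0.5 * np.log(2.0 * np.pi * sig**2)[None, :] - resid2 / (2.0 * sig**2)[None, :]
    ll = np.zeros((arr.n, params.n_classes))
    np.add.at(ll, arr.subj, ll_obs)
    ll += arr.S @ np.log1p(-params.hazard).T + arr.E @ np.log(params.hazard).T
    return ll


def _e_step(arr: _Arrays, params: MixtureParams) -> tuple[np.ndarray, float]:
    """Posterior class probabilities (N x K) and the observed-data
    log-likelihood, computed in log space."""
    params.validate()
    A = _log_membership(arr.X, params.gamma) + _class_loglik(arr, params)
    ll_i = logsumexp(A, axis=1)
    if not np.all(np.isfinite(ll_i)):
        raise FloatingPointError("non-finite subject likelihood")
    post = np.exp(A - ll_i[:, None])
    return post, float(ll_i.sum())


def _fit_weighted_multinomial(
    X: np.ndarray, W: np.ndarray, gamma0: np.ndarray,
    grad_tol: float = 1e-8, max_iter: int = 100, ridge: float = 1e-10,
) -> np.ndarray:
    """Posterior-weighted multinomial-logit maximization by damped Newton.

    Maximizes Q(gamma) = sum_i sum_k W_ik log pi_k(x_i) (minus a vanishing
    ridge for numerical identifiability). Reference row stays zero. Each
    accepted step increases Q, preserving EM monotonicity.
    """
    n, p1 = X.shape
    K = W.shape[1]
    if K == 1:
        return np.zeros((1, p1))
    theta = gamma0[1:].copy()  # (K-1) x p1 free block

    def q_of(th: np.ndarray) -> tuple[float, np.ndarray]:
        g = np.vstack([np.zeros(p1), th])
        logpi = _log_membership(X, g)
        q = float((W * logpi).sum()) - 0.5 * ridge * float((th * th).sum())
        return q, np.exp(logpi)

    q, P = q_of(theta)
    for _ in range(max_iter):
        G = X.T @ (W - P)[:, 1:]                     # p1 x (K-1)
        grad = G.T.ravel() - ridge * theta.ravel()
        if np.linalg.norm(grad, ord=np.inf) < grad_tol:
            break
        H = np.zeros(((K - 1) * p1, (K - 1) * p1))
        for a in range(1, K):
            for b in range(1, K):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                block = (X * w[:, None]).T @ X
                H[(a - 1) * p1:a * p1, (b - 1) * p1:b * p1] = block
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, grad).reshape(K - 1, p1)
        except np.linalg.LinAlgError:
            step = grad.reshape(K - 1, p1)
        t = 1.0
        improved = False
        for _ in range(40):
            q_new, P_new = q_of(theta + t * step)
            if q_new >= q - 1e-12:
                theta = theta + t * step
                if q_new > q:
                    improved = True
                q, P = q_new, P_new
                break
            t *= 0.5
        if not improved:
            break
    return np.vstack([np.zeros(p1), theta])


def _m_step(
    arr: _Arrays, W: np.ndarray, degree: int,
    gamma0: np.ndarray, class_specific_sigma: bool = False,
) -> MixtureParams:
    """Maximize the EM lower bound given responsibilities ``W``."""
    n, K = W.shape
    mass = W.sum(axis=0)
    weak = np.where(mass < DEGENERATE_MASS)[0]
    if weak.size:
        raise DegenerateClassError(f"class {weak[0] + 1} lost all posterior mass")

    p1 = degree + 1
    beta = np.zeros((K, p1))
    w_obs = W[arr.subj]                              # n_obs x K
    for k in range(K):
        wk = w_obs[:, k]
        A = arr.T.T @ (arr.T * wk[:, None]) + 1e-8 * np.eye(p1)
        b = arr.T.T @ (arr.y * wk)
        beta[k] = np.linalg.solve(A, b)
    resid2 = (arr.y[:, None] - arr.T @ beta.T) ** 2
    if class_specific_sigma:
        ss = (w_obs * resid2).sum(axis=0)
        nn = w_obs.sum(axis=0)
        sigma = np.sqrt(np.maximum(ss / np.maximum(nn, 1e-12), 1e-6))
    else:
        sigma = float(np.sqrt(max((w_obs * resid2).sum() / len(arr.y), 1e-6)))

    num = W.T @ arr.E                                # K x 7
    den = W.T @ (arr.S + arr.E)
    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = np.where(den > 0, num / np.maximum(den, 1e-300), HAZARD_FLOOR)
    hazard = np.clip(hazard, HAZARD_FLOOR, 1.0 - HAZARD_FLOOR)

    gamma = _fit_weighted_multinomial(arr.X, W, gamma0)
    return MixtureParams(gamma=gamma, beta=beta, sigma=sigma, hazard=hazard)


def _canonical_order(params: MixtureParams, degree: int) -> np.ndarray:
    """Permutation sorting classes by the model-implied mean outcome
    averaged over the follow-up window [0, 7] years.

    Averaging over the window gives the same ranking as the year-7
    endpoint whenever endpoints are well separated, but stays stable when
    two trajectories converge near the scale ceiling by year 7 (where the
    endpoint ranking flips under estimation noise); class 1 is always the
    floor-level non-responder curve.
    """
    d = np.arange(degree + 1)
    basis = 7.0 ** d / (d + 1)  # mean of t^d over [0, 7]
    return np.argsort(params.beta @ basis, kind="stable")


def _relabel(params: MixtureParams, post: np.ndarray, order: np.ndarray,
             class_specific_sigma: bool) -> tuple[MixtureParams, np.ndarray]:
    gamma = params.gamma[order]
    gamma = gamma - gamma[0]                         # new class 1 is reference
    sigma = params.sigma_vector()[order] if class_specific_sigma else params.sigma
    new = MixtureParams(gamma=gamma, beta=params.beta[order],
                        sigma=sigma, hazard=params.hazard[order])
    return new, post[:, order]


class TrajectoryMixture(BaseEstimator):
    """K-class joint latent-class growth model with informative dropout.

    Parameters
    ----------
    n_classes : int, default 4
        Number of latent trajectory classes (2-5 in the intended use).
    degree : int, default 2
        Polynomial degree of the class mean trajectories.
    membership_covariates : list of str, optional
        Encoded covariate names entering the membership submodel; defaults
        to the full screened clinical set.
    em_tol : float, default 1e-6
        Relative log-likelihood change declaring EM convergence.
    max_iter : int, default 500
        EM iteration cap per start.
    n_starts : int, default 10
        Random restarts; each draws initial responsibilities from a
        per-subject flat Dirichlet seeded with ``seed + start``.
    seed : int, default 0
        Base seed.
    outcome : {"total", "selfcare", "mobility", "cognition"}, default "total"
        Score series to model.
    class_specific_sigma : bool, default False
        Estimate one residual SD per class instead of a shared one.

    Attributes (after ``fit``)
    --------------------------
    ``params_`` (:class:`MixtureParams`), ``beta_``, ``gamma_``,
    ``sigma_``, ``hazard_``, ``loglik_``, ``bic_``, ``n_params_``,
    ``posterior_``, ``labels_``, ``marginal_probs_``, ``class_order_``,
    ``converged_``, ``n_iter_``, ``start_index_``, ``loglik_path_``,
    ``endpoint_means_``, ``feature_names_``.
    """

    def __init__(self, n_classes: int = 4, degree: int = 2,
                 membership_covariates: list[str] | None = None,
                 em_tol: float = 1e-6, max_iter: int = 500, n_starts: int = 10,
                 seed: int = 0, outcome: str = "total",
                 class_specific_sigma: bool = False):
        self.n_classes = n_classes
        self.degree = degree
        self.membership_covariates = membership_covariates
        self.em_tol = em_tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.seed = seed
        self.outcome = outcome
        self.class_specific_sigma = class_specific_sigma

    # -- internals -------------------------------------------------------
    def _covariate_names(self) -> list[str]:
        return list(self.membership_covariates or DEFAULT_MEMBERSHIP_COVARIATES)

    def _run_em(self, arr: _Arrays, W0: np.ndarray):
        K = self.n_classes
        p1 = arr.X.shape[1]
        params = _m_step(arr, W0, self.degree, np.zeros((K, p1)),
                         self.class_specific_sigma)
        ll_prev = -np.inf
        path: list[float] = []
        converged = False
        n_iter = 0
        for it in range(self.max_iter):
            W, ll = _e_step(arr, params)
            path.append(ll)
            n_iter = it + 1
            if ll - ll_prev <= self.em_tol * (abs(ll_prev) + 1.0) and it > 0:
                converged = True
                break
            ll_prev = ll
            params = _m_step(arr, W, self.degree, params.gamma,
                             self.class_specific_sigma)
        W, ll = _e_step(arr, params)
        return params, W, ll, n_iter, converged, np.array(path)

    # -- API -------------------------------------------------------------
    def fit(self, cohort: Cohort, y=None) -> "TrajectoryMixture":
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        names = self._covariate_names()
        arr, center, scale = _prepare_arrays(cohort, names, self.degree, self.outcome)
        K = self.n_classes
        best = None
        failures: list[str] = []
        for s in range(self.n_starts):
            rng = np.random.default_rng((self.seed + s) % (2**31))
            W0 = rng.dirichlet(np.ones(K), size=arr.n)
            try:
                out = self._run_em(arr, W0)
            except (DegenerateClassError, FloatingPointError) as exc:
                failures.append(f"start {s}: {exc}")
                continue
            params, W, ll, n_iter, converged, path = out
            if converged and (best is None or ll > best[2]):
                best = (params, W, ll, n_iter, converged, path, s)
        if best is None:
            raise ConvergenceError(
                "no EM start converged; diagnostics: " + "; ".join(failures or ["none"]))
        params, W, ll, n_iter, converged, path, start_idx = best

        order = _canonical_order(params, self.degree)
        params, W = _relabel(params, W, order, self.class_specific_sigma)

        self.feature_names_ = names
        self.center_, self.scale_ = center, scale
        self.params_ = params
        self.gamma_, self.beta_ = params.gamma, params.beta
        self.sigma_, self.hazard_ = params.sigma, params.hazard
        self.posterior_ = W
        self.labels_ = W.argmax(axis=1) + 1
        self.loglik_ = ll
        self.loglik_path_ = path
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.start_index_ = start_idx
        self.class_order_ = order
        p = len(names)
        n_sigma = K if self.class_specific_sigma else 1
        self.n_params_ = (K - 1) * (p + 1) + K * (self.degree + 1) + n_sigma + K * N_INTERVALS
        self.bic_ = -2.0 * ll + self.n_params_ * np.log(arr.n)
        X = arr.X
        self.marginal_probs_ = np.exp(_log_membership(X, params.gamma)).mean(axis=0)
        self.endpoint_means_ = params.beta @ (7.0 ** np.arange(self.degree + 1))
        d = np.arange(self.degree + 1)
        self.trajectory_means_ = params.beta @ (7.0 ** d / (d + 1))
        self.subject_ids_ = arr.subject_ids
        return self

    def predict_proba(self, cohort: Cohort) -> np.ndarray:
        """Posterior class probabilities for (possibly unseen) subjects,
        with the fitted parameters frozen."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "params_")
        arr, _, _ = _prepare_arrays(cohort, self.feature_names_, self.degree,
                                    self.outcome, self.center_, self.scale_)
        post, _ = _e_step(arr, self.params_)
        return post

    def predict(self, cohort: Cohort) -> np.ndarray:
        """Maximal-posterior class labels (1-based canonical order; ties go
        to the lower class index)."""
        return self.predict_proba(cohort).argmax(axis=1) + 1

    def mean_trajectory(self, klass: int, times: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Model-implied mean outcome of class ``klass`` (1-based) at
        ``times`` (years); for reporting the curve is clamped to the scale
        bounds — clamping never enters the likelihood."""
        from .cohort import SCORE_BOUNDS
        t = np.asarray(times, dtype=float)
        T = t[:, None] ** np.arange(self.degree + 1)
        mu = T @ self.beta_[klass - 1]
        if clamp:
            lo, hi = SCORE_BOUNDS[self.outcome]
            mu = np.clip(mu, lo, hi)
        return mu

    def class_mean_max_posterior(self) -> np.ndarray:
        """Per-class mean of the maximal posterior probability among the
        subjects assigned to that class (the classification-sharpness
        diagnostic reported per class)."""
        out = np.full(self.n_classes, np.nan)
        top = self.posterior_.max(axis=1)
        for k in range(self.n_classes):
            mask = self.labels_ == k + 1
            if mask.any():
                out[k] = top[mask].mean()
        return out


# ----------------------------------------------------------------------
# thin functional wrappers

def subject_class_loglik(
    series: pd.DataFrame, last_timepoint: str, reason: str,
    beta_k: np.ndarray, sigma: float, hazard_k: np.ndarray,
    los_days: int, degree: int = 2, outcome: str = "total",
) -> float:
    """Conditional log-likelihood of one subject under one class: Gaussian
    log-densities of the observed scores around the class trajectory, plus
    survival terms log(1-h_j) for each interval completed in service and,
    for subjects who actively left (death/recovery/opt-out) within the
    follow-up window, log(h_j) at the exit interval."""
    beta_k = np.asarray(beta_k, dtype=float)
    total = 0.0
    for _, row in series.iterrows():
        tb = time_basis(row["timepoint"], los_days, degree)
        mu = float(tb @ beta_k)
        r = float(row[outcome]) - mu
        total += -0.5 * np.log(2.0 * np.pi * sigma**2) - r**2 / (2.0 * sigma**2)
    n_surv = max(TIMEPOINT_INDEX[last_timepoint] - 1, 0)
    for j in range(n_surv):
        total += np.log1p(-hazard_k[j])
    if reason in EVENT_REASONS and n_surv < N_INTERVALS:
        total += np.log(hazard_k[n_surv])
    return float(total)


def mixture_loglik(cohort: Cohort, params: MixtureParams,
                   membership_covariates: list[str] | None = None,
                   degree: int = 2, outcome: str = "total",
                   standardize: bool = False) -> float:
    """Observed-data log-likelihood of a cohort under explicit parameters
    (log-sum-exp over classes per subject). With ``standardize=False`` the
    covariates enter on their raw scale."""
    names = list(membership_covariates or DEFAULT_MEMBERSHIP_COVARIATES)
    if standardize:
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome)
    else:
        p = len(names)
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome,
                                    center=np.zeros(p), scale=np.ones(p))
    _, ll = _e_step(arr, params)
    return ll


def e_step(cohort: Cohort, params: MixtureParams,
           membership_covariates: list[str] | None = None,
           degree: int = 2, outcome: str = "total",
           standardize: bool = False) -> np.ndarray:
    """Posterior class-membership matrix under explicit parameters."""
    names = list(membership_covariates or DEFAULT_MEMBERSHIP_COVARIATES)
    if standardize:
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome)
    else:
        p = len(names)
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome,
                                    center=np.zeros(p), scale=np.ones(p))
    post, _ = _e_step(arr, params)
    return post


def m_step(cohort: Cohort, posterior: np.ndarray,
           membership_covariates: list[str] | None = None,
           degree: int = 2, outcome: str = "total",
           standardize: bool = False,
           class_specific_sigma: bool = False) -> MixtureParams:
    """One M-step from explicit responsibilities."""
    names = list(membership_covariates or DEFAULT_MEMBERSHIP_COVARIATES)
    if standardize:
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome)
    else:
        p = len(names)
        arr, _, _ = _prepare_arrays(cohort, names, degree, outcome,
                                    center=np.zeros(p), scale=np.ones(p))
    K = posterior.shape[1]
    return _m_step(arr, posterior, degree, np.zeros((K, arr.X.shape[1])),
                   class_specific_sigma)


def fit(cohort: Cohort, n_classes: int = 4, **kwargs) -> TrajectoryMixture:
    """Fit the joint latent-class model; see :class:`TrajectoryMixture`."""
    return TrajectoryMixture(n_classes=n_classes, **kwargs).fit(cohort)


def assign(fitted: TrajectoryMixture, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Labels and posterior matrix for a cohort under frozen parameters."""
    post = fitted.predict_proba(cohort)
    return post.argmax(axis=1) + 1, post


def bic_scan(cohort: Cohort, class_range=(2, 3, 4, 5), seed: int = 0,
             return_models: bool = False, **kwargs):
    """Fit one model per K and tabulate loglik, parameter count, BIC and
    the per-class posterior-sharpness diagnostic (minimum over classes of
    the mean maximal posterior within each class)."""
    rows, models = [], {}
    for K in class_range:
        try:
            model = TrajectoryMixture(n_classes=K, seed=seed, **kwargs).fit(cohort)
        except (ConvergenceError, DegenerateClassError) as exc:
            warnings.warn(f"K={K}: fit failed ({exc}); row omitted")
            continue
        sharp = model.class_mean_max_posterior()
        rows.append({"K": K, "loglik": model.loglik_, "n_params": model.n_params_,
                     "bic": model.bic_,
                     "min_class_mean_max_posterior": float(np.nanmin(sharp)),
                     "converged": model.converged_})
        models[K] = model
    table = pd.DataFrame(rows)
    return (table, models) if return_models else table
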