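"""Joint latent-class model: likelihood oracle equivalence, EM behaviour,
canonical ordering, recovery of generating structure."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from trajstrata.cohort import TIMEPOINT_INDEX
from trajstrata.mixture import (
    DEFAULT_MEMBERSHIP_COVARIATES, DegenerateClassError, MixtureParams,
    TrajectoryMixture, e_step, m_step, membership_probs, mixture_loglik,
    subject_class_loglik, time_basis,
)
from trajstrata.mixture import _prepare_arrays, _e_step, _m_step
from trajstrata.simulate import GeneratorConfig, generate_cohort, two_class_specs
from trajstrata.cohort import encode_covariates

from conftest import make_toy_cohort
from test_simulate import no_dropout, noiseless_config


# ---------------------------------------------------------------------------
# independent brute-force oracle: explicit loops, no shared code

def brute_force_mixture_loglik(cohort, params, covariate_names, degree, outcome):
    gamma = params.gamma
    K = gamma.shape[0]
    enc = encode_covariates(cohort.covariates)
    total = 0.0
    for i, sid in enumerate(cohort.subject_ids):
        x = [1.0] + [float(enc.iloc[i][c]) for c in covariate_names]
        etas = [sum(g * xx for g, xx in zip(gamma[k], x)) for k in range(K)]
        denom = sum(math.exp(e - max(etas)) for e in etas)
        per_class = []
        for k in range(K):
            pi_k = math.exp(etas[k] - max(etas)) / denom
            ll = 0.0
            sub = cohort.series[cohort.series["subject_id"] == sid]
            los = int(cohort.covariates.set_index("subject_id").at[sid, "los_days"])
            sigma = params.sigma_vector()[k]
            for _, row in sub.iterrows():
                idx = TIMEPOINT_INDEX[row["timepoint"]]
                t = 0.0 if idx == 0 else (los / 365.25 if idx == 1 else idx - 1.0)
                mu = sum(params.beta[k][d] * t**d for d in range(degree + 1))
                r = float(row[outcome]) - mu
                ll += -0.5 * math.log(2 * math.pi * sigma**2) - r * r / (2 * sigma**2)
            ext = cohort.exits.set_index("subject_id")
            last = TIMEPOINT_INDEX[ext.at[sid, "last_timepoint"]]
            n_surv = max(last - 1, 0)
            for j in range(n_surv):
                ll += math.log(1.0 - params.hazard[k][j])
            if ext.at[sid, "reason"] in {"death", "recovery", "opt_out"} and n_surv < 7:
                ll += math.log(params.hazard[k][n_surv])
            per_class.append(pi_k * math.exp(ll))
        total += math.log(sum(per_class))
    return total


def toy_params(K=2, p=2, degree=2, seed=0):
    rng = np.random.default_rng(seed)
    gamma = np.vstack([np.zeros(p + 1), rng.normal(size=(K - 1, p + 1)) * 0.5])
    beta = np.array([[20.0, 3.0, -0.2], [40.0, 10.0, -0.8],
                     [60.0, 8.0, -0.5], [80.0, 5.0, -0.3]])[:K, :degree + 1]
    hazard = np.tile(np.linspace(0.05, 0.2, K)[:, None], (1, 7))
    return MixtureParams(gamma=gamma, beta=beta, sigma=8.0, hazard=hazard)


class TestTimeBasis:
    def test_admission_is_time_zero(self):
        assert np.allclose(time_basis("admission", 112, 2), [1, 0, 0])

    def test_followups_in_integer_years(self):
        assert np.allclose(time_basis("Y2", 999, 2), [1, 2, 4])

    def test_discharge_in_fractional_years(self):
        b = time_basis("discharge", 365, 1)
        assert np.allclose(b, [1.0, 365 / 365.25])

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            time_basis("Y9", 100, 2)


class TestMembershipProbs:
    def test_zero_coefficients_give_uniform(self):
        p = membership_probs(np.zeros((4, 3)), np.array([1.0, 0.5, -0.5]))
        assert np.allclose(p, 0.25)

    def test_binary_softmax_value(self):
        gamma = np.array([[0.0, 0.0], [1.0, 0.0]])
        p = membership_probs(gamma, np.array([1.0, 0.0]))
        assert np.allclose(p, [1 / (1 + math.e), math.e / (1 + math.e)], atol=1e-5)
        assert abs(p[1] - 0.73106) < 1e-5

    def test_saturation(self):
        gamma = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 0.0]])
        p = membership_probs(gamma, np.array([1.0, 0.0]))
        assert np.allclose(p, [0, 1, 0], atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            membership_probs(np.zeros((2, 3)), np.ones(4))


class TestSubjectClassLoglik:
    def test_single_observation_at_mean_standard_normal(self):
        ser = pd.DataFrame([{"timepoint": "admission", "total": 20}])
        ll = subject_class_loglik(ser, "admission", "censored",
                                  beta_k=[20.0, 0.0, 0.0], sigma=1.0,
                                  hazard_k=np.full(7, 0.1), los_days=100)
        assert abs(ll - (-0.5 * math.log(2 * math.pi))) < 1e-12

    def test_censored_after_y2_survival_terms(self):
        ser = pd.DataFrame(columns=["timepoint", "total"])
        ll = subject_class_loglik(ser, "Y2", "censored",
                                  beta_k=[0.0, 0.0, 0.0], sigma=1.0,
                                  hazard_k=np.full(7, 0.1), los_days=100)
        assert abs(ll - 2 * math.log(0.9)) < 1e-12

    def test_opt_out_in_first_interval(self):
        ser = pd.DataFrame(columns=["timepoint", "total"])
        ll = subject_class_loglik(ser, "discharge", "opt_out",
                                  beta_k=[0.0, 0.0, 0.0], sigma=1.0,
                                  hazard_k=np.full(7, 0.5), los_days=100)
        assert abs(ll - math.log(0.5)) < 1e-12


class TestMixtureLoglikOracle:
    COVS = ["age_at_event_months", "coma_days"]

    @pytest.mark.parametrize("K,n,seed", [(2, 3, 0), (3, 5, 1), (2, 5, 2), (3, 4, 3)])
    def test_matches_brute_force(self, K, n, seed):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=n, seed=seed))
        params = toy_params(K=K, p=len(self.COVS), seed=seed)
        fast = mixture_loglik(cohort, params, membership_covariates=self.COVS)
        slow = brute_force_mixture_loglik(cohort, params, self.COVS, 2, "total")
        assert abs(fast - slow) <= 1e-10 * abs(slow)

    def test_single_component_is_plain_sum(self, toy_cohort):
        params = toy_params(K=2, p=len(self.COVS))
        p1 = MixtureParams(gamma=np.zeros((1, 3)), beta=params.beta[:1],
                           sigma=8.0, hazard=params.hazard[:1])
        ll1 = mixture_loglik(toy_cohort, p1, membership_covariates=self.COVS)
        total = 0.0
        ext = toy_cohort.exits.set_index("subject_id")
        cov = toy_cohort.covariates.set_index("subject_id")
        for sid in toy_cohort.subject_ids:
            sub = toy_cohort.series[toy_cohort.series["subject_id"] == sid]
            total += subject_class_loglik(
                sub, ext.at[sid, "last_timepoint"], ext.at[sid, "reason"],
                p1.beta[0], 8.0, p1.hazard[0], int(cov.at[sid, "los_days"]))
        assert abs(ll1 - total) < 1e-9

    def test_identical_components_equal_single(self, toy_cohort):
        params = toy_params(K=2, p=len(self.COVS))
        same = MixtureParams(gamma=np.zeros((2, 3)),
                             beta=np.vstack([params.beta[0]] * 2), sigma=8.0,
                             hazard=np.vstack([params.hazard[0]] * 2))
        single = MixtureParams(gamma=np.zeros((1, 3)), beta=params.beta[:1],
                               sigma=8.0, hazard=params.hazard[:1])
        a = mixture_loglik(toy_cohort, same, membership_covariates=self.COVS)
        b = mixture_loglik(toy_cohort, single, membership_covariates=self.COVS)
        assert abs(a - b) < 1e-9

    def test_non_finite_parameters_rejected(self, toy_cohort):
        params = toy_params(K=2, p=len(self.COVS))
        params.beta[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mixture_loglik(toy_cohort, params, membership_covariates=self.COVS)


class TestEStep:
    COVS = ["age_at_event_months", "coma_days"]

    def test_identical_components_posterior_equals_prior(self, toy_cohort):
        gamma = np.array([[0.0, 0.0, 0.0], [0.7, 0.3, -0.4]])
        params = MixtureParams(gamma=gamma,
                               beta=np.array([[20.0, 3.0, -0.2]] * 2),
                               sigma=5.0, hazard=np.full((2, 7), 0.1))
        post = e_step(toy_cohort, params, membership_covariates=self.COVS)
        arr, _, _ = _prepare_arrays(toy_cohort, self.COVS, 2, "total",
                                    center=np.zeros(2), scale=np.ones(2))
        prior = membership_probs(gamma, arr.X)
        assert np.allclose(post, prior, atol=1e-12)

    def test_dominating_component_saturates(self, toy_cohort):
        params = toy_params(K=2, p=2)
        params.beta[1, 0] = 1e4  # absurd mean: component 2 impossible
        post = e_step(toy_cohort, params, membership_covariates=self.COVS)
        assert np.allclose(post[:, 0], 1.0)

    def test_two_class_bayes_hand_computation(self):
        cohort = make_toy_cohort(1, all_timepoints=False)
        covs = ["coma_days"]
        params = MixtureParams(
            gamma=np.array([[0.0, 0.0], [math.log(3.0), 0.0]]),  # prior 1:3
            beta=np.array([[20.0, 0.0, 0.0], [22.0, 0.0, 0.0]]),
            sigma=2.0, hazard=np.full((2, 7), 0.5))
        post = e_step(cohort, params, membership_covariates=covs)
        # subject T1: totals 20 at admission and ~20 at discharge
        sub = cohort.series[cohort.series["subject_id"] == "T1"]
        lls = []
        for k in range(2):
            ll = 0.0
            for _, row in sub.iterrows():
                t = 0.0 if row["timepoint"] == "admission" else 100 / 365.25
                mu = params.beta[k][0]
                ll += -0.5 * math.log(2 * math.pi * 4) - (row["total"] - mu) ** 2 / 8.0
            lls.append(ll)
        w1 = 0.25 * math.exp(lls[0])
        w2 = 0.75 * math.exp(lls[1])
        assert abs(post[0, 0] - w1 / (w1 + w2)) < 1e-12

    def test_rows_sum_to_one(self, fit_k4):
        assert np.allclose(fit_k4.posterior_.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    COVS = ["age_at_event_months", "coma_days"]

    def test_all_mass_on_one_class_is_single_class_ls(self, toy_cohort):
        n = toy_cohort.n_subjects
        post = np.column_stack([np.ones(n), np.zeros(n)])
        with pytest.raises(DegenerateClassError):
            m_step(toy_cohort, post, membership_covariates=self.COVS)
        post1 = np.ones((n, 1))
        params = m_step(toy_cohort, post1, membership_covariates=self.COVS)
        arr, _, _ = _prepare_arrays(toy_cohort, self.COVS, 2, "total",
                                    center=np.zeros(2), scale=np.ones(2))
        beta_ls, *_ = np.linalg.lstsq(arr.T, arr.y, rcond=None)
        assert np.allclose(params.beta[0], beta_ls, atol=1e-5)

    def test_noiseless_data_beta_exact_sigma_floored(self):
        # single-class noiseless cohort: every subject on the same quadratic
        specs = no_dropout([replace(two_class_specs()[0], prob=1.0)])
        cohort, truth = generate_cohort(noiseless_config(specs=specs,
                                                         n_subjects=12, seed=0))
        post = np.ones((cohort.n_subjects, 1))
        params = m_step(cohort, post, membership_covariates=self.COVS)
        beta_true = specs[0].beta
        assert np.allclose(params.beta[0], beta_true, atol=0.6)  # integer rounding
        assert params.sigma_vector()[0] < 0.5

    def test_symmetric_posterior_gives_equal_betas(self, toy_cohort):
        n = toy_cohort.n_subjects
        post = np.full((n, 2), 0.5)
        params = m_step(toy_cohort, post, membership_covariates=self.COVS)
        assert np.allclose(params.beta[0], params.beta[1], atol=1e-8)
        assert np.allclose(params.gamma[1], 0.0, atol=1e-6)


class TestFit:
    def test_refit_same_seed_is_identical(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=80, seed=5))
        kw = dict(n_classes=2, seed=3, n_starts=3)
        m1 = TrajectoryMixture(**kw).fit(cohort)
        m2 = TrajectoryMixture(**kw).fit(cohort)
        assert np.array_equal(m1.beta_, m2.beta_)
        assert m1.loglik_ == m2.loglik_
        assert np.array_equal(m1.posterior_, m2.posterior_)

    def test_noiseless_two_class_recovery_exact(self):
        specs = no_dropout(two_class_specs())
        cohort, truth = generate_cohort(noiseless_config(specs=specs,
                                                         n_subjects=60, seed=1))
        m = TrajectoryMixture(n_classes=2, seed=0, n_starts=3).fit(cohort)
        assert np.array_equal(m.labels_, truth.labels["true_class"].to_numpy())

    def test_em_loglik_monotone_within_fit(self, fit_k4):
        diffs = np.diff(fit_k4.loglik_path_)
        assert (diffs >= -1e-8).all()

    def test_canonical_order_ascending(self, fit_k4):
        assert (np.diff(fit_k4.trajectory_means_) > 0).all()
        assert fit_k4.endpoint_means_.argmin() == 0  # class 1 = floor level
        assert np.allclose(fit_k4.gamma_[0], 0.0)

    def test_marginal_probs_simplex(self, fit_k4):
        assert abs(fit_k4.marginal_probs_.sum() - 1.0) < 1e-9
        assert (fit_k4.marginal_probs_ > 0).all()

    def test_bic_formula(self, fit_k4):
        assert np.isclose(fit_k4.bic_,
                          -2 * fit_k4.loglik_ + fit_k4.n_params_ * np.log(600))

    def test_initial_label_permutation_invariance(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_subjects=60, seed=8))
        sel = ["age_at_event_months", "coma_days"]
        m = TrajectoryMixture(n_classes=2, seed=0, n_starts=1,
                              membership_covariates=sel)
        arr, _, _ = _prepare_arrays(cohort, sel, 2, "total")
        rng = np.random.default_rng(0)
        W0 = rng.dirichlet(np.ones(2), size=arr.n)
        out_a = m._run_em(arr, W0)
        out_b = m._run_em(arr, W0[:, ::-1])
        from trajstrata.mixture import _canonical_order, _relabel
        pa, wa = _relabel(out_a[0], out_a[1], _canonical_order(out_a[0], 2), False)
        pb, wb = _relabel(out_b[0], out_b[1], _canonical_order(out_b[0], 2), False)
        assert np.allclose(pa.beta, pb.beta, atol=1e-4)
        assert np.allclose(wa, wb, atol=1e-4)

    def test_parameter_recovery_over_seeds(self, screened):
        """Generating anchors, mixing proportions and membership-coefficient
        signs recovered across independent replicates."""
        sel = screened[0]
        probs_true = GeneratorConfig().class_probs
        sign_hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cohort, truth = generate_cohort(GeneratorConfig(seed=100 + seed))
            m = TrajectoryMixture(n_classes=4, seed=7, n_starts=5,
                                  membership_covariates=sel).fit(cohort)
            # anchors at t = 0, 1, 7 within 5 points of generating values
            for k, spec in enumerate(GeneratorConfig().classes):
                for t, a in zip((0.0, 1.0, 7.0), spec.anchors):
                    est = m.beta_[k] @ t ** np.arange(3)
                    assert abs(est - a) < 5.0
            counts = np.bincount(m.labels_, minlength=5)[1:]
            assert np.abs(counts / 600 - probs_true).max() < 0.05
            g = pd.DataFrame(m.gamma_[1:], columns=["icpt"] + list(sel))
            ok = ((g["age_at_event_months"] > 0).all()
                  and (g["coma_days"] < 0).all()
                  and (g["anoxic"] < 0).all()
                  and g.loc[0, "epilepsy"] < 0)
            sign_hits += ok
        assert sign_hits >= n_seeds - 1


class TestAssign:
    def test_training_cohort_assignment_idempotent(self, default_cohort, fit_k4):
        cohort, _ = default_cohort
        post = fit_k4.predict_proba(cohort)
        assert np.allclose(post, fit_k4.posterior_, atol=1e-10)
        labels = fit_k4.predict(cohort)
        assert np.array_equal(labels, fit_k4.labels_)

    def test_unseen_half_label_accuracy(self, screened):
        sel = screened[0]
        cohort, truth = generate_cohort(GeneratorConfig(seed=77))
        ids = cohort.subject_ids
        train, test = cohort.subset(ids[:300]), cohort.subset(ids[300:])
        m = TrajectoryMixture(n_classes=4, seed=7, n_starts=5,
                              membership_covariates=sel).fit(train)
        labels = m.predict(test)
        tc = truth.labels.set_index("subject_id")["true_class"].reindex(
            test.subject_ids).to_numpy()
        assert (labels == tc).mean() >= 0.9

    def test_missing_covariate_rejected(self, fit_k4, toy_cohort):
        broken = toy_cohort.covariates.drop(columns=["coma_days"])
        from trajstrata.cohort import Cohort
        bad = Cohort(broken, toy_cohort.series, toy_cohort.exits)
        with pytest.raises((ValueError, KeyError)):
            fit_k4.predict_proba(bad)


class TestBicScan:
    def test_n_params_strictly_increasing(self, default_cohort, screened):
        from trajstrata.mixture import bic_scan
        cohort, _ = default_cohort
        tab = bic_scan(cohort, class_range=(2, 3), seed=1, n_starts=2,
                       membership_covariates=screened[0])
        assert (tab["n_params"].diff().dropna() > 0).all()
        assert list(tab["K"]) == [2, 3]
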