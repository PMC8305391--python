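"""Shared fixtures: the default synthetic cohort, expensive fitted models
(session-scoped so the mixture is fitted once), and small hand-built toys."""

import numpy as np
import pandas as pd
import pytest

from trajstrata.cohort import Cohort, screen_covariates, validate_cohort
from trajstrata.mixture import TrajectoryMixture
from trajstrata.simulate import GeneratorConfig, generate_cohort
from trajstrata.validation import cross_design_labels

MASTER_SEED = 42


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition synthetic cohort (n=600) with truth."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=MASTER_SEED))
    return cohort, truth


@pytest.fixture(scope="session")
def screened(default_cohort):
    cohort, _ = default_cohort
    selected, report = screen_covariates(cohort.covariates)
    return selected, report


@pytest.fixture(scope="session")
def fit_k4(default_cohort, screened):
    cohort, _ = default_cohort
    selected, _ = screened
    return TrajectoryMixture(n_classes=4, seed=7, n_starts=10,
                             membership_covariates=selected).fit(cohort)


@pytest.fixture(scope="session")
def fit_k2(default_cohort, screened):
    cohort, _ = default_cohort
    selected, _ = screened
    return TrajectoryMixture(n_classes=2, seed=7, n_starts=10,
                             membership_covariates=selected).fit(cohort)


@pytest.fixture(scope="session")
def cross_labels_k4(default_cohort, screened):
    cohort, _ = default_cohort
    selected, _ = screened
    return cross_design_labels(cohort, 4, seed=3, n_starts=10,
                               membership_covariates=selected)


def make_toy_cohort(n_subjects=3, all_timepoints=True):
    """Tiny hand-built cohort: subject i follows total = 20 + 2i + 3t
    (rounded), fully observed, still in service."""
    from trajstrata.cohort import TIMEPOINTS
    from trajstrata.simulate import split_total
    cov_rows, ser_rows, exit_rows = [], [], []
    tps = TIMEPOINTS if all_timepoints else TIMEPOINTS[:2]
    for i in range(n_subjects):
        sid = f"T{i+1}"
        los = 100 + 10 * i
        cov_rows.append({
            "subject_id": sid, "gender": "M" if i % 2 == 0 else "F",
            "age_at_event_months": 60.0 + 10 * i, "etiology":
                ["traumatic", "anoxic", "other_nontraumatic"][i % 3],
            "age_at_admission_months": 62.0 + 10 * i, "los_days": los,
            "coma_days": 5 + i, "event_to_discharge_days": 60 + los,
            "dcn": bool(i % 2), "epilepsy": bool(i == 0),
        })
        for tp in tps:
            t = 0.0 if tp == "admission" else (
                los / 365.25 if tp == "discharge" else float(int(tp[1])))
            total = int(round(20 + 2 * i + 3 * t))
            sc, mo, cg = split_total(total)
            ser_rows.append({"subject_id": sid, "timepoint": tp, "total": total,
                             "selfcare": sc, "mobility": mo, "cognition": cg})
        exit_rows.append({"subject_id": sid,
                          "last_timepoint": tps[-1] if all_timepoints else "discharge",
                          "reason": "in_service" if all_timepoints else "censored"})
    cohort = Cohort(pd.DataFrame(cov_rows), pd.DataFrame(ser_rows),
                    pd.DataFrame(exit_rows))
    validate_cohort(cohort)
    return cohort


@pytest.fixture
def toy_cohort():
    return make_toy_cohort(3)
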