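"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a pediatric acquired-brain-injury
rehabilitation cohort: four latent recovery archetypes (non-responders,
slow responders, low-start fast responders, high-start fast responders,
stored in ascending order of the year-7 endpoint), covariate
distributions that differ by class with the sign pattern reported for
the clinical cohort (responders are older, had shorter coma, fewer
anoxic etiologies; high-start fast responders shorter stays; slow
responders less epilepsy), bounded noisy FIM observations around a
class-specific quadratic mean trajectory, and informative monotone
attrition through class-specific discrete-time exit hazards with a
reason mixture (death / exit-on-recovery / opt-out), plus administrative
censoring from staggered study entry.

Ground-truth class labels are returned alongside the cohort so that
recovery of the latent structure can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    Cohort, DOMAINS, FOLLOWUPS, N_INTERVALS, SCORE_BOUNDS, TIMEPOINTS,
    validate_cohort,
)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

#: fixed split of the total score over the three subscales, proportional
#: to their item counts (8/5/5 of 18 items).
DOMAIN_SHARES = np.array([8 / 18, 5 / 18, 5 / 18])


def _quad_from_anchors(a0: float, a1: float, a7: float) -> np.ndarray:
    """Quadratic coefficients (b0, b1, b2) through (0,a0), (1,a1), (7,a7)."""
    b2 = ((a7 - a0) - 7.0 * (a1 - a0)) / 42.0
    b1 = (a1 - a0) - b2
    return np.array([a0, b1, b2])


@dataclass
class ClassSpec:
    """Generating parameters for one latent trajectory class."""

    name: str
    prob: float
    #: total-FIM anchors at admission, year 1 and year 7; the class mean is
    #: the quadratic through them (kept inside [18, 126] on [0, 7]).
    anchors: tuple[float, float, float]
    age_mean: float            # months at event
    age_sd: float
    coma_median: float         # days; log-normal
    coma_sigma_log: float
    los_median: float          # days; log-normal
    los_sigma_log: float
    epilepsy_p: float
    anoxic_p: float
    other_nontraumatic_p: float
    dcn_p: float
    #: per-interval probability of leaving the service during years 1..7
    hazards: tuple[float, ...]
    #: mixture over exit reasons (death, recovery, opt_out) given an exit
    reason_probs: tuple[float, float, float]

    @property
    def beta(self) -> np.ndarray:
        return _quad_from_anchors(*self.anchors)


def default_class_specs() -> list[ClassSpec]:
    """Four archetypes in canonical order (ascending year-7 endpoint).

    Mixing proportions 35/22/28/15% for non-responders, slow, low-start
    fast and high-start fast responders. Hazards decline over time (long
    stayers are progressively less likely to drop out); exits on recovery
    concentrate in the high-functioning classes, opt-outs among slow and
    non-responders, deaths at a low rate.
    """
    return [
        ClassSpec("non_responder", 0.35, (18, 22, 28),
                  age_mean=65, age_sd=50, coma_median=70, coma_sigma_log=0.7,
                  los_median=140, los_sigma_log=0.40,
                  epilepsy_p=0.38, anoxic_p=0.50, other_nontraumatic_p=0.25, dcn_p=0.55,
                  hazards=(0.08, 0.07, 0.06, 0.05, 0.04, 0.04, 0.03),
                  reason_probs=(0.15, 0.05, 0.80)),
        ClassSpec("slow", 0.22, (25, 40, 85),
                  age_mean=95, age_sd=50, coma_median=35, coma_sigma_log=0.7,
                  los_median=120, los_sigma_log=0.40,
                  epilepsy_p=0.08, anoxic_p=0.15, other_nontraumatic_p=0.30, dcn_p=0.50,
                  hazards=(0.10, 0.09, 0.08, 0.06, 0.05, 0.04, 0.04),
                  reason_probs=(0.05, 0.10, 0.85)),
        ClassSpec("low_start_fast", 0.28, (30, 60, 115),
                  age_mean=105, age_sd=50, coma_median=12, coma_sigma_log=0.7,
                  los_median=105, los_sigma_log=0.40,
                  epilepsy_p=0.25, anoxic_p=0.08, other_nontraumatic_p=0.28, dcn_p=0.45,
                  hazards=(0.12, 0.11, 0.09, 0.08, 0.07, 0.06, 0.05),
                  reason_probs=(0.02, 0.68, 0.30)),
        ClassSpec("high_start_fast", 0.15, (85, 100, 118),
                  age_mean=112, age_sd=50, coma_median=4, coma_sigma_log=0.7,
                  los_median=75, los_sigma_log=0.40,
                  epilepsy_p=0.20, anoxic_p=0.05, other_nontraumatic_p=0.27, dcn_p=0.40,
                  hazards=(0.15, 0.13, 0.11, 0.09, 0.08, 0.07, 0.06),
                  reason_probs=(0.02, 0.80, 0.18)),
    ]


def two_class_specs() -> list[ClassSpec]:
    """A well-separated two-archetype configuration (responders vs
    non-responders) for model-selection and calibration studies."""
    specs = default_class_specs()
    non_resp = replace(specs[0], prob=0.5)
    resp = replace(specs[2], name="responder", prob=0.5)
    return [non_resp, resp]


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    ``sigma_obs`` is the residual SD of an observed total score around its
    class mean, in FIM points; ``visit_skip_p`` is the rate of intermittent
    missed follow-up visits (missing at random given class, never past the
    service-exit time); ``entry_span_years`` spreads study entry uniformly
    over a recruitment window, inducing administrative censoring of late
    entrants' long-term visits.
    """

    n_subjects: int = 600
    classes: list[ClassSpec] = field(default_factory=default_class_specs)
    sigma_obs: float = 6.0
    male_p: float = 0.612
    admission_delay_median: float = 43.0   # days from event to admission
    admission_delay_sigma_log: float = 0.5
    visit_skip_p: float = 0.05
    entry_span_years: float = 16.0
    seed: int = 42

    @property
    def class_probs(self) -> np.ndarray:
        return np.array([c.prob for c in self.classes])

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be non-negative")
        if not self.classes:
            raise ValueError("at least one class required")
        probs = self.class_probs
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("class probabilities must sum to 1")
        if (probs <= 0).any():
            raise ValueError("empty class (zero probability)")
        for spec in self.classes:
            h = np.asarray(spec.hazards, dtype=float)
            if len(h) != N_INTERVALS or ((h < 0) | (h > 1)).any():
                raise ValueError(f"class {spec.name}: hazards must be {N_INTERVALS} values in [0,1]")
            if abs(sum(spec.reason_probs) - 1.0) > 1e-9:
                raise ValueError(f"class {spec.name}: reason_probs must sum to 1")


@dataclass
class GroundTruth:
    """True class label per subject plus the generating configuration."""

    labels: pd.DataFrame  # subject_id, true_class (1-based, canonical order)
    config: GeneratorConfig


def split_total(total: int) -> tuple[int, int, int]:
    """Split a total score over (selfcare, mobility, cognition) in fixed
    item-count proportions using largest-remainder rounding; the parts sum
    to ``total`` exactly and respect the subscale bounds."""
    raw = DOMAIN_SHARES * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort plus ground-truth class labels.

    Per subject: class from the mixing proportions; covariates from the
    class-conditional distributions; a bounded, integer-rounded noisy
    observation of the class trajectory at admission, discharge (at
    LOS/365.25 years) and each yearly follow-up survived; service exit by
    the class hazard with a class-specific reason mixture, or
    administrative censoring at the subject's entry horizon.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = config.classes
    K = len(specs)
    lo, hi = SCORE_BOUNDS["total"]

    cov_rows, ser_rows, exit_rows, truth_rows = [], [], [], []
    labels = rng.choice(K, size=config.n_subjects, p=config.class_probs)
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        spec = specs[labels[i]]
        age_event = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 3.0, 216.0))
        age_event = round(age_event, 1)
        delay_days = int(round(rng.lognormal(np.log(config.admission_delay_median),
                                             config.admission_delay_sigma_log)))
        los = max(7, int(round(rng.lognormal(np.log(spec.los_median), spec.los_sigma_log))))
        coma = int(round(rng.lognormal(np.log(max(spec.coma_median, 0.5)), spec.coma_sigma_log)))
        eti_u = rng.random()
        if eti_u < spec.anoxic_p:
            etiology = "anoxic"
        elif eti_u < spec.anoxic_p + spec.other_nontraumatic_p:
            etiology = "other_nontraumatic"
        else:
            etiology = "traumatic"
        cov_rows.append({
            "subject_id": sid,
            "gender": "M" if rng.random() < config.male_p else "F",
            "age_at_event_months": age_event,
            "etiology": etiology,
            "age_at_admission_months": round(age_event + delay_days / DAYS_PER_MONTH, 1),
            "los_days": los,
            "coma_days": coma,
            "event_to_discharge_days": delay_days + los,
            "dcn": rng.random() < spec.dcn_p,
            "epilepsy": rng.random() < spec.epilepsy_p,
        })

        # service-exit process over yearly intervals; leaving (or being
        # censored) during interval j means the last in-service visit was
        # Y_{j-1} — timepoint index j — or discharge (index 1) when j == 1.
        if config.entry_span_years <= 0:  # censoring disabled
            horizon = N_INTERVALS
        else:
            horizon = min(N_INTERVALS, int(rng.uniform(0.0, config.entry_span_years)))
        reason = "in_service"
        last_tp_index = N_INTERVALS + 1  # Y7 if never exiting
        for j in range(1, N_INTERVALS + 1):
            if j > horizon:
                reason = "censored"
                last_tp_index = j
                break
            if rng.random() < spec.hazards[j - 1]:
                reason = ("death", "recovery", "opt_out")[
                    rng.choice(3, p=np.asarray(spec.reason_probs))]
                last_tp_index = j
                break
        last_tp = TIMEPOINTS[last_tp_index]
        exit_rows.append({"subject_id": sid, "last_timepoint": last_tp, "reason": reason})

        # observations: admission, discharge always; survived follow-ups
        beta = spec.beta
        t_disch = los / DAYS_PER_YEAR
        times = [("admission", 0.0), ("discharge", t_disch)]
        for k in range(1, last_tp_index):  # follow-ups Y1..Y_{last-1}... up to last visit
            times.append((FOLLOWUPS[k - 1], float(k)))
        for tp, t in times:
            if tp in FOLLOWUPS and rng.random() < config.visit_skip_p:
                continue  # intermittent missed visit
            mean = beta[0] + beta[1] * t + beta[2] * t * t
            total = int(round(np.clip(mean + rng.normal(0.0, config.sigma_obs), lo, hi)))
            sc, mo, cg = split_total(total)
            ser_rows.append({"subject_id": sid, "timepoint": tp, "total": total,
                             "selfcare": sc, "mobility": mo, "cognition": cg})
        truth_rows.append({"subject_id": sid, "true_class": int(labels[i]) + 1})

    cov = pd.DataFrame(cov_rows)
    ser = pd.DataFrame(ser_rows)
    ext = pd.DataFrame(exit_rows)
    cohort = Cohort(cov, ser, ext)
    validate_cohort(cohort)
    truth = GroundTruth(pd.DataFrame(truth_rows), config)
    return cohort, truth


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-timepoint descriptive table: median [IQR] of the total and each
    domain score, plus counts of missing visits and cumulative exit
    reasons — the layout of the study's descriptive follow-up table."""
    n = cohort.n_subjects
    from .cohort import TIMEPOINT_INDEX
    last_idx = cohort.exits.set_index("subject_id")["last_timepoint"].map(TIMEPOINT_INDEX)
    reasons = cohort.exits.set_index("subject_id")["reason"]
    rows = []
    for tp_i, tp in enumerate(TIMEPOINTS):
        at_tp = cohort.series[cohort.series["timepoint"] == tp]
        row: dict[str, object] = {"timepoint": tp, "n_observed": len(at_tp)}
        for col in ("total",) + DOMAINS:
            if len(at_tp):
                q1, med, q3 = np.percentile(at_tp[col], [25, 50, 75])
                row[f"{col}_median"] = med
                row[f"{col}_iqr"] = f"[{q1:g}; {q3:g}]"
            else:
                row[f"{col}_median"] = np.nan
                row[f"{col}_iqr"] = ""
        row["missing"] = int(n - len(at_tp)) if tp_i >= 2 else 0
        for reason in ("death", "recovery", "opt_out", "censored"):
            # exited for this reason with last visit strictly before tp
            row[reason] = int(((reasons == reason) & (last_idx < tp_i)).sum()) if tp_i >= 2 else 0
        rows.append(row)
    return pd.DataFrame(rows)
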