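"""Cohort data model, long-format CSV I/O, and covariate screening.

A cohort couples three tables keyed by ``subject_id``:

``covariates``
    one row per subject: demographics and acute-phase clinical variables
    (gender, age at event/admission in months, etiology, length of stay,
    days of coma, event-to-discharge interval, decompressive
    craniotomy/neurosurgery flag, epilepsy flag).
``series``
    one row per functional assessment: total FIM/WeeFIM score plus the
    three domain scores (selfcare, mobility, cognition) at up to nine
    timepoints (admission, discharge, yearly follow-ups Y1..Y7).
``exits``
    one row per subject recording the last timepoint in service and the
    reason observation ended (still in service, death, exit on recovery,
    opt-out, or administratively censored).

Scores are bounded: total 18-126, selfcare 8-56, mobility 5-35,
cognition 5-35, and the three domains always sum to the total. Missing
follow-up visits are absent rows, never sentinel values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

TIMEPOINTS: tuple[str, ...] = (
    "admission", "discharge", "Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "Y7",
)
TIMEPOINT_INDEX: dict[str, int] = {tp: i for i, tp in enumerate(TIMEPOINTS)}
FOLLOWUPS: tuple[str, ...] = TIMEPOINTS[2:]
N_INTERVALS = len(FOLLOWUPS)  # yearly intervals at risk of service exit

EXIT_REASONS: tuple[str, ...] = ("in_service", "death", "recovery", "opt_out", "censored")
#: reasons that mean the subject actively left the service (an exit event);
#: ``censored``/``in_service`` only contribute survival information.
EVENT_REASONS: frozenset[str] = frozenset({"death", "recovery", "opt_out"})

ETIOLOGIES: tuple[str, ...] = ("traumatic", "anoxic", "other_nontraumatic")

SCORE_BOUNDS: dict[str, tuple[int, int]] = {
    "total": (18, 126),
    "selfcare": (8, 56),
    "mobility": (5, 35),
    "cognition": (5, 35),
}
DOMAINS: tuple[str, ...] = ("selfcare", "mobility", "cognition")

COVARIATE_COLUMNS = [
    "subject_id", "gender", "age_at_event_months", "etiology",
    "age_at_admission_months", "los_days", "coma_days",
    "event_to_discharge_days", "dcn", "epilepsy",
]
SERIES_COLUMNS = ["subject_id", "timepoint", "total", "selfcare", "mobility", "cognition"]
EXIT_COLUMNS = ["subject_id", "last_timepoint", "reason"]

#: order in which the study listed its screened covariates; used as the
#: default retention priority when a correlated pair must be broken.
DEFAULT_KEEP_PRIORITY = [
    "gender", "age_at_event_months", "anoxic", "other_nontraumatic",
    "age_at_admission_months", "los_days", "coma_days", "dcn", "epilepsy",
]


class CohortSchemaError(ValueError):
    """A required column or file is missing."""


class CohortValidationError(ValueError):
    """A row violates a cohort invariant; message names subject and rule."""


@dataclass
class Cohort:
    """Validated container for a longitudinal functional-recovery cohort."""

    covariates: pd.DataFrame
    series: pd.DataFrame
    exits: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def validate(self) -> "Cohort":
        validate_cohort(self)
        return self

    def subset(self, subject_ids) -> "Cohort":
        """Row-subset all three tables to ``subject_ids`` (order preserved)."""
        ids = list(subject_ids)
        order = {s: i for i, s in enumerate(ids)}
        cov = self.covariates[self.covariates["subject_id"].isin(order)].copy()
        cov = cov.sort_values("subject_id", key=lambda s: s.map(order), kind="stable")
        ser = self.series[self.series["subject_id"].isin(order)].copy()
        ext = self.exits[self.exits["subject_id"].isin(order)].copy()
        return Cohort(cov.reset_index(drop=True), ser.reset_index(drop=True),
                      ext.reset_index(drop=True))

    def equals(self, other: "Cohort") -> bool:
        return (
            self.covariates.reset_index(drop=True).equals(other.covariates.reset_index(drop=True))
            and self.series.reset_index(drop=True).equals(other.series.reset_index(drop=True))
            and self.exits.reset_index(drop=True).equals(other.exits.reset_index(drop=True))
        )


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{name}: missing required column(s) {missing}")


def validate_cohort(cohort: Cohort) -> None:
    """Enforce every cohort invariant; raise with subject id and rule on failure."""
    cov, ser, ext = cohort.covariates, cohort.series, cohort.exits
    _require_columns(cov, COVARIATE_COLUMNS, "covariates")
    _require_columns(ser, SERIES_COLUMNS, "series")
    _require_columns(ext, EXIT_COLUMNS, "exits")

    ids = set(cov["subject_id"])
    if len(ids) != len(cov):
        dup = cov["subject_id"][cov["subject_id"].duplicated()].iloc[0]
        raise CohortValidationError(f"subject {dup}: duplicate covariate row")
    if set(ser["subject_id"]) - ids or set(ext["subject_id"]) != ids:
        raise CohortValidationError("covariates, series and exits must share one subject_id key set")
    if len(cov) and set(ser["subject_id"]) != ids:
        raise CohortValidationError("covariates, series and exits must share one subject_id key set")

    bad_gender = ~cov["gender"].isin(["M", "F"])
    if bad_gender.any():
        sid = cov.loc[bad_gender, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: gender must be M or F")
    bad_eti = ~cov["etiology"].isin(ETIOLOGIES)
    if bad_eti.any():
        sid = cov.loc[bad_eti, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: unknown etiology")
    for col, rule in [
        ("age_at_event_months", cov["age_at_event_months"] < 0),
        ("age_at_admission_months", cov["age_at_admission_months"] < cov["age_at_event_months"]),
        ("los_days", cov["los_days"] <= 0),
        ("coma_days", cov["coma_days"] < 0),
        ("event_to_discharge_days", cov["event_to_discharge_days"] < 0),
    ]:
        if rule.any():
            sid = cov.loc[rule, "subject_id"].iloc[0]
            raise CohortValidationError(f"subject {sid}: invalid {col}")

    bad_tp = ~ser["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        sid = ser.loc[bad_tp, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: unknown timepoint")
    dup = ser.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        sid = ser.loc[dup, "subject_id"].iloc[0]
        tp = ser.loc[dup, "timepoint"].iloc[0]
        raise CohortValidationError(f"subject {sid}: duplicate row at timepoint {tp}")

    for col, (lo, hi) in SCORE_BOUNDS.items():
        below = ser[col] < lo
        if below.any():
            sid = ser.loc[below, "subject_id"].iloc[0]
            raise CohortValidationError(
                f"subject {sid}: {col} below scale floor {lo}")
        above = ser[col] > hi
        if above.any():
            sid = ser.loc[above, "subject_id"].iloc[0]
            raise CohortValidationError(
                f"subject {sid}: {col} above scale ceiling {hi}")
    mismatch = ser["total"] != ser[DOMAINS[0]] + ser[DOMAINS[1]] + ser[DOMAINS[2]]
    if mismatch.any():
        sid = ser.loc[mismatch, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: domain sum mismatch")

    # admission and discharge always observed
    for tp in ("admission", "discharge"):
        have = set(ser.loc[ser["timepoint"] == tp, "subject_id"])
        lacking = ids - have
        if lacking:
            sid = sorted(lacking)[0]
            raise CohortValidationError(f"subject {sid}: missing {tp} observation")

    bad_reason = ~ext["reason"].isin(EXIT_REASONS)
    if bad_reason.any():
        sid = ext.loc[bad_reason, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: unknown exit reason")
    bad_last = ~ext["last_timepoint"].isin(TIMEPOINTS)
    if bad_last.any():
        sid = ext.loc[bad_last, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: unknown last_timepoint")

    # no observation after the recorded service exit
    last = ext.set_index("subject_id")["last_timepoint"].map(TIMEPOINT_INDEX)
    obs_idx = ser["timepoint"].map(TIMEPOINT_INDEX)
    too_late = obs_idx.to_numpy() > last.reindex(ser["subject_id"]).to_numpy()
    if too_late.any():
        sid = ser.loc[too_late, "subject_id"].iloc[0]
        raise CohortValidationError(f"subject {sid}: observation after last_timepoint")


def _sort_series(ser: pd.DataFrame) -> pd.DataFrame:
    ser = ser.copy()
    ser["_tp"] = ser["timepoint"].map(TIMEPOINT_INDEX)
    ser = ser.sort_values(["subject_id", "_tp"], kind="stable").drop(columns="_tp")
    return ser.reset_index(drop=True)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort from ``covariates.csv``, ``fim_long.csv``,
    ``exits.csv`` under directory ``path``; timepoints come back ordered."""
    path = Path(path)
    for fname in ("covariates.csv", "fim_long.csv", "exits.csv"):
        if not (path / fname).exists():
            raise CohortSchemaError(f"missing cohort file {path / fname}")
    cov = pd.read_csv(path / "covariates.csv", dtype={"subject_id": str})
    ser = pd.read_csv(path / "fim_long.csv", dtype={"subject_id": str})
    ext = pd.read_csv(path / "exits.csv", dtype={"subject_id": str})
    _require_columns(cov, COVARIATE_COLUMNS, "covariates.csv")
    _require_columns(ser, SERIES_COLUMNS, "fim_long.csv")
    _require_columns(ext, EXIT_COLUMNS, "exits.csv")
    cov = cov[COVARIATE_COLUMNS].copy()
    for col in ("dcn", "epilepsy"):
        cov[col] = cov[col].astype(int).astype(bool)
    for col in ("los_days", "coma_days", "event_to_discharge_days"):
        cov[col] = cov[col].astype(int)
    for col in ("age_at_event_months", "age_at_admission_months"):
        cov[col] = cov[col].astype(float)
    ser = ser[SERIES_COLUMNS].copy()
    for col in SCORE_BOUNDS:
        ser[col] = ser[col].astype(int)
    ser = _sort_series(ser)
    ext = ext[EXIT_COLUMNS].copy()
    cohort = Cohort(cov.reset_index(drop=True), ser, ext.reset_index(drop=True))
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> dict[str, Path]:
    """Write the three cohort CSVs under directory ``path`` (lossless:
    ``read_cohort(write_cohort(c))`` reproduces ``c``)."""
    validate_cohort(cohort)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cov = cohort.covariates.copy()
    for col in ("dcn", "epilepsy"):
        cov[col] = cov[col].astype(int)
    files = {
        "covariates": path / "covariates.csv",
        "series": path / "fim_long.csv",
        "exits": path / "exits.csv",
    }
    cov.to_csv(files["covariates"], index=False)
    _sort_series(cohort.series).to_csv(files["series"], index=False)
    cohort.exits.to_csv(files["exits"], index=False)
    return files


def encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric design table: gender M=0/F=1, etiology one-hot vs traumatic,
    booleans as 0/1; indexed like ``cov``."""
    out = pd.DataFrame(index=cov.index)
    out["gender"] = (cov["gender"] == "F").astype(float)
    out["age_at_event_months"] = cov["age_at_event_months"].astype(float)
    out["anoxic"] = (cov["etiology"] == "anoxic").astype(float)
    out["other_nontraumatic"] = (cov["etiology"] == "other_nontraumatic").astype(float)
    out["age_at_admission_months"] = cov["age_at_admission_months"].astype(float)
    out["los_days"] = cov["los_days"].astype(float)
    out["coma_days"] = cov["coma_days"].astype(float)
    out["dcn"] = cov["dcn"].astype(float)
    out["epilepsy"] = cov["epilepsy"].astype(float)
    return out


def screen_covariates(
    covariates: pd.DataFrame,
    rho_max: float = 0.5,
    alpha: float = 0.01,
    keep_priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Spearman-based redundancy screen.

    Retains a covariate set such that no retained pair is both strongly
    correlated (|r| >= ``rho_max``) and significant at Bonferroni-corrected
    level ``alpha``; of a conflicting pair, the covariate earlier in
    ``keep_priority`` survives. Accepts either a raw covariate table (with
    ``gender``/``etiology`` columns, encoded internally) or an
    already-numeric table. Returns ``(selected, report)`` where ``report``
    lists every tested pair with r, raw and corrected p-values.
    """
    if "etiology" in covariates.columns:
        num = encode_covariates(covariates)
    else:
        num = covariates.drop(columns=[c for c in ("subject_id",) if c in covariates.columns])
        num = num.astype(float)
    if len(num) < 3:
        raise ValueError("screening needs at least 3 subjects")

    cols = list(num.columns)
    constant = [c for c in cols if num[c].nunique() <= 1]
    if constant:
        warnings.warn(f"excluding zero-variance covariate(s): {constant}")
        cols = [c for c in cols if c not in constant]

    priority = list(keep_priority) if keep_priority is not None else list(DEFAULT_KEEP_PRIORITY)
    priority += [c for c in cols if c not in priority]
    cols = sorted(cols, key=priority.index)

    pairs = list(itertools.combinations(cols, 2))
    m = len(pairs)
    rows = []
    conflict: dict[str, set[str]] = {c: set() for c in cols}
    for a, b in pairs:
        r, p = stats.spearmanr(num[a], num[b])
        if np.isnan(r):  # ties-only degenerate pair
            r, p = 0.0, 1.0
        p_corr = min(1.0, p * m)
        violates = (abs(r) >= rho_max) and (p_corr < alpha)
        rows.append({"var_a": a, "var_b": b, "spearman_r": r,
                     "p_raw": p, "p_bonferroni": p_corr, "conflict": violates})
        if violates:
            conflict[a].add(b)
            conflict[b].add(a)

    selected: list[str] = []
    for c in cols:  # priority order
        if not any(s in conflict[c] for s in selected):
            selected.append(c)
    report = pd.DataFrame(rows)
    return selected, report
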