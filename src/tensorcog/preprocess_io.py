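"""Longitudinal cohort I/O and preprocessing.

The package starts from FreeSurfer-style tabular MRI features: one row per
(patient, visit) with a patient identifier, a visit code (BL, M06, M12, M24),
the exam date, a diagnosis group (AD / MCI / CN) and ``d`` biomarker columns
(regional volumes in mm^3, surface areas in mm^2, cortical thickness mean/SD
in mm). Cognitive targets (MMSE or ADAS-Cog) live in a separate per-patient
table over the prediction horizon M12..M48.

The preprocessing rules implemented here: drop features missing in more than
half of the rows, keep only patients with both BL and M06 scans (and, for the
dynamic-prediction workflow, all requested follow-up scans), mean-impute the
remaining gaps, and drop patients with incomplete cognitive follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VISIT_MONTHS",
    "TIME_POINTS",
    "BIOMARKER_CATEGORIES",
    "SCORE_RANGES",
    "SchemaError",
    "IntegrityError",
    "EmptyDataError",
    "LongitudinalCohort",
    "ScoreTable",
    "load_cohort",
    "load_scores",
    "filter_features",
    "filter_patients_baseline",
    "filter_patients_followup_mri",
    "impute_mean",
    "filter_score_followups",
]

#: Nominal month offset of each MRI visit code from the first screening.
VISIT_MONTHS = {"BL": 0, "M06": 6, "M12": 12, "M24": 24}

#: Cognitive-score prediction horizon.
TIME_POINTS = ("M12", "M24", "M36", "M48")

#: FreeSurfer feature categories: cortical volume, white-matter volume,
#: surface area, thickness average, thickness standard deviation.
BIOMARKER_CATEGORIES = ("CV", "SV", "SA", "TA", "TS")

SCORE_RANGES = {"MMSE": (0.0, 30.0), "ADAS-Cog": (0.0, 70.0)}


class SchemaError(ValueError):
    """A mandatory column is absent or mis-mapped."""


class IntegrityError(ValueError):
    """The table violates a cohort invariant (duplicates, bad dates)."""


class EmptyDataError(ValueError):
    """An operation would leave no usable rows or features."""


@dataclass(frozen=True)
class LongitudinalCohort:
    """Per-(patient, visit) biomarker measurements.

    ``data`` holds the metadata columns ``patient_id``, ``visit_code``,
    ``exam_date``, ``group`` followed by one column per biomarker; missing
    biomarker cells are NaN. ``categories`` optionally tags each biomarker
    with its FreeSurfer category.
    """

    data: pd.DataFrame
    biomarker_names: tuple[str, ...]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"patient_id", "visit_code", "exam_date", "group"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"cohort table lacks columns {sorted(missing)}")
        dup = self.data.duplicated(subset=["patient_id", "visit_code"])
        if dup.any():
            pairs = self.data.loc[dup, ["patient_id", "visit_code"]].to_records(index=False)
            raise IntegrityError(f"duplicate (patient, visit) rows: {list(pairs)[:5]}")
        self._check_date_order()

    def _check_date_order(self) -> None:
        df = self.data.dropna(subset=["exam_date"])
        order = df["visit_code"].map(VISIT_MONTHS)
        for pid, grp in df.assign(_ord=order).groupby("patient_id", sort=False):
            grp = grp.sort_values("_ord")
            dates = pd.to_datetime(grp["exam_date"]).to_numpy()
            if len(dates) > 1 and not (np.diff(dates) > np.timedelta64(0, "s")).all():
                raise IntegrityError(f"exam dates not increasing with visit order for {pid!r}")

    # -- convenience views ------------------------------------------------
    @property
    def patients(self) -> list:
        seen: dict = {}
        for pid in self.data["patient_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def d(self) -> int:
        return len(self.biomarker_names)

    def visit_frame(self, visit_code: str) -> pd.DataFrame:
        """Rows of one visit, indexed by patient."""
        sub = self.data[self.data["visit_code"] == visit_code]
        return sub.set_index("patient_id")

    def patients_with_visits(self, visits) -> list:
        """Patients having a row for every visit code in ``visits``."""
        visits = set(visits)
        have = self.data.groupby("patient_id", sort=False)["visit_code"].agg(set)
        return [pid for pid in self.patients if visits <= have[pid]]


@dataclass(frozen=True)
class ScoreTable:
    """Cognitive scores per patient over the prediction horizon.

    ``scores`` is wide: one row per patient, one column per time point
    (M12..M48), NaN = missing assessment.
    """

    scores: pd.DataFrame
    kind: str = "MMSE"

    def __post_init__(self) -> None:
        bad = [c for c in self.scores.columns if c not in TIME_POINTS]
        if bad:
            raise SchemaError(f"unknown score time points {bad}; expected {TIME_POINTS}")
        lo, hi = SCORE_RANGES.get(self.kind, (-np.inf, np.inf))
        vals = self.scores.to_numpy(dtype=float)
        out = (vals < lo) | (vals > hi)
        if np.nansum(out):
            warnings.warn(
                f"{int(np.nansum(out))} {self.kind} scores outside [{lo}, {hi}]; "
                "values are kept as-is",
                stacklevel=2,
            )

    @property
    def time_points(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    def matrix(self, patient_ids) -> np.ndarray:
        """(n, t) float matrix aligned to ``patient_ids``; NaN = missing."""
        return self.scores.reindex(patient_ids).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# loading


def load_cohort(path, schema: dict | None = None, biomarkers=None) -> LongitudinalCohort:
    """Read a delimited cohort table.

    ``schema`` maps the canonical names ``patient_id``, ``visit_code``,
    ``exam_date``, ``group`` to the file's column names; all unmapped columns
    are taken as biomarkers unless ``biomarkers`` lists them explicitly.
    Unparseable dates become NaT and are reported with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise EmptyDataError(f"no rows in {path}")
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    absent = [v for v in schema.values() if v not in df.columns]
    if absent:
        raise SchemaError(f"mapped columns {absent} not present in {path}")
    df = df.rename(columns=rename)
    required = ["patient_id", "visit_code", "exam_date", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file lacks mandatory columns {missing}")
    parsed = pd.to_datetime(df["exam_date"], errors="coerce", format="mixed")
    bad = parsed.isna() & df["exam_date"].notna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} unparseable exam dates set to missing", stacklevel=2)
    df["exam_date"] = parsed
    if biomarkers is None:
        biomarkers = [c for c in df.columns if c not in required]
    df[list(biomarkers)] = df[list(biomarkers)].apply(pd.to_numeric, errors="coerce")
    order = df["visit_code"].map(VISIT_MONTHS)
    df = df.assign(_ord=order).sort_values(["patient_id", "_ord"]).drop(columns="_ord")
    df = df.reset_index(drop=True)
    return LongitudinalCohort(df[required + list(biomarkers)], tuple(biomarkers))


def load_scores(path, kind: str = "MMSE", schema: dict | None = None) -> ScoreTable:
    """Read a long score table with columns patient_id, time_point, score."""
    df = pd.read_csv(path, sep=None, engine="python")
    schema = dict(schema or {})
    df = df.rename(columns={v: k for k, v in schema.items()})
    for col in ("patient_id", "time_point", "score"):
        if col not in df.columns:
            raise SchemaError(f"score file lacks column {col!r}")
    wide = df.pivot_table(index="patient_id", columns="time_point", values="score", aggfunc="first")
    wide = wide.reindex(columns=[tp for tp in TIME_POINTS if tp in wide.columns])
    return ScoreTable(wide, kind=kind)


# ---------------------------------------------------------------------------
# filtering / imputation


def filter_features(cohort: LongitudinalCohort, max_missing_fraction: float = 0.5) -> LongitudinalCohort:
    """Drop biomarkers whose missing fraction strictly exceeds the threshold.

    The default 0.5 drops features missing in more than half of the rows;
    a feature missing in exactly half is kept.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = cohort.data[list(cohort.biomarker_names)].isna().mean()
    kept = [b for b in cohort.biomarker_names if frac[b] <= max_missing_fraction]
    if not kept:
        raise EmptyDataError("all biomarkers exceed the missingness threshold")
    meta = ["patient_id", "visit_code", "exam_date", "group"]
    cats = {b: c for b, c in cohort.categories.items() if b in kept}
    return LongitudinalCohort(cohort.data[meta + kept].copy(), tuple(kept), cats)


def _keep_patients(cohort: LongitudinalCohort, keep) -> LongitudinalCohort:
    keep = set(keep)
    df = cohort.data[cohort.data["patient_id"].isin(keep)].reset_index(drop=True)
    return replace(cohort, data=df)


def filter_patients_baseline(cohort: LongitudinalCohort) -> LongitudinalCohort:
    """Keep only patients that have both a BL and an M06 scan."""
    keep = cohort.patients_with_visits({"BL", "M06"})
    if not keep:
        warnings.warn("no patient has both BL and M06 scans", stacklevel=2)
    return _keep_patients(cohort, keep)


def filter_patients_followup_mri(cohort: LongitudinalCohort, required_visits) -> LongitudinalCohort:
    """Keep only patients with every visit in ``required_visits`` (dynamic prediction)."""
    bad = set(required_visits) - set(VISIT_MONTHS)
    if bad:
        raise ValueError(f"unknown visit codes {sorted(bad)}")
    return _keep_patients(cohort, cohort.patients_with_visits(required_visits))


def impute_mean(cohort: LongitudinalCohort, stratify_by_visit: bool = False) -> LongitudinalCohort:
    """Fill missing biomarker cells with the feature's mean over observed rows.

    By default the mean pools all retained rows across visits and diagnosis
    groups; ``stratify_by_visit`` computes per-visit means instead. A feature
    with no observed value at all cannot be imputed and raises.
    """
    cols = list(cohort.biomarker_names)
    df = cohort.data.copy()
    all_missing = [b for b in cols if df[b].isna().all()]
    if all_missing:
        raise EmptyDataError(f"features with no observed values: {all_missing[:5]}")
    if stratify_by_visit:
        df[cols] = df.groupby("visit_code")[cols].transform(lambda s: s.fillna(s.mean()))
        df[cols] = df[cols].fillna(df[cols].mean())  # visits with no observation fall back to pooled
    else:
        df[cols] = df[cols].fillna(df[cols].mean())
    return replace(cohort, data=df)


def filter_score_followups(scores: ScoreTable, required_points) -> ScoreTable:
    """Drop patients missing any required follow-up assessment."""
    required = [tp for tp in TIME_POINTS if tp in set(required_points)]
    if set(required_points) - set(TIME_POINTS):
        raise ValueError(f"unknown time points {sorted(set(required_points) - set(TIME_POINTS))}")
    if not required:
        return scores
    present = [tp for tp in required if tp in scores.scores.columns]
    if len(present) < len(required):
        return ScoreTable(scores.scores.iloc[0:0], kind=scores.kind)
    ok = scores.scores[required].notna().all(axis=1)
    return ScoreTable(scores.scores[ok], kind=scores.kind)
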