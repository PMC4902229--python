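"""Analysis dataset container, CSV loading and cohort description.

An :class:`AnalysisDataset` joins one-row-per-subject records (clinical
covariates plus morphometry) to one-row-per-visit longitudinal eGFR
measurements.  Loading is complete-case: subjects missing any mapped
covariate are dropped and counted, mirroring how observational-cohort
models are usually restricted to subjects with full baseline data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError, UndefinedResultError

__all__ = [
    "AnalysisDataset",
    "CohortSummary",
    "load_cohort_csv",
    "summarize_cohort",
]

#: canonical -> source column names; identity unless overridden in config
DEFAULT_COLUMN_MAP = {
    "subject_id": "subject_id",
    "time": "time",
    "egfr": "egfr",
}

VISIT_COLUMNS = ("subject_id", "time", "egfr")


@dataclass
class AnalysisDataset:
    """Subjects x covariates joined to repeated (time, eGFR) visits."""

    subjects: pd.DataFrame            # indexed by subject_id
    visits: pd.DataFrame              # columns subject_id, time, egfr
    provenance: str = "unknown"
    n_dropped: int = 0

    def __post_init__(self):
        missing_cols = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing_cols:
            raise SchemaError(f"visit table missing column(s): {missing_cols}")
        unknown = set(self.visits["subject_id"]) - set(self.subjects.index)
        if unknown:
            raise SchemaError(
                f"visits reference unknown subject(s): {sorted(unknown)[:5]}"
            )
        if (self.visits["time"] < 0).any():
            raise InvalidParameterError("visit times must be nonnegative")
        have_baseline = set(
            self.visits.loc[self.visits["time"] == 0, "subject_id"]
        )
        missing_baseline = set(self.subjects.index) - have_baseline
        if missing_baseline:
            raise SchemaError(
                f"subject(s) without a time-0 visit: {sorted(missing_baseline)[:5]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def joined(self) -> pd.DataFrame:
        """Long format: one row per visit with subject columns attached."""
        return self.visits.merge(
            self.subjects, left_on="subject_id", right_index=True, how="left"
        )

    def drop_subjects(self, subject_ids) -> "AnalysisDataset":
        keep = ~self.subjects.index.isin(list(subject_ids))
        subjects = self.subjects[keep]
        visits = self.visits[self.visits["subject_id"].isin(subjects.index)]
        return AnalysisDataset(
            subjects=subjects, visits=visits.reset_index(drop=True),
            provenance=self.provenance,
            n_dropped=self.n_dropped + int((~keep).sum()),
        )

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "subjects.csv")
        self.visits.to_csv(directory / "visits.csv", index=False)


def _apply_map(frame: pd.DataFrame, column_map: dict) -> pd.DataFrame:
    rename = {src: dst for dst, src in column_map.items() if src in frame.columns}
    return frame.rename(columns=rename)


def load_cohort_csv(
    path: str | Path,
    column_map: dict | None = None,
    required_covariates=(),
    exclude_subjects=(),
    provenance: str | None = None,
) -> AnalysisDataset:
    """Load an analysis dataset from CSV.

    ``path`` may be a directory containing ``subjects.csv`` and
    ``visits.csv`` (the generator's tidy layout) or a single long-format
    CSV in which subject-level columns are repeated on every visit row.
    ``column_map`` maps canonical names (``subject_id``, ``time``,
    ``egfr``, covariates) to the file's header names.  Subjects with a
    missing value in any ``required_covariates`` column are dropped and
    counted (complete-case); ``exclude_subjects`` removes listed ids
    (e.g. a subject who reached end-stage disease before follow-up).
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if path.is_dir():
        subjects = _apply_map(pd.read_csv(path / "subjects.csv"), cmap)
        visits = _apply_map(pd.read_csv(path / "visits.csv"), cmap)
    elif path.exists():
        long = _apply_map(pd.read_csv(path), cmap)
        missing = [c for c in VISIT_COLUMNS if c not in long.columns]
        if missing:
            raise SchemaError(f"input file missing mapped column(s): {missing}")
        visits = long[list(VISIT_COLUMNS)].copy()
        subject_cols = [c for c in long.columns if c not in ("time", "egfr")]
        subjects = long[subject_cols].drop_duplicates("subject_id")
    else:
        raise FileNotFoundError(path)

    for frame, cols in ((subjects, ("subject_id",)), (visits, VISIT_COLUMNS)):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mapped column(s): {missing}")
    bad = pd.to_numeric(visits["egfr"], errors="coerce").isna() & visits["egfr"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"non-numeric eGFR value at visit row {row}")
    visits = visits.dropna(subset=["egfr", "time"])
    visits["time"] = visits["time"].astype(float)
    visits["egfr"] = visits["egfr"].astype(float)

    subjects = subjects.set_index("subject_id")
    n_before = len(subjects)
    if exclude_subjects:
        subjects = subjects[~subjects.index.isin(list(exclude_subjects))]
    check_cols = [c for c in required_covariates if c in subjects.columns]
    missing_req = [c for c in required_covariates if c not in subjects.columns]
    if missing_req:
        raise SchemaError(f"required covariate column(s) absent: {missing_req}")
    if check_cols:
        subjects = subjects.dropna(subset=check_cols)
    visits = visits[visits["subject_id"].isin(subjects.index)].reset_index(drop=True)
    return AnalysisDataset(
        subjects=subjects,
        visits=visits,
        provenance=provenance or str(path),
        n_dropped=n_before - len(subjects),
    )


@dataclass
class CohortSummary:
    """Descriptive statistics of an analysis dataset."""

    n_subjects: int
    cohort_counts: dict
    race_proportions: dict = field(default_factory=dict)
    female_proportion: float = float("nan")
    pediatric_proportion: float = float("nan")
    baseline_egfr_median: float = float("nan")
    baseline_egfr_iqr: tuple = (float("nan"), float("nan"))
    followup_median: float = float("nan")
    followup_range: tuple = (float("nan"), float("nan"))
    egfr_slope_per_year: float = float("nan")
    visits_per_year_median: float = float("nan")


def summarize_cohort(dataset: AnalysisDataset) -> CohortSummary:
    """Medians/IQRs, composition and the pooled eGFR time slope.

    The pooled slope is the OLS slope of eGFR on time over all visit
    rows, expressed per year; quantiles use linear interpolation.
    """
    if len(dataset.visits) == 0:
        raise UndefinedResultError("dataset has no visits")
    subj = dataset.subjects
    visits = dataset.visits

    baseline = visits.loc[visits["time"] == 0].set_index("subject_id")["egfr"]
    q25, q50, q75 = np.quantile(baseline.to_numpy(), [0.25, 0.5, 0.75])

    followup = visits.groupby("subject_id")["time"].max()
    t = visits["time"].to_numpy(dtype=float)
    y = visits["egfr"].to_numpy(dtype=float)
    slope_per_month = np.polyfit(t, y, 1)[0] if len(np.unique(t)) > 1 else float("nan")

    with_followup = followup[followup > 0]
    n_visits = visits.groupby("subject_id").size()
    vpy = (
        (n_visits[with_followup.index] - 1) / (with_followup / 12.0)
    ).to_numpy() if len(with_followup) else np.array([])

    cohort_counts = (
        subj["cohort"].value_counts().to_dict() if "cohort" in subj.columns else {}
    )
    race_props = (
        subj["race"].value_counts(normalize=True).to_dict()
        if "race" in subj.columns else {}
    )
    return CohortSummary(
        n_subjects=len(subj),
        cohort_counts=cohort_counts,
        race_proportions=race_props,
        female_proportion=(
            float(subj["female"].astype(bool).mean()) if "female" in subj.columns
            else float("nan")
        ),
        pediatric_proportion=(
            float((subj["age"] < 18).mean()) if "age" in subj.columns else float("nan")
        ),
        baseline_egfr_median=float(q50),
        baseline_egfr_iqr=(float(q25), float(q75)),
        followup_median=float(followup.median()),
        followup_range=(float(followup.min()), float(followup.max())),
        egfr_slope_per_year=float(slope_per_month * 12.0),
        visits_per_year_median=float(np.median(vpy)) if len(vpy) else float("nan"),
    )
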