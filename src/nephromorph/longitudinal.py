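"""Model specification, predictive validation and slope contrasts for
longitudinal eGFR analyses.

A :class:`ModelSpec` names the covariates of one GEE model (the 12
clinical terms, follow-up time, and up to four structural terms), the
design builder resolves those names against an :class:`~nephromorph.dataset.AnalysisDataset`,
and helpers compute the leave-one-subject-out PRESS-based predictive R^2
and quartile-stratified slope contrasts.

R^2_pred = 1 - PRESS / SSR, where PRESS is the averaged squared
leave-one-subject-out prediction error of the candidate model and SSR
the averaged squared residual of the reference model containing only the
time covariate, fitted to all data.  Defining SSR against the time-only
reference (rather than the candidate's own residuals) is what makes the
statistic a measure of predictive gain: a candidate's own SSR never
exceeds its PRESS, which would force the ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    StratificationError,
    UndefinedResultError,
)
from .gee import GEEModel, GEEResults

__all__ = [
    "CLINICAL_TERMS",
    "ModelSpec",
    "FitQuality",
    "build_design",
    "fit_gee",
    "loo_press_r2",
    "stratified_slope_test",
]

# the clinical/demographic adjustment set: baseline kidney function, race
# indicators (reference = Other), age, sex, onset/duration, diagnostic
# cohort indicators (reference = membranous nephropathy), body-mass index
# and quantitative proteinuria
CLINICAL_TERMS = (
    "baseline_egfr",
    "race_asian",
    "race_black",
    "race_white",
    "age",
    "female",
    "age_at_onset",
    "disease_duration",
    "cohort_mcd",
    "cohort_fsgs",
    "bmi",
    "upc",
)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate list for one longitudinal eGFR model.

    ``covariates`` must include ``time``; ``interactions`` are
    ``"a:b"`` product terms (used by the stratified slope analysis).
    """

    covariates: tuple[str, ...]
    interactions: tuple[str, ...] = ()
    outcome: str = "egfr"
    working_correlation: str = "independence"
    name: str = "model"

    def __post_init__(self):
        if "time" not in self.covariates:
            raise InvalidParameterError("the time covariate is always required")
        if len(set(self.covariates)) != len(self.covariates):
            raise InvalidParameterError("duplicate covariates in spec")

    @classmethod
    def clinical(cls, structural: tuple[str, ...] = (), name: str = "model",
                 working_correlation: str = "independence") -> "ModelSpec":
        """The 12 clinical terms + time, plus optional structural terms."""
        return cls(
            covariates=(*CLINICAL_TERMS, "time", *structural),
            name=name,
            working_correlation=working_correlation,
        )

    @classmethod
    def time_only(cls) -> "ModelSpec":
        return cls(covariates=("time",), name="time_only")


def _resolve_term(frame: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a covariate name to a numeric column.

    Indicator shorthand (race_*, cohort_*) is derived from the
    categorical columns when no numeric column of that name exists.
    """
    if name in frame.columns and frame[name].dtype != object:
        col = frame[name]
        if col.dtype == bool:
            return col.to_numpy(dtype=float)
        return col.to_numpy(dtype=float)
    if name.startswith("race_") and "race" in frame.columns:
        level = name.split("_", 1)[1]
        return (frame["race"].astype(str).str.lower() == level).to_numpy(dtype=float)
    if name.startswith("cohort_") and "cohort" in frame.columns:
        level = name.split("_", 1)[1]
        return (frame["cohort"].astype(str).str.lower() == level).to_numpy(dtype=float)
    raise InvalidParameterError(f"covariate {name!r} cannot be resolved in the dataset")


def build_design(dataset, spec: ModelSpec):
    """Long-format outcome/design/groups for a model spec.

    Returns ``(y, X, groups, names)`` with an explicit intercept column
    first.
    """
    frame = dataset.joined()
    y = frame[spec.outcome].to_numpy(dtype=float)
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for c in spec.covariates:
        cols.append(_resolve_term(frame, c))
        names.append(c)
    for term in spec.interactions:
        a, b = term.split(":")
        cols.append(_resolve_term(frame, a) * _resolve_term(frame, b))
        names.append(term)
    X = np.column_stack(cols)
    groups = frame["subject_id"].to_numpy()
    return y, X, groups, names


def fit_gee(dataset, spec: ModelSpec, **fit_kwargs) -> GEEResults:
    """Fit one longitudinal GEE model to an analysis dataset."""
    y, X, groups, names = build_design(dataset, spec)
    model = GEEModel(
        y, X, groups, exog_names=names,
        working_correlation=spec.working_correlation,
    )
    return model.fit(**fit_kwargs)


@dataclass
class FitQuality:
    """Goodness-of-fit and predictive validation of one model."""

    qic: float
    press: float      # averaged leave-one-subject-out squared error
    ssr: float        # averaged squared residual of the time-only reference
    r2_pred: float


def loo_press_r2(
    dataset,
    spec: ModelSpec,
    reference_spec: ModelSpec | None = None,
) -> FitQuality:
    """Leave-one-subject-out predictive R^2 of a candidate model.

    For each subject the candidate model is refitted without that
    subject and the subject's visits are predicted from the marginal
    mean; PRESS averages the squared held-out errors over all visits.
    """
    reference_spec = reference_spec or ModelSpec.time_only()
    y, X, groups, names = build_design(dataset, spec)
    y_ref, X_ref, groups_ref, _ = build_design(dataset, reference_spec)

    ref_fit = GEEModel(
        y_ref, X_ref, groups_ref,
        working_correlation=reference_spec.working_correlation,
    ).fit()
    ref_resid = y_ref - X_ref @ ref_fit.params
    ssr = float(np.mean(ref_resid ** 2))
    if ssr <= 1e-10 * max(float(np.mean(y_ref ** 2)), 1.0):
        raise UndefinedResultError("reference model SSR is zero; R^2_pred undefined")

    unique = pd.unique(groups)
    if len(unique) < 3:
        raise InvalidParameterError("need at least 3 subjects for leave-one-out")
    sq_errors = []
    for g in unique:
        held = groups == g
        model = GEEModel(
            y[~held], X[~held], groups[~held], exog_names=names,
            working_correlation=spec.working_correlation,
        )
        fit = model.fit()
        pred = X[held] @ fit.params
        sq_errors.append((y[held] - pred) ** 2)
    press = float(np.mean(np.concatenate(sq_errors)))

    full_fit = GEEModel(
        y, X, groups, exog_names=names,
        working_correlation=spec.working_correlation,
    ).fit()
    return FitQuality(
        qic=full_fit.qic(), press=press, ssr=ssr, r2_pred=1.0 - press / ssr
    )


@dataclass
class StratifiedSlopes:
    """Per-stratum eGFR slopes and contrasts against the lowest stratum."""

    stratifier: str
    edges: np.ndarray               # interior quantile cut points
    counts: list[int]               # subjects per stratum
    slopes: np.ndarray              # per-stratum slope, per month
    contrasts: np.ndarray           # slope differences vs stratum 1
    contrast_se: np.ndarray
    contrast_p: np.ndarray
    fit: GEEResults


def stratified_slope_test(
    dataset,
    stratifier: str = "FATA",
    n_strata: int = 4,
    working_correlation: str = "independence",
) -> StratifiedSlopes:
    """Test for differential eGFR slopes across stratifier quantile bins.

    Subjects are binned at sample quantiles of the stratifier (lowest
    bin inclusive of its boundary), and a GEE of
    ``egfr ~ stratum + time + stratum:time`` is fitted; the reported
    contrasts are the interaction coefficients — slope differences of
    each upper stratum against the lowest — with robust Wald p-values.
    """
    subjects = dataset.subjects
    if stratifier not in subjects.columns:
        raise InvalidParameterError(f"stratifier {stratifier!r} not in subjects table")
    values = subjects[stratifier].astype(float)
    if values.isna().any():
        raise InvalidParameterError(f"stratifier {stratifier!r} has missing values")
    qs = np.linspace(0, 1, n_strata + 1)[1:-1]
    edges = np.quantile(values.to_numpy(), qs)
    bins = np.searchsorted(edges, values.to_numpy(), side="left")
    # values equal to a cut point fall in the lower stratum
    counts = [int((bins == b).sum()) for b in range(n_strata)]
    if any(c == 0 for c in counts):
        raise StratificationError(
            f"empty stratum with edges {edges!r}: counts {counts}"
        )
    strata = pd.Series(bins, index=subjects.index, name="stratum")

    frame = dataset.joined()
    frame = frame.merge(strata, left_on="subject_id", right_index=True)
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for b in range(1, n_strata):
        cols.append((frame["stratum"] == b).to_numpy(dtype=float))
        names.append(f"stratum{b+1}")
    cols.append(frame["time"].to_numpy(dtype=float))
    names.append("time")
    for b in range(1, n_strata):
        cols.append(
            (frame["stratum"] == b).to_numpy(dtype=float)
            * frame["time"].to_numpy(dtype=float)
        )
        names.append(f"stratum{b+1}:time")
    X = np.column_stack(cols)
    fit = GEEModel(
        frame["egfr"].to_numpy(dtype=float), X, frame["subject_id"].to_numpy(),
        exog_names=names, working_correlation=working_correlation,
    ).fit()

    idx_time = names.index("time")
    base_slope = fit.params[idx_time]
    contrast_idx = [names.index(f"stratum{b+1}:time") for b in range(1, n_strata)]
    contrasts = fit.params[contrast_idx]
    se = fit.bse[contrast_idx]
    pvals = fit.pvalues[contrast_idx]
    slopes = np.concatenate([[base_slope], base_slope + contrasts])
    return StratifiedSlopes(
        stratifier=stratifier, edges=edges, counts=counts, slopes=slopes,
        contrasts=contrasts, contrast_se=se, contrast_p=pvals, fit=fit,
    )
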