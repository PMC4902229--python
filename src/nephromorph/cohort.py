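"""Synthetic clinical cohorts and longitudinal eGFR trajectories.

The generator's defaults emulate a multicentre cohort of primary
proteinuric glomerulopathies (minimal change disease, FSGS, membranous
nephropathy): 56 subjects split 25 FSGS / 19 MCD / 12 MN, 25% Black,
70% male, 39% children; baseline eGFR with median 89.5 and IQR
64.5-108.4 mL/min/1.73m^2; visits every 4-6 months for up to 55.4
months (median follow-up ~30 months, a fraction of subjects contributing
only a baseline visit); and a population mean eGFR slope of -3.36 per
year, part of which is carried by structural covariates (larger
fractional atrophic-tubule area means faster decline, an MCD diagnosis
slower decline).

Categorical covariates are allocated by largest-remainder apportionment
and continuous marginals by stratified (quantile-matched) sampling, so
that a small simulated cohort reproduces the target composition and
descriptive statistics closely; assignments are then shuffled, so joint
structure is random.  Morphometric fractions come from a Gaussian model
whose compartment SDs are proportional to the null eigenvector of the
target correlation matrix — that construction yields the target
correlations exactly in expectation *and* rows that sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import egfr as egfr_eq
from .errors import InvalidParameterError
from .features import REFERENCE_COMPARTMENT_CORRELATION
from .tissue import FRACTION_COLUMNS

__all__ = [
    "CohortMix",
    "MorphometryDistribution",
    "TrajectoryEffects",
    "SubjectRecord",
    "generate_clinical_cohort",
    "generate_morphometry",
    "simulate_trajectories",
]

RACES = ("Asian", "Black", "White", "Other")
COHORTS = ("MCD", "FSGS", "MN")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's baseline clinical/demographic record."""

    subject_id: str
    baseline_egfr: float          # mL/min/1.73m^2
    race: str
    age: float                    # years
    female: bool
    age_at_onset: float           # years
    disease_duration: float       # years
    cohort: str
    bmi: float                    # kg/m^2
    upc: float                    # urine protein/creatinine, mg/mg
    height: float                 # m
    serum_creatinine: float       # mg/dL

    def __post_init__(self):
        if self.baseline_egfr <= 0:
            raise InvalidParameterError("baseline eGFR must be positive")
        if not 0 <= self.age_at_onset <= self.age:
            raise InvalidParameterError("need 0 <= age_at_onset <= age")
        if self.race not in RACES:
            raise InvalidParameterError(f"unknown race {self.race!r}")
        if self.cohort not in COHORTS:
            raise InvalidParameterError(f"unknown cohort {self.cohort!r}")


@dataclass(frozen=True)
class CohortMix:
    """Target composition and covariate marginals of a simulated cohort."""

    cohort_probs: tuple[float, ...] = (19 / 56, 25 / 56, 12 / 56)  # MCD, FSGS, MN
    race_probs: tuple[float, ...] = (0.07, 0.25, 0.58, 0.10)       # Asian, Black, White, Other
    p_female: float = 0.30
    p_pediatric: float = 0.39
    pediatric_age_range: tuple[float, float] = (2.0, 17.9)
    adult_age_range: tuple[float, float] = (18.0, 72.0)
    # piecewise-linear inverse CDF knots for baseline eGFR:
    # (probability, eGFR) pairs; interior knots are the target quartiles
    egfr_quantile_knots: tuple[tuple[float, float], ...] = (
        (0.0, 15.0),
        (0.25, 64.5),
        (0.5, 89.5),
        (0.75, 108.4),
        (1.0, 150.0),
    )
    disease_duration_mean: float = 2.0     # years, exponential
    bmi_mean: float = 25.0
    bmi_sd: float = 5.0
    upc_log_median: float = 1.0            # log mg/mg -> median ~2.7
    upc_log_sd: float = 0.8

    def __post_init__(self):
        for name, probs in (("cohort_probs", self.cohort_probs), ("race_probs", self.race_probs)):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} must be nonnegative and sum to 1")


def _apportion(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder integer allocation of n among categories."""
    quotas = n * probs
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(quotas - counts)[::-1]
    counts[order[:remainder]] += 1
    return counts


def _stratified_uniform(rng, n: int) -> np.ndarray:
    """One uniform draw per stratum (i + u)/n, shuffled."""
    u = (np.arange(n) + rng.uniform(0, 1, n)) / n
    rng.shuffle(u)
    return u


def _egfr_icdf(mix: CohortMix, p: np.ndarray) -> np.ndarray:
    knots = np.asarray(mix.egfr_quantile_knots, dtype=float)
    return np.interp(p, knots[:, 0], knots[:, 1])


def generate_clinical_cohort(
    n: int,
    mix: CohortMix | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[SubjectRecord]:
    """Generate ``n`` subjects with the given composition.

    Reproducible given the seed; categorical counts follow
    largest-remainder apportionment of the target proportions, so the
    default 56-subject cohort splits exactly 25 FSGS / 19 MCD / 12 MN.
    """
    if n < 1:
        raise InvalidParameterError("n must be at least 1")
    mix = mix or CohortMix()
    rng = np.random.default_rng(seed)

    def allocate(categories, probs):
        counts = _apportion(n, np.asarray(probs, dtype=float))
        col = np.repeat(np.asarray(categories, dtype=object), counts)
        rng.shuffle(col)
        return col

    cohort = allocate(COHORTS, mix.cohort_probs)
    race = allocate(RACES, mix.race_probs)
    female = allocate([True, False], (mix.p_female, 1 - mix.p_female))
    pediatric = allocate([True, False], (mix.p_pediatric, 1 - mix.p_pediatric))

    ages = np.where(
        pediatric.astype(bool),
        rng.uniform(*mix.pediatric_age_range, n),
        rng.uniform(*mix.adult_age_range, n),
    )
    egfr0 = _egfr_icdf(mix, _stratified_uniform(rng, n))
    duration = np.minimum(rng.exponential(mix.disease_duration_mean, n), 0.9 * ages)
    # proteinuria onset precedes diagnosis by a variable lag, so age at
    # onset is not an exact linear function of age and disease duration
    onset_lag = rng.uniform(0.0, 1.0, n)
    bmi = np.clip(rng.normal(mix.bmi_mean, mix.bmi_sd, n), 14.0, 45.0)
    upc = np.clip(np.exp(rng.normal(mix.upc_log_median, mix.upc_log_sd, n)), 0.5, 25.0)
    height = np.where(
        ages < 18,
        np.clip(0.75 + 0.057 * ages + rng.normal(0, 0.05, n), 0.7, 1.9),
        np.clip(rng.normal(1.70, 0.10, n), 1.45, 2.05),
    )

    records = []
    for i in range(n):
        age = float(ages[i])
        is_f = bool(female[i])
        is_black = race[i] == "Black"
        if age < 18:
            scr = egfr_eq.invert_ckid(float(egfr0[i]), float(height[i]))
        else:
            scr = egfr_eq.invert_ckdepi(float(egfr0[i]), age, is_f, is_black)
        records.append(
            SubjectRecord(
                subject_id=f"S{i+1:03d}",
                baseline_egfr=float(egfr0[i]),
                race=str(race[i]),
                age=age,
                female=is_f,
                age_at_onset=float(max(age - duration[i] - onset_lag[i], 0.0)),
                disease_duration=float(duration[i]),
                cohort=str(cohort[i]),
                bmi=float(bmi[i]),
                upc=float(upc[i]),
                height=float(height[i]),
                serum_creatinine=float(scr),
            )
        )
    return records


def subjects_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy one-row-per-subject table."""
    return pd.DataFrame([r.__dict__ for r in records]).set_index("subject_id")


@dataclass(frozen=True)
class MorphometryDistribution:
    """Marginal means and correlation target of the morphometric record.

    ``fraction_sds`` defaults to the target correlation matrix's null
    eigenvector scaled so the largest compartment SD is ``scale`` — the
    unique direction (up to scale) for which the generated fractions sum
    to a constant while attaining the target correlations exactly.
    """

    fraction_means: tuple[float, ...] = (0.25, 0.05, 0.55, 0.08, 0.05, 0.02)
    scale: float = 0.08
    log_ag_mean: float = np.log(14000.0)   # um^2
    log_ag_sd: float = 0.30
    log_na_mean: float = np.log(3.2)       # per mm^2
    log_na_sd: float = 0.35
    ag_na_corr: float = -0.5
    descriptor_noise_sd: float = 0.028     # IF/TA vs FIA/FATA, fraction scale

    def __post_init__(self):
        mu = np.asarray(self.fraction_means, dtype=float)
        if mu.shape != (6,) or abs(mu.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("fraction means must be six values summing to 1")


def _simplex_gaussian_factors(corr: np.ndarray, scale: float):
    """Square-root factor and SD vector for the sum-constrained model."""
    w, v = np.linalg.eigh(corr)
    null = v[:, np.argmin(np.abs(w))]
    if not (np.all(null >= -1e-8) or np.all(null <= 1e-8)):
        raise InvalidParameterError(
            "correlation matrix null eigenvector changes sign; "
            "not compatible with a sum constraint"
        )
    sds = np.abs(null)
    sds = sds / sds.max() * scale
    w_clip = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w_clip))
    return root, sds


def generate_morphometry(
    subject_ids,
    dist: MorphometryDistribution | None = None,
    corr: pd.DataFrame | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-subject morphometric records with the target correlations.

    Returns a table indexed by subject with the six fractions, A_G
    (um^2), N_A (per mm^2), N_V (per mm^3, via the corpuscle relation),
    and pathologist-style percentage descriptors IF and TA modelled as
    noisy copies of FIA and FATA.
    """
    dist = dist or MorphometryDistribution()
    R = (corr if corr is not None else REFERENCE_COMPARTMENT_CORRELATION).to_numpy()
    rng = np.random.default_rng(seed)
    ids = list(subject_ids)
    n = len(ids)

    root, sds = _simplex_gaussian_factors(R, dist.scale)
    z = rng.standard_normal((n, 6)) @ root.T
    fracs = np.asarray(dist.fraction_means) + z * sds
    fracs = np.clip(fracs, 1e-4, 1.0)
    fracs /= fracs.sum(axis=1, keepdims=True)

    # mean tuft area and areal density: correlated lognormals
    # (hypertrophy accompanies glomerular loss, so the correlation is negative)
    rho = dist.ag_na_corr
    za = rng.standard_normal(n)
    zb = rho * za + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    a_g = np.exp(dist.log_ag_mean + dist.log_ag_sd * za)
    n_a = np.exp(dist.log_na_mean + dist.log_na_sd * zb)
    d_um = np.sqrt(4.0 * a_g / np.pi)
    n_v = n_a / (d_um * 1e-3)

    out = pd.DataFrame(fracs, index=ids, columns=FRACTION_COLUMNS)
    out["A_G_um2"] = a_g
    out["N_A_per_mm2"] = n_a
    out["N_V_per_mm3"] = n_v
    out["IF"] = 100.0 * np.clip(
        out["FIA"] + rng.normal(0, dist.descriptor_noise_sd, n), 0, 1
    )
    out["TA"] = 100.0 * np.clip(
        out["FATA"] + rng.normal(0, dist.descriptor_noise_sd, n), 0, 1
    )
    out.index.name = "subject_id"
    return out


@dataclass(frozen=True)
class TrajectoryEffects:
    """Data-generating process for longitudinal eGFR.

    eGFR_ij = sum_k intercept_coefs[k] x_ik
              + (slope_base + sum_k slope_coefs[k] x_ik) * t_ij + e_ij

    with e_ij mean-zero noise of SD ``noise_sd`` and within-subject
    correlation of the stated structure.  Units: eGFR in mL/min/1.73m^2,
    time in months, slopes per month.  The default slope_base is set so
    that with the default morphometry and cohort mix the population mean
    slope is -0.28/month (-3.36/year).
    """

    # level: measured eGFR tracks the screening value but carries an
    # additional atrophy-linked deficit (tubular dropout lowers filtration
    # beyond what one screening measurement captured); the constant
    # recenters the population mean at the screening marginal
    intercept_coefs: dict = field(
        default_factory=lambda: {
            "intercept": 7.2, "baseline_egfr": 1.0, "FATA": -90.0,
        }
    )
    slope_coefs: dict = field(default_factory=lambda: {"FATA": -1.5, "cohort_mcd": 0.12})
    slope_base: float = -0.200714
    within_subject_corr: tuple[str, float] = ("exchangeable", 0.5)
    noise_sd: float = 8.0
    visit_interval: tuple[float, float] = (4.0, 6.0)
    max_followup: float = 55.4
    dropout_rate: float = 0.0170          # per month
    baseline_only_prob: float = 0.125

    def __post_init__(self):
        structure, rho = self.within_subject_corr
        if structure not in ("independence", "exchangeable", "ar1"):
            raise InvalidParameterError(f"unknown correlation structure {structure!r}")
        if not 0 <= rho < 1:
            raise InvalidParameterError("correlation parameter must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if self.dropout_rate < 0:
            raise InvalidParameterError("dropout_rate must be nonnegative")


def _covariate_value(subject_row: pd.Series, name: str) -> float:
    """Resolve a coefficient name against a joined subject row.

    Indicator shorthand: cohort_mcd / cohort_fsgs / cohort_mn and
    race_<level> resolve to 0/1; ``female`` to 0/1; anything else must
    be a numeric column.
    """
    if name == "intercept":
        return 1.0
    if name.startswith("cohort_"):
        return float(str(subject_row["cohort"]).lower() == name.split("_", 1)[1])
    if name.startswith("race_"):
        return float(str(subject_row["race"]).lower() == name.split("_", 1)[1])
    if name == "female":
        return float(bool(subject_row["female"]))
    value = subject_row[name]
    return float(value)


def _correlated_noise(rng, m: int, sd: float, structure: str, rho: float) -> np.ndarray:
    if sd == 0 or m == 0:
        return np.zeros(m)
    if structure == "independence" or rho == 0:
        return rng.normal(0, sd, m)
    if structure == "exchangeable":
        shared = rng.normal(0, sd)
        return np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(0, sd, m)
    # ar1 over successive visits
    e = np.empty(m)
    e[0] = rng.normal(0, sd)
    for j in range(1, m):
        e[j] = rho * e[j - 1] + np.sqrt(1 - rho ** 2) * rng.normal(0, sd)
    return e


def simulate_trajectories(
    subjects: pd.DataFrame,
    morpho: pd.DataFrame,
    effects: TrajectoryEffects | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate visit rows (subject_id, time, egfr) for every subject.

    Every subject has a time-0 visit; later visits are spaced uniformly
    within ``visit_interval`` months until ``max_followup``, exponential
    dropout, or (with ``baseline_only_prob``) no follow-up at all.
    Raises ``KeyError`` naming the first subject without a morphometric
    record.
    """
    effects = effects or TrajectoryEffects()
    rng = np.random.default_rng(seed)
    structure, rho = effects.within_subject_corr

    missing = [s for s in subjects.index if s not in morpho.index]
    if missing:
        raise KeyError(f"no morphometric record for subject {missing[0]!r}")

    rows = []
    for sid, subj in subjects.iterrows():
        joined = pd.concat([subj, morpho.loc[sid]])
        level = sum(
            c * _covariate_value(joined, k) for k, c in effects.intercept_coefs.items()
        )
        slope = effects.slope_base + sum(
            c * _covariate_value(joined, k) for k, c in effects.slope_coefs.items()
        )

        times = [0.0]
        if effects.baseline_only_prob == 0 or rng.random() >= effects.baseline_only_prob:
            if effects.dropout_rate > 0:
                t_end = min(rng.exponential(1.0 / effects.dropout_rate), effects.max_followup)
            else:
                t_end = effects.max_followup
            t = rng.uniform(*effects.visit_interval)
            while t <= t_end:
                times.append(t)
                t += rng.uniform(*effects.visit_interval)
        times = np.asarray(times)
        noise = _correlated_noise(rng, len(times), effects.noise_sd, structure, rho)
        egfr = level + slope * times + noise
        for t, y in zip(times, egfr):
            rows.append((sid, float(t), float(y)))

    return pd.DataFrame(rows, columns=["subject_id", "time", "egfr"])
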