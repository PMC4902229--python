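"""Least-angle regression ranking of morphometric predictors.

The outcome is each subject's average rate of eGFR change
(operationalized as the per-subject OLS slope of eGFR on time), and the
predictors are the six morphometric variables (N_A, A_G, N_V and the
first three principal-component scores).  LAR enters predictors in
order of their correlation with the evolving residual, moving the
coefficient vector along the equiangular direction of the active set
until an inactive predictor ties; the entry order ranks predictor
importance and the final breakpoint is the full OLS solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedResultError

__all__ = ["SlopeOutcome", "LARPath", "subject_slopes", "lar_path",
           "DEFAULT_LAR_PREDICTORS"]

DEFAULT_LAR_PREDICTORS = (
    "N_A_per_mm2", "A_G_um2", "N_V_per_mm3", "PC1", "PC2", "PC3"
)


@dataclass(frozen=True)
class SlopeOutcome:
    """Per-subject eGFR slope (mL/min/1.73m^2 per month)."""

    subject_id: str
    slope: float
    n_visits: int


def subject_slopes(visits: pd.DataFrame) -> list[SlopeOutcome]:
    """OLS slope of eGFR on time for every subject with >= 2 distinct
    visit times; subjects that cannot yield a slope are dropped.
    """
    outcomes = []
    n_dropped = 0
    for sid, grp in visits.groupby("subject_id", sort=True):
        t = grp["time"].to_numpy(dtype=float)
        y = grp["egfr"].to_numpy(dtype=float)
        if len(np.unique(t)) < 2:
            n_dropped += 1
            continue
        slope = np.polyfit(t, y, 1)[0]
        outcomes.append(SlopeOutcome(str(sid), float(slope), len(t)))
    if not outcomes:
        raise UndefinedResultError(
            f"no subject has two distinct visit times ({n_dropped} dropped)"
        )
    return outcomes


@dataclass
class LARPath:
    """Entry order and coefficient breakpoints of a LAR run.

    ``breakpoints`` holds the coefficient vector (original predictor
    scale) after each step; the last row equals the full OLS solution.
    ``max_correlations`` is the decreasing sequence of maximal absolute
    residual correlations (on the standardized scale) at each step.
    """

    predictors: list[str]
    entry_order: list[str]
    breakpoints: np.ndarray          # (n_steps + 1) x p, includes start at 0
    breakpoints_std: np.ndarray      # same, on the standardized scale
    max_correlations: np.ndarray
    y_mean: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.breakpoints, columns=self.predictors)
        frame.insert(0, "step", np.arange(len(frame)))
        return frame


def lar_path(X, y, predictor_names=None) -> LARPath:
    """Classic least-angle regression path (no lasso modification).

    Columns of ``X`` are standardized internally to mean 0 and unit
    Euclidean norm and ``y`` is centered; ties at entry are broken
    deterministically by column order.  Requires more observations than
    predictors so the full OLS endpoint exists.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = list(predictor_names) if predictor_names is not None else [
            f"x{i+1}" for i in range(X.shape[1])
        ]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise InvalidParameterError("X and y lengths differ")
    if n <= p:
        raise InvalidParameterError("need more observations than predictors")

    x_mean = X.mean(axis=0)
    xc = X - x_mean
    norms = np.sqrt((xc ** 2).sum(axis=0))
    if np.any(norms == 0):
        bad = [names[i] for i in np.flatnonzero(norms == 0)]
        raise UndefinedResultError(f"constant predictor column(s): {bad}")
    xs = xc / norms
    y_mean = y.mean()
    yc = y - y_mean

    beta = np.zeros(p)              # standardized scale
    mu = np.zeros(n)
    active: list[int] = []
    inactive = list(range(p))
    betas = [beta.copy()]
    cmaxes = []
    eps = 1e-12

    while len(active) < p:
        c = xs.T @ (yc - mu)
        c_inactive = c[inactive]
        jrel = int(np.argmax(np.abs(c_inactive)))   # first max: column-order tie-break
        cmax = abs(c_inactive[jrel])
        cmaxes.append(cmax)
        j = inactive[jrel]
        active.append(j)
        inactive.remove(j)

        signs = np.sign(c[active])
        signs[signs == 0] = 1.0
        Xa = xs[:, active] * signs
        G = Xa.T @ Xa
        Ginv1 = np.linalg.solve(G, np.ones(len(active)))
        A = 1.0 / np.sqrt(np.ones(len(active)) @ Ginv1)
        w = A * Ginv1
        u = Xa @ w                                  # equiangular direction
        a = xs.T @ u

        if inactive:
            C = cmax
            gammas = []
            for k in inactive:
                for num, den in ((C - c[k], A - a[k]), (C + c[k], A + a[k])):
                    if den > eps and num / den > eps:
                        gammas.append(num / den)
            gamma = min(gammas) if gammas else C / A
            gamma = min(gamma, C / A)
        else:
            gamma = cmax / A                        # last step: go to OLS

        mu = mu + gamma * u
        for idx, k in enumerate(active):
            beta[k] += gamma * signs[idx] * w[idx]
        betas.append(beta.copy())

    betas_std = np.vstack(betas)
    betas_orig = betas_std / norms
    return LARPath(
        predictors=names,
        entry_order=[names[j] for j in active],
        breakpoints=betas_orig,
        breakpoints_std=betas_std,
        max_correlations=np.asarray(cmaxes),
        y_mean=float(y_mean),
    )
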