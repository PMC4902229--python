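"""Generalized estimating equations for longitudinal Gaussian outcomes.

A marginal linear model for clustered data: E[y_ij] = x_ij' beta, with a
working within-cluster correlation (independence or exchangeable) and
robust "sandwich" covariance for inference.  The engine is written for
the identity-link Gaussian family used in eGFR modelling; coefficients
under an independence working correlation coincide with ordinary least
squares, while standard errors do not.

Model comparison uses the quasi-likelihood under the independence model
criterion (QIC), QIC = -2 Q(beta; I) + 2 tr(Omega_I V_robust), where Q
is the Gaussian quasi-likelihood at the fitted means evaluated under
independence and Omega_I the corresponding model-based information.  The
trace term approaches the parameter count when the working model is
adequate, making QIC the GEE analogue of AIC.

Robust covariance comes in two flavours.  ``cov_type="robust"`` is the
plain sandwich; it is consistent but biased downward when the number of
clusters is modest relative to the parameter count.  The default,
``cov_type="bias_reduced"``, applies the standard cluster-leverage
bias correction (each cluster's residual is inflated by the inverse of
I - H_i, the cluster hat matrix), the usual small-sample convention for
GEE inference with tens of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, SingularDesignError

__all__ = ["GEEModel", "GEEResults", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    """Emitted when the estimating equations do not converge."""

_STRUCTURES = ("independence", "exchangeable")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns implicated in rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return bad


class GEEModel:
    """Marginal Gaussian model for clustered longitudinal data.

    Parameters
    ----------
    endog : array, shape (n_obs,)
        Outcome vector.
    exog : array, shape (n_obs, p)
        Design matrix (include an intercept column explicitly or use
        :meth:`from_dataframe`).
    groups : array, shape (n_obs,)
        Cluster (subject) identifier per observation.
    exog_names : sequence of str, optional
    working_correlation : {"independence", "exchangeable"}
    """

    def __init__(self, endog, exog, groups, exog_names=None,
                 working_correlation: str = "independence"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise InvalidParameterError("endog and exog row counts differ")
        groups = np.asarray(groups)
        if groups.shape[0] != self.endog.shape[0]:
            raise InvalidParameterError("groups length must match observations")
        if working_correlation not in _STRUCTURES:
            raise InvalidParameterError(
                f"working_correlation must be one of {_STRUCTURES}"
            )
        self.working_correlation = working_correlation
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        if len(self.exog_names) != self.exog.shape[1]:
            raise InvalidParameterError("exog_names length mismatch")

        _, inverse = np.unique(groups, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        self._order = order
        self._groups_sorted = inverse[order]
        self._unique_groups = np.unique(groups)
        self.n_subjects = len(self._unique_groups)
        self.n_obs = self.endog.shape[0]
        if self.n_subjects < 2:
            raise InvalidParameterError("need at least 2 clusters")

        p = self.exog.shape[1]
        if np.linalg.matrix_rank(self.exog) < p:
            bad = _collinear_columns(self.exog, self.exog_names)
            raise SingularDesignError(
                f"design matrix is rank deficient; collinear terms: {bad}", columns=bad
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, covariates,
                       group: str, working_correlation: str = "independence",
                       add_intercept: bool = True) -> "GEEModel":
        """Build a model from a long-format DataFrame.

        ``covariates`` are column names; an intercept column is prepended
        unless ``add_intercept`` is False.
        """
        covariates = list(covariates)
        missing = [c for c in [outcome, group, *covariates] if c not in data.columns]
        if missing:
            raise InvalidParameterError(f"columns not in data: {missing}")
        X = data[covariates].to_numpy(dtype=float)
        names = covariates
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["intercept", *covariates]
        return cls(
            data[outcome].to_numpy(dtype=float), X, data[group].to_numpy(),
            exog_names=names, working_correlation=working_correlation,
        )

    # ------------------------------------------------------------------
    def _cluster_slices(self):
        g = self._groups_sorted
        boundaries = np.flatnonzero(np.diff(g)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [len(g)]])
        return list(zip(starts, stops))

    def fit(self, maxiter: int = 100, tol: float = 1e-8,
            cov_type: str = "bias_reduced") -> "GEEResults":
        """Solve the estimating equations by iteratively reweighted steps.

        Converges when the largest coefficient change is below ``tol``.
        Under the independence working correlation the solution is the
        OLS solution and one iteration suffices.  ``cov_type`` selects
        the plain sandwich (``"robust"``) or its cluster-leverage
        bias-reduced version (``"bias_reduced"``, default).
        """
        if cov_type not in ("robust", "bias_reduced"):
            raise InvalidParameterError(f"unknown cov_type {cov_type!r}")
        y = self.endog[self._order]
        X = self.exog[self._order]
        n, p = X.shape
        slices = self._cluster_slices()
        m = len(slices)

        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        alpha = 0.0
        phi = np.nan
        converged = False
        iterations = 0
        for iterations in range(1, maxiter + 1):
            resid = y - X @ beta
            phi = resid @ resid / (n - p)
            if self.working_correlation == "exchangeable":
                num = 0.0
                pairs = 0
                for s0, s1 in slices:
                    r = resid[s0:s1]
                    ni = s1 - s0
                    if ni > 1:
                        num += (r.sum() ** 2 - r @ r) / 2.0
                        pairs += ni * (ni - 1) // 2
                denom = max(pairs - p, 1) * phi
                alpha = float(np.clip(num / denom, 0.0, 0.99)) if pairs else 0.0
            bread = np.zeros((p, p))
            rhs = np.zeros(p)
            for s0, s1 in slices:
                Xi = X[s0:s1]
                yi = y[s0:s1]
                XtVinv = self._xt_vinv(Xi, alpha)
                bread += XtVinv @ Xi
                rhs += XtVinv @ yi
            beta_new = np.linalg.solve(bread, rhs)
            delta = np.max(np.abs(beta_new - beta))
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged and self.working_correlation == "independence":
            converged = True  # closed form; no iteration needed

        # final covariance pieces at the solution
        resid = y - X @ beta
        phi = resid @ resid / (n - p)
        bread = np.zeros((p, p))
        for s0, s1 in slices:
            Xi = X[s0:s1]
            bread += self._xt_vinv(Xi, alpha) @ Xi
        bread_inv = np.linalg.inv(bread)
        meat = np.zeros((p, p))
        for s0, s1 in slices:
            Xi = X[s0:s1]
            ei = resid[s0:s1]
            XtVinv = self._xt_vinv(Xi, alpha)
            if cov_type == "bias_reduced":
                # inflate the cluster residual by (I - H_i)^{-1}, the
                # cluster-leverage correction for small cluster counts
                Hi = Xi @ bread_inv @ XtVinv
                ei = np.linalg.solve(np.eye(len(ei)) - Hi, ei)
            gi = XtVinv @ ei
            meat += np.outer(gi, gi)
        robust = bread_inv @ meat @ bread_inv
        model_based = phi * bread_inv
        return GEEResults(
            model=self, params=beta, robust_cov=robust, model_cov=model_based,
            scale=phi, alpha=alpha, converged=converged, iterations=iterations,
        )

    def _xt_vinv(self, Xi: np.ndarray, alpha: float) -> np.ndarray:
        """X_i' V_i^{-1} up to the scale factor phi (which cancels)."""
        ni = Xi.shape[0]
        if self.working_correlation == "independence" or alpha == 0.0 or ni == 1:
            return Xi.T
        # exchangeable: V = (1-a) I + a J; Woodbury inverse
        c = alpha / (1.0 + (ni - 1) * alpha)
        Xt = Xi.T / (1.0 - alpha)
        col_sums = Xi.sum(axis=0) / (1.0 - alpha)
        return Xt - c * np.outer(col_sums, np.ones(ni))


@dataclass
class GEEResults:
    """Fit results: coefficients, covariances, robust Wald inference."""

    model: GEEModel
    params: np.ndarray
    robust_cov: np.ndarray
    model_cov: np.ndarray
    scale: float
    alpha: float
    converged: bool
    iterations: int

    def __post_init__(self):
        if not self.converged:
            import warnings

            warnings.warn(
                f"GEE did not converge in {self.iterations} iterations; "
                "results are flagged (converged=False)",
                ConvergenceWarning,
                stacklevel=2,
            )

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        """Robust (sandwich) standard errors."""
        return np.sqrt(np.diag(self.robust_cov))

    @property
    def wald_chi2(self) -> np.ndarray:
        return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values against chi-square(1)."""
        return stats.chi2.sf(self.wald_chi2, df=1)

    @property
    def n_subjects(self) -> int:
        return self.model.n_subjects

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Marginal mean prediction X beta (no cluster-specific update)."""
        return np.atleast_2d(np.asarray(exog, dtype=float)) @ self.params

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.exog_names, name="coef")

    # ------------------------------------------------------------------
    def qic(self) -> float:
        """Quasi-likelihood under the independence model criterion."""
        return self._qic_parts()[0]

    def qic_trace(self) -> float:
        """tr(Omega_I V_robust); approaches p for an adequate model."""
        return self._qic_parts()[1]

    def _qic_parts(self) -> tuple[float, float]:
        X = self.model.exog
        y = self.model.endog
        resid = y - X @ self.params
        ssr = float(resid @ resid)
        if self.scale <= 0:
            raise InvalidParameterError("nonpositive dispersion; QIC undefined")
        omega_i = (X.T @ X) / self.scale
        trace = float(np.trace(omega_i @ self.robust_cov))
        minus2q = ssr / self.scale
        return minus2q + 2.0 * trace, trace

    def summary(self) -> str:
        """Human-readable coefficient table with robust inference."""
        se = self.bse
        ci = self.conf_int()
        lines = [
            "Generalized estimating equations (Gaussian, identity link)",
            f"working correlation: {self.model.working_correlation}"
            + (f" (alpha = {self.alpha:.3f})"
               if self.model.working_correlation == "exchangeable" else ""),
            f"clusters: {self.n_subjects}   observations: {self.n_obs}   "
            f"scale: {self.scale:.3f}   QIC: {self.qic():.2f}",
            "-" * 78,
            f"{'term':<28}{'coef':>10}{'robust SE':>11}{'95% CI':>22}{'Pr(>|W|)':>9}",
        ]
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<28}{self.params[i]:>10.4f}{se[i]:>11.4f}"
                f"{'[' + format(ci[i, 0], '.3f') + ', ' + format(ci[i, 1], '.3f') + ']':>22}"
                f"{self.pvalues[i]:>9.4f}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)
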