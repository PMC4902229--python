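"""Correlation structure and principal-component composites of the six
fractional cortical areas.

The six point-counted compartment fractions (FIA, FBVA, FITA, FATA,
FPGA, FSGA) are strongly inter-correlated — fibrotic cortex trades
intact tubular area for interstitium and atrophic tubules — so the
modelling stage compresses them into principal components of their
correlation matrix.  PC1 is an acquired-nephron-loss axis (positive on
interstitium and atrophic tubules, negative on intact tubules).

:data:`REFERENCE_COMPARTMENT_CORRELATION` is the published correlation
matrix of the six fractions observed in a multicentre cohort of primary
proteinuric glomerulopathies; the synthetic cohort generator uses it as
its default correlation target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UndefinedResultError
from .tissue import FRACTION_COLUMNS

__all__ = [
    "REFERENCE_COMPARTMENT_CORRELATION",
    "CorrelationReport",
    "PCALoadings",
    "compartment_correlations",
    "principal_components",
    "pc_scores",
]

# Published Pearson correlations among the six fractional cortical areas
# (rows/columns ordered as FRACTION_COLUMNS).  The matrix is singular to
# printed precision: its null eigenvector has components of one sign,
# which is exactly the degeneracy induced by the fractions summing to 1.
REFERENCE_COMPARTMENT_CORRELATION = pd.DataFrame(
    [
        [1.000, 0.026, -0.867, 0.670, -0.308, 0.324],
        [0.026, 1.000, -0.213, -0.092, 0.044, 0.123],
        [-0.867, -0.213, 1.000, -0.852, 0.016, -0.411],
        [0.670, -0.092, -0.852, 1.000, -0.149, 0.275],
        [-0.308, 0.044, 0.016, -0.149, 1.000, -0.097],
        [0.324, 0.123, -0.411, 0.275, -0.097, 1.000],
    ],
    index=FRACTION_COLUMNS,
    columns=FRACTION_COLUMNS,
)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with Bonferroni-corrected flags."""

    matrix: pd.DataFrame          # k x k correlations
    n: int                        # complete-case sample size
    significant: pd.DataFrame     # boolean, Bonferroni over the k(k-1)/2 tests
    alpha: float = 0.05


@dataclass
class PCALoadings:
    """Eigenvectors of a correlation matrix, eigenvalues descending.

    ``loadings`` has one column per component; the sign of each column
    is fixed so that its first-variable (FIA) loading is nonnegative,
    falling back to the largest-magnitude entry when that loading is
    numerically zero.
    """

    loadings: pd.DataFrame        # p x k
    eigenvalues: np.ndarray       # k, descending
    sign_convention: str = "first_variable_nonnegative"

    def dominant(self, component: int, threshold: float = 0.3) -> pd.Series:
        """Coefficients with |loading| >= threshold, as reported in
        truncated published listings."""
        col = self.loadings.iloc[:, component]
        return col[col.abs() >= threshold]


def compartment_correlations(
    table: pd.DataFrame, alpha: float = 0.05, columns=None
) -> CorrelationReport:
    """Pearson correlations among fraction columns, Bonferroni flags.

    Rows with any missing value among the used columns are dropped
    (complete-case).  Raises :class:`UndefinedResultError` for a
    constant column, naming it.
    """
    cols = list(columns) if columns is not None else [
        c for c in FRACTION_COLUMNS if c in table.columns
    ]
    if not cols:
        raise InvalidParameterError("no fraction columns found in table")
    data = table[cols].dropna()
    n = len(data)
    if n < 3:
        raise InvalidParameterError(f"need at least 3 complete rows, got {n}")
    sds = data.std(ddof=1)
    is_constant = (data.nunique() <= 1) | (sds <= 1e-12 * (data.abs().mean() + 1.0))
    if is_constant.any():
        raise UndefinedResultError(
            "correlation undefined for constant column(s): "
            f"{list(is_constant[is_constant].index)}"
        )
    k = len(cols)
    n_tests = k * (k - 1) // 2
    corr = data.corr(method="pearson")
    # two-sided t test for each off-diagonal entry at alpha / n_tests
    r = corr.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    sig = pd.DataFrame(p < alpha / n_tests, index=cols, columns=cols)
    sig.values[np.diag_indices(k)] = False
    return CorrelationReport(matrix=corr, n=n, significant=sig, alpha=alpha)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for j in range(out.shape[1]):
        pivot = out[0, j]
        if abs(pivot) < 1e-12:
            pivot = out[np.argmax(np.abs(out[:, j])), j]
        if pivot < 0:
            out[:, j] = -out[:, j]
    return out


def principal_components(corr, k: int = 3) -> PCALoadings:
    """Top-k eigenvectors of a correlation matrix.

    The input must be symmetric; eigenvalues are clipped at zero when a
    printed (rounded) matrix is very slightly indefinite.  Signs follow
    the FIA-nonnegative convention so that loadings are comparable
    across samples.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.index)
        mat = corr.to_numpy(dtype=float)
    else:
        mat = np.asarray(corr, dtype=float)
        names = [f"x{i+1}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidParameterError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise InvalidParameterError("correlation matrix must be symmetric")
    p = mat.shape[0]
    if not 1 <= k <= p:
        raise InvalidParameterError(f"k must be in 1..{p}, got {k}")
    w, v = np.linalg.eigh(mat)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w[-1] < -1e-4:  # printed 3-decimal matrices can be minutely indefinite
        raise InvalidParameterError("matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)[:k]
    v = _fix_signs(v[:, :k])
    loadings = pd.DataFrame(v, index=names, columns=[f"PC{i+1}" for i in range(k)])
    return PCALoadings(loadings=loadings, eigenvalues=w)


def pc_scores(
    table: pd.DataFrame, loadings: PCALoadings, k: int | None = None
) -> pd.DataFrame:
    """Project a fraction table onto principal components.

    Columns are standardized with the table's own mean and SD (ddof=1)
    before projection, so score columns have mean 0; when the loadings
    come from the same table's correlation matrix the scores are
    mutually uncorrelated.
    """
    avail = loadings.loadings.shape[1]
    if k is None:
        k = avail
    if k > avail:
        raise InvalidParameterError(f"requested {k} components, only {avail} available")
    cols = list(loadings.loadings.index)
    data = table[cols]
    sds = data.std(ddof=1)
    bad = (data.nunique() <= 1) | (sds <= 1e-12 * (data.abs().mean() + 1.0))
    if bad.any():
        raise UndefinedResultError(
            f"cannot standardize constant column(s): {list(bad[bad].index)}"
        )
    z = (data - data.mean()) / sds
    scores = z.to_numpy() @ loadings.loadings.to_numpy()[:, :k]
    return pd.DataFrame(
        scores, index=table.index, columns=[f"PC{i+1}" for i in range(k)]
    )
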