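"""Composite-index construction (PCA first component) and collinearity screening.

County studies commonly collapse several socioeconomic indicators (college
attainment, unemployment, child poverty, log median income) into a single
index: the first principal component of the correlation matrix, oriented so
that a chosen anchor variable loads positively, with scores standardized to
mean 0 / SD 1.  Correlation-matrix PCA makes the index invariant to the
mixed units of its inputs.

The variance-inflation factor (VIF) screen — 1/(1 - R^2) from regressing
each covariate on the others plus an intercept — flags multicollinearity
before a regression; values above ~4 are the usual warning level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import add_constant


@dataclass
class CompositeIndex:
    """First-principal-component index: loadings, variance share, scores."""

    loadings: pd.Series          # unit-norm weights of the first component
    variance_explained: float    # fraction of total correlation variance in [0, 1]
    scores: np.ndarray           # per-area index values, mean 0 and SD 1


def _as_matrix(X, columns=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be two-dimensional")
    if columns is None:
        columns = [f"x{j + 1}" for j in range(arr.shape[1])]
    return arr, list(columns)


def pca_index(X, sign_anchor=None, columns=None) -> CompositeIndex:
    """First principal component of the correlation matrix of ``X``.

    Parameters
    ----------
    X : DataFrame or (n, p) array, p >= 2
        Index inputs; columns are standardized internally, so any affine
        rescaling of an input leaves the index unchanged.
    sign_anchor : column name, optional
        The component sign is chosen so this column's loading is positive
        (default: the first column).

    Raises
    ------
    ValueError
        On missing values or a constant (zero-variance) column.
    """
    arr, names = _as_matrix(X, columns)
    n, p = arr.shape
    if p < 2:
        raise ValueError("pca_index needs at least 2 columns")
    if not np.isfinite(arr).all():
        raise ValueError("pca_index does not accept missing/non-finite values")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s) have zero variance: {bad}")
    z = (arr - arr.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    anchor = names.index(str(sign_anchor)) if sign_anchor is not None else 0
    if lead[anchor] < 0:
        lead = -lead
    scores = z @ lead
    s = scores.std(ddof=1)
    if s > 0:
        scores = (scores - scores.mean()) / s
    return CompositeIndex(
        loadings=pd.Series(lead, index=names),
        variance_explained=float(evals[-1] / p),
        scores=scores,
    )


def vif(X, columns=None) -> pd.Series:
    """Variance inflation factor of each column of ``X``.

    Each column is regressed on the remaining columns plus an intercept;
    VIF_j = 1/(1 - R_j^2).  Perfect collinearity is reported as +inf rather
    than raised.
    """
    arr, names = _as_matrix(X, columns)
    n, p = arr.shape
    if n <= p:
        raise ValueError(f"vif needs n > p, got n={n}, p={p}")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}")
    exog = add_constant(arr, has_constant="add")
    out = np.empty(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(p):
            v = variance_inflation_factor(exog, j + 1)
            out[j] = np.inf if (not np.isfinite(v) or v > 1e12) else v
    return pd.Series(out, index=names)
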