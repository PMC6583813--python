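"""Synthetic areal data with spatial Durbin structure.

Two generators cover what a simulation study of county-level spatial
regression needs:

* :func:`simulate_covariates` draws spatially autocorrelated covariate
  columns as (I - rho_x W)^{-1} eps, affinely rescaled to target means and
  standard deviations, so that exploratory statistics (Moran's I, quintile
  maps) behave like real clustered county attributes.
* :func:`simulate_sdm_outcome` draws the outcome from the spatial Durbin
  process (I - rho W) y = alpha + X beta + W X theta + eps, solved by a
  sparse linear solve (never an explicit inverse).

:func:`demo_county_table` bundles both into a demonstration table whose
marginal means/SDs mimic a published county mental-distress data set
(outcome ~12.2% with SD 1.9, a standardized social-capital index with SD
1.26, etc.).  The demo rescales and clamps the outcome to (0, 100) for
realism; simulation-study code must use :func:`simulate_sdm_outcome`
directly, which never clamps (clamping would bias parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .weights import SpatialWeights, lattice_weights


@dataclass
class SDMParams:
    """Parameters of the spatial Durbin data-generating process.

    rho is the spatial autoregressive coefficient (must lie strictly inside
    the admissible interval of the weights matrix), alpha the intercept,
    beta/theta the own- and neighbor-covariate coefficients (length p), and
    sigma2 >= 0 the error variance (0 gives the deterministic limit).
    """

    rho: float
    alpha: float
    beta: np.ndarray
    theta: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.beta.shape != self.theta.shape:
            raise ValueError("beta and theta must have the same length")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @property
    def p(self) -> int:
        return self.beta.size

    def validate(self, weights: SpatialWeights) -> None:
        lo, hi = weights.rho_interval()
        if not (lo < self.rho < hi):
            raise ValueError(
                f"rho={self.rho} outside admissible interval ({lo:.6f}, {hi:.6f})"
            )


def simulate_covariates(
    weights: SpatialWeights,
    means,
    sds,
    spatial_rho_x: float = 0.0,
    names=None,
    seed=None,
) -> pd.DataFrame:
    """Spatially autocorrelated covariate columns with exact target moments.

    Each column is generated as (I - spatial_rho_x W)^{-1} eps with iid
    standard-normal eps, then affinely rescaled to the requested sample mean
    and SD (ddof=1).  ``spatial_rho_x = 0`` gives iid columns.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    if means.shape != sds.shape:
        raise ValueError("means and sds must have the same length")
    p = means.size
    if spatial_rho_x != 0.0:
        lo, hi = weights.rho_interval()
        if not (lo < spatial_rho_x < hi):
            raise ValueError(
                f"spatial_rho_x={spatial_rho_x} outside admissible interval "
                f"({lo:.6f}, {hi:.6f})"
            )
    rng = np.random.default_rng(seed)
    n = weights.n
    eps = rng.standard_normal((n, p))
    if spatial_rho_x != 0.0:
        a = (sp.identity(n, format="csc") - spatial_rho_x * weights.sparse).tocsc()
        cols = splu(a).solve(eps)
    else:
        cols = eps
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0, ddof=1)
    cols = (cols - mu) / sd * sds + means
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    return pd.DataFrame(cols, columns=list(names))


def simulate_sdm_outcome(
    weights: SpatialWeights,
    X,
    params: SDMParams,
    seed=None,
    error_dist: str = "gaussian",
    df: float = 5.0,
) -> np.ndarray:
    """Draw an outcome vector from the spatial Durbin process.

    Solves (I - rho W) y = alpha + X beta + W X theta + eps with a sparse LU
    factorization.  ``error_dist="t"`` substitutes scaled Student-t errors
    (df degrees of freedom, variance still sigma2) for robustness checks.
    """
    if not weights.standardized:
        raise ValueError("simulate_sdm_outcome expects a row-standardized W")
    params.validate(weights)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != weights.n or X.shape[1] != params.p:
        raise ValueError(
            f"X must be (n={weights.n}, p={params.p}); got {X.shape}"
        )
    rng = np.random.default_rng(seed)
    n = weights.n
    if params.sigma2 == 0:
        eps = np.zeros(n)
    elif error_dist == "gaussian":
        eps = rng.normal(0.0, np.sqrt(params.sigma2), n)
    elif error_dist == "t":
        if df <= 2:
            raise ValueError("t errors need df > 2 for a finite variance")
        scale = np.sqrt(params.sigma2 * (df - 2) / df)
        eps = scale * rng.standard_t(df, n)
    else:
        raise ValueError(f"unknown error_dist {error_dist!r}")
    rhs = params.alpha + X @ params.beta + weights.sparse @ (X @ params.theta) + eps
    a = (sp.identity(n, format="csc") - params.rho * weights.sparse).tocsc()
    try:
        y = splu(a).solve(rhs)
    except RuntimeError as exc:  # singular factorization
        raise ArithmeticError(
            f"(I - rho W) is singular at rho={params.rho}; "
            "rho is at the boundary of the admissible interval"
        ) from exc
    return y


# ---------------------------------------------------------------------- #
# demonstration preset
# ---------------------------------------------------------------------- #

#: Target marginal (mean, SD) per variable for the demo county table.  These
#: mimic the descriptive statistics of a published 2018 county-level study of
#: mental distress in the contiguous US (N = 3,106 counties).
DEMO_MARGINALS: dict[str, tuple[float, float]] = {
    "mental_distress": (12.21, 1.88),
    "social_capital": (0.00, 1.26),
    "ses_index": (0.00, 1.00),
    "pct_under_18": (22.34, 3.40),
    "pct_over_65": (18.45, 4.51),
    "pct_nh_black": (9.03, 14.37),
    "pct_nh_asian": (1.40, 2.41),
    "pct_hispanic": (9.33, 13.73),
    "pct_not_english": (1.75, 2.93),
    "pct_female": (49.93, 2.22),
    "pct_rural": (58.52, 31.44),
    "income_ratio_80_20": (4.52, 0.74),
}

#: Covariate names of the demo table, in reporting order.
DEMO_COVARIATES = [k for k in DEMO_MARGINALS if k != "mental_distress"]

#: Durbin process used by the demo outcome, before rescaling to the target
#: marginal.  Signs follow the qualitative pattern of the emulated study:
#: negative own and spillover effects of social capital and SES, positive
#: female share; remaining coefficients small.
DEMO_PARAMS = SDMParams(
    rho=0.4,
    alpha=0.0,
    beta=np.array([-0.09, -1.26, 0.02, -0.08, -0.01, -0.01, -0.03, 0.01, 0.11, 0.0, 0.3]),
    theta=np.array([-0.15, -0.3, -0.06, 0.0, 0.0, 0.0, 0.0, 0.0, 0.08, 0.0, -0.4]),
    sigma2=1.0,
)


def demo_county_table(
    weights: SpatialWeights,
    seed=None,
    spatial_rho_x: float = 0.6,
    sc_ses_corr: float = 0.0,
) -> pd.DataFrame:
    """Demonstration area table with county-study-like marginals.

    Covariates are spatially autocorrelated with exact target means/SDs;
    optionally the social-capital column is correlated with the SES index by
    ``sc_ses_corr`` (moderate collinearity, as a VIF screen would tolerate).
    The outcome is drawn from :data:`DEMO_PARAMS`, then rescaled to the
    target marginal and clamped to (0, 100) — demo only, see module note.
    """
    if not weights.standardized:
        weights = weights.row_standardize()
    rng = np.random.default_rng(seed)
    cov_seed, y_seed = rng.integers(2**31 - 1, size=2)
    names = DEMO_COVARIATES
    means = [DEMO_MARGINALS[k][0] for k in names]
    sds = [DEMO_MARGINALS[k][1] for k in names]
    X = simulate_covariates(
        weights, means, sds, spatial_rho_x=spatial_rho_x, names=names, seed=int(cov_seed)
    )
    if sc_ses_corr != 0.0:
        if not -1 < sc_ses_corr < 1:
            raise ValueError("sc_ses_corr must be in (-1, 1)")
        z_sc = (X["social_capital"] - X["social_capital"].mean()) / X["social_capital"].std()
        z_ses = (X["ses_index"] - X["ses_index"].mean()) / X["ses_index"].std()
        # residualize so the achieved sample correlation is exact
        resid = z_sc - z_ses * float(z_ses @ z_sc) / float(z_ses @ z_ses)
        resid = resid / resid.std()
        mixed = sc_ses_corr * z_ses + np.sqrt(1 - sc_ses_corr**2) * resid
        m, s = DEMO_MARGINALS["social_capital"]
        X["social_capital"] = (mixed - mixed.mean()) / mixed.std() * s + m
    y = simulate_sdm_outcome(weights, X.to_numpy(), DEMO_PARAMS, seed=int(y_seed))
    m, s = DEMO_MARGINALS["mental_distress"]
    y = (y - y.mean()) / y.std(ddof=1) * s + m
    y = np.clip(y, 1e-9, 100 - 1e-9)
    out = pd.DataFrame({"id": weights.ids, "mental_distress": y})
    return pd.concat([out, X], axis=1)


def demo_lattice_table(
    rows: int = 30, cols: int = 30, contiguity: str = "queen", seed=None, **kwargs
) -> tuple[pd.DataFrame, SpatialWeights]:
    """Convenience: queen-lattice weights plus a demo table on them."""
    w = lattice_weights(rows, cols, contiguity).row_standardize()
    return demo_county_table(w, seed=seed, **kwargs), w
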