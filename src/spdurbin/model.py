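"""Maximum-likelihood estimation of the spatial Durbin model.

The model for n areas with outcome y, covariates X and row-standardized
weights W is

    (I - rho W) y = alpha 1 + X beta + W X theta + eps,   eps ~ N(0, sigma2 I).

Estimation concentrates the log-likelihood in rho: for a candidate rho the
regression of (I - rho W) y on Z = [1, X, WX] gives alpha, beta, theta and
sigma2(rho) in closed form, leaving the scalar profile

    l(rho) = -(n/2) (log(2 pi sigma2(rho)) + 1) + log|I - rho W|

to be maximized over the admissible interval (1/lambda_min, 1) by bounded
derivative-free (Brent-type) search.  The Jacobian term log|I - rho W| is
evaluated from the precomputed real spectrum of W (symmetrized similar
matrix) when n allows a dense eigen-decomposition, and by sparse LU above
that.  The covariance of (alpha, beta, theta, rho) comes from the
numerically differentiated Hessian of the full log-likelihood at the
optimum.

``model_form`` selects the Durbin model, its spatial-lag special case
(theta = 0, i.e. WX omitted), or plain OLS (rho = theta = 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .weights import DENSE_THRESHOLD, SpatialWeights

#: Offset keeping the rho search strictly inside the open admissible interval.
BOUND_MARGIN = 1e-5

#: An optimum closer than this to the search bound is a boundary failure.
BOUNDARY_TOL = 1e-6

MODEL_FORMS = ("durbin", "lag", "ols")


class ConvergenceError(RuntimeError):
    """Estimation failed in a structured way (boundary optimum, singular
    design, non-finite likelihood); never a silent wrong answer."""


class SpatialDurbin:
    """Spatial Durbin model (and nested spatial-lag / OLS forms).

    Parameters
    ----------
    y : (n,) array
        Outcome (e.g. percent of adults reporting frequent mental distress).
    X : (n, p) array or DataFrame
        Covariates, without a constant column.
    weights : SpatialWeights
        Row-standardized spatial weights; ``n`` must match.
    model_form : {"durbin", "lag", "ols"}
    exog_names : sequence of str, optional
        Covariate names when ``X`` is a bare array.

    Missing values are refused rather than dropped: listwise deletion would
    desynchronize rows from the weights matrix.
    """

    def __init__(self, y, X, weights: SpatialWeights, model_form: str = "durbin",
                 exog_names=None):
        if model_form not in MODEL_FORMS:
            raise ValueError(f"model_form must be one of {MODEL_FORMS}")
        if not isinstance(weights, SpatialWeights):
            raise TypeError("weights must be a SpatialWeights instance")
        if model_form != "ols" and not weights.standardized:
            raise ValueError("spatial forms require a row-standardized W; "
                             "call weights.row_standardize() first")
        if isinstance(X, pd.DataFrame):
            exog_names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        n, p = X.shape
        if y.size != n or n != weights.n:
            raise ValueError(
                f"shape mismatch: y has {y.size}, X has {n} rows, W is {weights.n}"
            )
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError(
                "missing/non-finite values refused: deletion would "
                "desynchronize the weights matrix; clean the table first"
            )
        if n <= 2 * p + 2:
            raise ValueError(f"need n > 2p + 2 observations, got n={n}, p={p}")

        self.y = y
        self.X = X
        self.weights = weights
        self.model_form = model_form
        self.nobs = n
        self.k_exog = p
        self.exog_names = (
            [str(c) for c in exog_names] if exog_names is not None
            else [f"x{j + 1}" for j in range(p)]
        )
        if len(self.exog_names) != p:
            raise ValueError("exog_names length does not match X")

        self.Wy = weights.sparse @ y if model_form != "ols" else np.zeros(n)
        if model_form == "durbin":
            WX = weights.sparse @ X
            self.Z = np.column_stack([np.ones(n), X, WX])
            self.param_names = (
                ["const"] + self.exog_names + [f"W.{c}" for c in self.exog_names]
            )
        else:
            self.Z = np.column_stack([np.ones(n), X])
            self.param_names = ["const"] + self.exog_names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates,
                       weights: SpatialWeights, model_form: str = "durbin"):
        """Build a model from named columns of an area table."""
        covariates = list(covariates)
        missing = [c for c in [outcome, *covariates] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return cls(
            df[outcome].to_numpy(dtype=float),
            df[covariates],
            weights,
            model_form=model_form,
        )

    # ------------------------------------------------------------------ #
    # likelihood machinery
    # ------------------------------------------------------------------ #

    def _projections(self):
        """Closed-form pieces of the concentrated likelihood."""
        Z = self.Z
        d0, res0, rank, _ = np.linalg.lstsq(Z, self.y, rcond=None)
        if rank < Z.shape[1]:
            raise ConvergenceError(
                f"singular design matrix (rank {rank} < {Z.shape[1]})"
            )
        dd = np.linalg.lstsq(Z, self.Wy, rcond=None)[0]
        e0 = self.y - Z @ d0
        ed = self.Wy - Z @ dd
        return d0, dd, e0, ed

    def _logdet(self, rho: float) -> float:
        if self.nobs <= DENSE_THRESHOLD:
            return self.weights.log_det(rho, method="eig")
        return self.weights.log_det(rho, method="lu")

    def _bounds(self) -> tuple[float, float]:
        lo, hi = self.weights.rho_interval()
        return lo + BOUND_MARGIN, hi - BOUND_MARGIN

    def loglik_profile(self, rho_grid) -> np.ndarray:
        """Concentrated log-likelihood on a grid of rho values.

        Every grid point must lie strictly inside the admissible interval.
        """
        rho_grid = np.asarray(rho_grid, dtype=float).ravel()
        lo, hi = self.weights.rho_interval()
        if np.any(rho_grid <= lo) or np.any(rho_grid >= hi):
            raise ValueError(
                f"rho grid must lie strictly inside ({lo:.6f}, {hi:.6f})"
            )
        _, _, e0, ed = self._projections()
        n = self.nobs
        out = np.empty(rho_grid.size)
        for i, rho in enumerate(rho_grid):
            u = e0 - rho * ed
            s2 = (u @ u) / n
            out[i] = -(n / 2) * (np.log(2 * np.pi * s2) + 1) + self._logdet(rho)
        return out

    def _full_loglik(self, delta: np.ndarray, rho: float, sigma2: float) -> float:
        n = self.nobs
        u = self.y - rho * self.Wy - self.Z @ delta
        ld = self._logdet(rho) if self.model_form != "ols" else 0.0
        return float(
            -(n / 2) * np.log(2 * np.pi * sigma2) + ld - (u @ u) / (2 * sigma2)
        )

    # ------------------------------------------------------------------ #
    # estimation
    # ------------------------------------------------------------------ #

    def fit(self, rho_tol: float = 1e-8) -> "SDMResults":
        """Estimate by (concentrated) maximum likelihood.

        Raises :class:`ConvergenceError` on a singular design, a non-finite
        likelihood, or an optimum pinned at the admissible-interval
        boundary.
        """
        n = self.nobs
        if self.model_form == "ols":
            d0, _, e0, _ = self._projections()
            sigma2 = float(e0 @ e0) / n
            llf = self._full_loglik(d0, 0.0, sigma2)
            vcov = self._numeric_vcov(d0, None, sigma2)
            params = pd.Series(d0, index=self.param_names)
            return SDMResults(self, params, sigma2, llf, vcov, converged=True)

        d0, dd, e0, ed = self._projections()
        lo, hi = self._bounds()

        def neg_profile(rho: float) -> float:
            u = e0 - rho * ed
            s2 = (u @ u) / n
            if s2 <= 0 or not np.isfinite(s2):
                return np.inf
            return (n / 2) * (np.log(2 * np.pi * s2) + 1) - self._logdet(rho)

        res = minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": rho_tol},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError("non-finite concentrated likelihood")
        rho = float(res.x)
        if min(rho - lo, hi - rho) < BOUNDARY_TOL:
            raise ConvergenceError(
                f"rho estimate {rho:.6f} pinned at the admissible-interval "
                f"boundary ({lo:.6f}, {hi:.6f}); the model is not identified "
                "on these data"
            )
        delta = d0 - rho * dd
        u = e0 - rho * ed
        sigma2 = float(u @ u) / n
        llf = self._full_loglik(delta, rho, sigma2)
        vcov = self._numeric_vcov(delta, rho, sigma2)
        params = pd.Series(
            np.append(delta, rho), index=self.param_names + ["rho"]
        )
        return SDMResults(
            self, params, sigma2, llf, vcov, converged=True, nit=res.nfev
        )

    def _numeric_vcov(self, delta, rho, sigma2) -> pd.DataFrame:
        """Covariance of (alpha, beta[, theta][, rho]) from the central-
        difference Hessian of the full log-likelihood (relative step 1e-5);
        sigma2 is profiled jointly and then marginalized out of the block."""
        has_rho = rho is not None
        psi = np.concatenate([delta, [rho] if has_rho else [], [sigma2]])
        k = psi.size

        def f(v: np.ndarray) -> float:
            d = v[: delta.size]
            r = float(v[delta.size]) if has_rho else 0.0
            s2 = float(v[-1])
            if s2 <= 0:
                return -np.inf
            if has_rho:
                lo, hi = self.weights.rho_interval()
                if not (lo < r < hi):
                    return -np.inf
            return self._full_loglik(d, r, s2)

        h = 1e-5 * np.maximum(1.0, np.abs(psi))
        H = np.empty((k, k))
        f0 = f(psi)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (f(psi + ei) - 2 * f0 + f(psi - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(psi + ei + ej) - f(psi + ei - ej)
                    - f(psi - ei + ej) + f(psi - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; using pseudo-inverse covariance",
                          UserWarning, stacklevel=2)
            cov = np.linalg.pinv(-H)
        cov = (cov + cov.T) / 2
        names = self.param_names + (["rho"] if has_rho else [])
        block = cov[: len(names), : len(names)]
        if np.any(np.diag(block) < 0):
            warnings.warn(
                "negative Hessian-based variance encountered; "
                "estimates near a likelihood ridge", UserWarning, stacklevel=2
            )
        return pd.DataFrame(block, index=names, columns=names)


class SDMResults:
    """Fitted spatial Durbin model: estimates, covariance, diagnostics.

    Impact decomposition hangs off this object: :meth:`impacts` gives the
    direct/indirect/total effects with Monte-Carlo inference, and
    :meth:`partition_impacts` the neighbor-order spatial profile.
    """

    def __init__(self, model: SpatialDurbin, params: pd.Series, sigma2: float,
                 llf: float, vcov: pd.DataFrame, converged: bool = True,
                 nit: int | None = None):
        self.model = model
        self.params = params
        self.sigma2 = float(sigma2)
        self.llf = float(llf)
        self.vcov = vcov
        self.converged = bool(converged)
        self.nit = nit
        self.nobs = model.nobs
        self.model_form = model.model_form
        self.exog_names = model.exog_names

    # --- parameter views ------------------------------------------------ #

    @property
    def rho(self) -> float:
        return float(self.params.get("rho", 0.0))

    @property
    def alpha(self) -> float:
        return float(self.params["const"])

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.exog_names].to_numpy()

    @property
    def theta(self) -> np.ndarray:
        if self.model_form == "durbin":
            return self.params[[f"W.{c}" for c in self.exog_names]].to_numpy()
        return np.zeros(len(self.exog_names))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.vcov.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params[self.vcov.index] / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.vcov.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = norm.ppf(1 - alpha / 2)
        lo = self.params[self.vcov.index] - q * self.bse
        hi = self.params[self.vcov.index] + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # --- impacts -------------------------------------------------------- #

    def impacts(self, draws: int = 1000, seed: int = 0, **kwargs):
        """Direct/indirect/total effects; see :func:`spdurbin.impacts.summarize_impacts`."""
        from .impacts import summarize_impacts

        return summarize_impacts(self, draws=draws, seed=seed, **kwargs)

    def partition_impacts(self, Q: int = 4, draws: int = 1000, seed: int = 0,
                          **kwargs):
        """Neighbor-order spatial profile; see :func:`spdurbin.impacts.partition_impacts`."""
        from .impacts import partition_impacts

        return partition_impacts(self, Q=Q, draws=draws, seed=seed, **kwargs)

    # --- reporting ------------------------------------------------------ #

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "n": self.nobs,
            "params": self.params.to_dict(),
            "sigma2": self.sigma2,
            "loglik": self.llf,
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "vcov": {
                "names": list(self.vcov.index),
                "matrix": self.vcov.to_numpy().tolist(),
            },
            "converged": self.converged,
        }

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels spirit."""
        lines = [
            f"Spatial {'Durbin' if self.model_form == 'durbin' else self.model_form.upper()} "
            f"model (ML), n = {self.nobs}",
            f"log-likelihood = {self.llf:.4f}   sigma2 = {self.sigma2:.6f}",
            "-" * 64,
            f"{'':<22}{'coef':>10}{'std err':>10}{'z':>9}{'P>|z|':>9}",
        ]
        for name in self.vcov.index:
            lines.append(
                f"{name:<22}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>9.3f}"
            )
        lines.append("-" * 64)
        return "\n".join(lines)


def fit_sdm(table: pd.DataFrame, weights: SpatialWeights, outcome: str,
            covariates, model_form: str = "durbin") -> SDMResults:
    """One-call convenience: build :class:`SpatialDurbin` from a table and fit."""
    return SpatialDurbin.from_dataframe(
        table, outcome, covariates, weights, model_form=model_form
    ).fit()
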