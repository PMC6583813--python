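"""Direct/indirect effect decomposition and neighbor-order partitioning.

In a spatial autoregressive model the marginal effect of covariate r is the
n x n matrix

    S_r(W) = (I - rho W)^{-1} (beta_r I + theta_r W),

whose diagonal mean is the *direct* effect (own-area), off-diagonal mean the
*indirect* (spillover) effect, and row-sum mean the *total* effect, so that
total = direct + indirect by construction.  Production code never forms the
inverse: quantities come from sparse LU solves against identity / W columns.

Because (I - rho W)^{-1} = I + rho W + rho^2 W^2 + ..., the effects can be
partitioned over neighbor orders: the order-q term rho^q W^q (beta_r I +
theta_r W) collects the contribution of q-step neighbors, giving a "spatial
profile" of how a covariate's influence decays with adjacency order.  Note
the order-0 term beta_r I + theta_r W already has off-diagonal mass
(indirect_0 = theta_r for row-standardized W): spillover exists even before
the autoregressive feedback.  The alternative grouping by literal powers of
W (which forces indirect_0 = 0) is available via ``grouping="by_power"``.

Inference is parametric Monte Carlo: parameter vectors are sampled from the
asymptotic normal of the ML estimates (draws with rho outside the
admissible interval rejected), effects recomputed per draw, and two-sided
p-values reported from the draw mean/SD (normal approximation; empirical
quantiles by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .model import SDMResults
from .weights import DENSE_THRESHOLD, SpatialWeights

#: Default / ceiling on the partition order.
DEFAULT_Q = 4
MAX_Q = 10

_CHUNK = 256  # columns per block in the solve-based trace path


# ---------------------------------------------------------------------- #
# reporting arithmetic (also used to tabulate externally supplied effects)
# ---------------------------------------------------------------------- #

def effects_table(direct, indirect) -> pd.DataFrame:
    """Assemble a direct/indirect/total effects table.

    ``direct`` and ``indirect`` are aligned mappings or Series per
    covariate; the total is their sum.  This is the reporting arithmetic
    used for every effects table the package prints.
    """
    direct = pd.Series(direct, dtype=float)
    indirect = pd.Series(indirect, dtype=float).reindex(direct.index)
    return pd.DataFrame(
        {"direct": direct, "indirect": indirect, "total": direct + indirect}
    )


def spillover_ratio(indirect: float, direct: float) -> float:
    """Indirect-to-direct effect ratio (how much stronger the spillover is)."""
    return indirect / direct


def order_share(component_at_order: float, component_total: float) -> float:
    """Fraction of a direct or indirect effect contributed at one order."""
    return component_at_order / component_total


# ---------------------------------------------------------------------- #
# impact matrix and solve-based point estimates
# ---------------------------------------------------------------------- #

def _resolve_r(results: SDMResults, r) -> int:
    if isinstance(r, str):
        return results.exog_names.index(r)
    return int(r)


def _check_interior(results: SDMResults) -> None:
    lo, hi = results.model.weights.rho_interval()
    if not (lo + 1e-9 < results.rho < hi - 1e-9):
        raise ArithmeticError(
            f"rho={results.rho} at the boundary of ({lo:.6f}, {hi:.6f})"
        )


def impact_matrix(results: SDMResults, r) -> np.ndarray:
    """Full n x n effect matrix S_r = (I - rho W)^{-1}(beta_r I + theta_r W).

    Computed by LU solves against the columns of beta_r I + theta_r W
    (never an explicit inverse).  Dense output, so refused above the dense
    threshold.
    """
    w = results.model.weights
    n = w.n
    if n > DENSE_THRESHOLD:
        raise ValueError(f"dense impact matrix refused for n={n} > {DENSE_THRESHOLD}")
    _check_interior(results)
    r = _resolve_r(results, r)
    b = results.beta[r] * sp.identity(n, format="csc") + results.theta[r] * w.sparse
    if results.rho == 0:
        return np.asarray(b.todense())
    a = (sp.identity(n, format="csc") - results.rho * w.sparse).tocsc()
    return splu(a).solve(np.asarray(b.todense()))


def _solve_traces(weights: SpatialWeights, rho: float):
    """tr(A^{-1}), tr(A^{-1}W), 1'A^{-1}1, 1'A^{-1}W1 for A = I - rho W,
    via chunked LU solves (the production path for point estimates)."""
    n = weights.n
    w = weights.sparse
    a = (sp.identity(n, format="csc") - rho * w).tocsc()
    lu = splu(a)
    tr_i = 0.0
    tr_w = 0.0
    wcsc = w.tocsc()
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        block = np.zeros((n, stop - start))
        block[np.arange(start, stop), np.arange(stop - start)] = 1.0
        xi = lu.solve(block)
        tr_i += float(xi[np.arange(start, stop), np.arange(stop - start)].sum())
        xw = lu.solve(np.asarray(wcsc[:, start:stop].todense()))
        tr_w += float(xw[np.arange(start, stop), np.arange(stop - start)].sum())
    ones = np.ones(n)
    v = lu.solve(ones, trans="T")
    sum_i = float(v @ ones)
    sum_w = float(v @ (w @ ones))
    return tr_i, tr_w, sum_i, sum_w


# ---------------------------------------------------------------------- #
# Monte-Carlo parameter draws
# ---------------------------------------------------------------------- #

def _draw_parameters(results: SDMResults, draws: int, seed):
    """Sample (beta, theta, rho) from the asymptotic normal of the fit,
    rejecting draws with rho outside the admissible interval."""
    rng = np.random.default_rng(seed)
    names = list(results.vcov.index)
    mean = results.params[names].to_numpy()
    cov = results.vcov.to_numpy()
    lo, hi = results.model.weights.rho_interval()
    has_rho = "rho" in names
    rho_ix = names.index("rho") if has_rho else None

    kept = []
    proposed = 0
    accepted = 0
    while accepted < draws:
        m = max(draws - accepted, 64)
        sample = rng.multivariate_normal(mean, cov, size=m, method="svd")
        proposed += m
        if has_rho:
            ok = (sample[:, rho_ix] > lo) & (sample[:, rho_ix] < hi)
            sample = sample[ok]
        kept.append(sample)
        accepted += len(sample)
        if proposed > 100 * draws:
            raise ArithmeticError(
                "Monte-Carlo rejection rate too high; covariance of rho "
                "spans the whole admissible interval"
            )
    sample = np.concatenate(kept)[:draws]
    rejection_rate = 1.0 - accepted / proposed
    if rejection_rate > 0.10:
        warnings.warn(
            f"{rejection_rate:.1%} of Monte-Carlo draws rejected for "
            "inadmissible rho", UserWarning, stacklevel=3,
        )

    p = len(results.exog_names)
    frame = pd.DataFrame(sample, columns=names)
    betas = frame[results.exog_names].to_numpy()
    if results.model_form == "durbin":
        thetas = frame[[f"W.{c}" for c in results.exog_names]].to_numpy()
    else:
        thetas = np.zeros((draws, p))
    rhos = frame["rho"].to_numpy() if has_rho else np.zeros(draws)
    return betas, thetas, rhos, rejection_rate


def _eigen_trace_terms(weights: SpatialWeights, rhos: np.ndarray):
    """Per-draw tr((I-rho W)^{-1}) and tr((I-rho W)^{-1} W) from the exact
    eigenvalue identities sum 1/(1-rho*lam) and sum lam/(1-rho*lam)."""
    lam = weights.eigenvalues()
    m = 1.0 / (1.0 - np.outer(rhos, lam))
    return m.sum(axis=1), (m * lam).sum(axis=1)


def _draw_sums(weights: SpatialWeights, rhos: np.ndarray):
    """Per-draw 1'(I-rho W)^{-1}1 and 1'(I-rho W)^{-1}W1.

    For island-free row-standardized W both equal n/(1-rho) in closed form;
    with islands each draw takes one sparse solve.
    """
    n = weights.n
    if weights.standardized and weights.islands.size == 0:
        s = n / (1.0 - rhos)
        return s, s
    w = weights.sparse
    ones = np.ones(n)
    w1 = w @ ones
    sum_i = np.empty(rhos.size)
    sum_w = np.empty(rhos.size)
    ident = sp.identity(n, format="csc")
    for d, rho in enumerate(rhos):
        v = splu((ident - rho * w).tocsc()).solve(ones, trans="T")
        sum_i[d] = v @ ones
        sum_w[d] = v @ w1
    return sum_i, sum_w


def _mc_pvalues(draw_matrix: np.ndarray, method: str):
    """Two-sided p-values per column of a draws x p matrix."""
    mean = draw_matrix.mean(axis=0)
    sd = draw_matrix.std(axis=0, ddof=1)
    if method == "normal":
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
        p = 2 * norm.sf(np.abs(z))
    elif method == "empirical":
        d = draw_matrix.shape[0]
        n_le = (draw_matrix <= 0).sum(axis=0)
        n_ge = (draw_matrix >= 0).sum(axis=0)
        p = np.minimum(1.0, 2 * (np.minimum(n_le, n_ge) + 1) / (d + 1))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return mean, sd, p


# ---------------------------------------------------------------------- #
# summaries
# ---------------------------------------------------------------------- #

@dataclass
class ImpactSummary:
    """Direct/indirect/total effects with Monte-Carlo dispersion.

    ``frame`` has one row per covariate and, for each component in
    (direct, indirect, total), the point estimate plus ``*_mc_mean``,
    ``*_mc_sd``, ``*_p`` and ``*_sig`` (significant at alpha = 0.05).
    """

    frame: pd.DataFrame
    draws: int
    seed: int | None
    rejection_rate: float
    alpha: float = 0.05

    def table(self) -> pd.DataFrame:
        """Compact reporting table: direct, indirect, total, significance."""
        out = self.frame[["direct", "indirect", "total"]].copy()
        for c in ("direct", "indirect", "total"):
            out[f"{c}_sig"] = self.frame[f"{c}_sig"]
        return out

    def summary(self) -> str:
        lines = [
            f"Impact decomposition ({self.draws} Monte-Carlo draws, "
            f"seed={self.seed}, rejection rate {self.rejection_rate:.1%})",
            f"{'variable':<22}{'direct':>10}{'indirect':>10}{'total':>10}",
        ]
        for name, row in self.frame.iterrows():
            def star(c):
                return "*" if row[f"{c}_sig"] else " "
            lines.append(
                f"{name:<22}{row['direct']:>9.4f}{star('direct')}"
                f"{row['indirect']:>9.4f}{star('indirect')}"
                f"{row['total']:>9.4f}{star('total')}"
            )
        lines.append("* significant at P < .05")
        return "\n".join(lines)


def summarize_impacts(
    results: SDMResults,
    draws: int = 1000,
    seed: int = 0,
    pvalue_method: str = "normal",
    alpha: float = 0.05,
) -> ImpactSummary:
    """Direct, indirect and total effects of every covariate, with inference.

    Point estimates use the solve-based production path; per-draw effects
    use the eigenvalue trace identities (exact for symmetric-adjacency W).
    ``draws`` must be at least 100 for a usable Monte-Carlo summary.
    """
    if draws < 100:
        raise ValueError("draws must be >= 100")
    if not results.converged:
        raise ValueError("cannot summarize impacts of a non-converged fit")
    _check_interior(results)
    w = results.model.weights
    n = w.n
    beta, theta, rho = results.beta, results.theta, results.rho

    tr_i, tr_w, sum_i, sum_w = _solve_traces(w, rho)
    direct = (beta * tr_i + theta * tr_w) / n
    total = (beta * sum_i + theta * sum_w) / n
    indirect = total - direct

    betas, thetas, rhos, rejection = _draw_parameters(results, draws, seed)
    t1, t2 = _eigen_trace_terms(w, rhos)
    s1, s2 = _draw_sums(w, rhos)
    d_draws = (betas * t1[:, None] + thetas * t2[:, None]) / n
    tot_draws = (betas * s1[:, None] + thetas * s2[:, None]) / n
    i_draws = tot_draws - d_draws

    data = {"direct": direct, "indirect": indirect, "total": total}
    frame = pd.DataFrame(data, index=results.exog_names)
    for name, mat in (("direct", d_draws), ("indirect", i_draws), ("total", tot_draws)):
        m, s, p = _mc_pvalues(mat, pvalue_method)
        frame[f"{name}_mc_mean"] = m
        frame[f"{name}_mc_sd"] = s
        frame[f"{name}_p"] = p
        frame[f"{name}_sig"] = p < alpha
    return ImpactSummary(
        frame=frame, draws=draws, seed=seed, rejection_rate=rejection, alpha=alpha
    )


# ---------------------------------------------------------------------- #
# neighbor-order partitioning
# ---------------------------------------------------------------------- #

@dataclass
class ImpactPartition:
    """Per-order contributions to direct and indirect effects.

    ``direct``/``indirect`` are covariate x order (W_0..W_Q) tables of
    point estimates; ``*_p`` hold the Monte-Carlo p-values; ``remainder``
    is the total effect minus all terms up to order Q (the tail of the
    geometric expansion).
    """

    direct: pd.DataFrame
    indirect: pd.DataFrame
    direct_p: pd.DataFrame
    indirect_p: pd.DataFrame
    remainder: pd.Series
    Q: int
    grouping: str
    draws: int
    seed: int | None
    alpha: float = 0.05

    def table(self) -> pd.DataFrame:
        """Wide reporting table: direct then indirect blocks, W_0..W_Q."""
        d = self.direct.add_prefix("direct_")
        i = self.indirect.add_prefix("indirect_")
        return pd.concat([d, i], axis=1)

    def plot_profile(self, variable: str, ax=None):
        """Bar profile of a covariate's per-order contributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        orders = np.arange(self.Q + 1)
        width = 0.4
        ax.bar(orders - width / 2, self.direct.loc[variable], width, label="direct")
        ax.bar(orders + width / 2, self.indirect.loc[variable], width, label="indirect")
        ax.set_xticks(orders)
        ax.set_xticklabels([f"W{q}" for q in orders])
        ax.set_xlabel("neighbor order")
        ax.set_ylabel("effect contribution")
        ax.set_title(f"Spatial profile: {variable}")
        ax.legend()
        return ax


def _order_terms(weights: SpatialWeights, Q: int):
    """tr(W^q) (eigenvalues when available, sparse powers otherwise) and
    1'W^q 1 (iterated mat-vec) for q = 0..Q+1."""
    n = weights.n
    qmax = Q + 1
    if n <= DENSE_THRESHOLD:
        lam = weights.eigenvalues()
        traces = np.array([np.sum(lam**q) for q in range(qmax + 1)])
        traces[0] = float(n)
    else:
        traces = np.empty(qmax + 1)
        acc = sp.identity(n, format="csr")
        for q in range(qmax + 1):
            traces[q] = acc.diagonal().sum()
            if q < qmax:
                acc = acc @ weights.sparse
    colsums = np.empty(qmax + 1)
    v = np.ones(n)
    for q in range(qmax + 1):
        colsums[q] = v.sum()
        v = weights.sparse.T @ v  # 1'W^{q+1} = (W' (W'^q 1))'
    return traces, colsums


def partition_impacts(
    results: SDMResults,
    Q: int = DEFAULT_Q,
    draws: int = 1000,
    seed: int = 0,
    grouping: str = "resolvent",
    max_Q: int = MAX_Q,
    pvalue_method: str = "normal",
    alpha: float = 0.05,
) -> ImpactPartition:
    """Partition direct and indirect effects over neighbor orders 0..Q.

    With the default ``grouping="resolvent"`` the order-q term is
    rho^q W^q (beta_r I + theta_r W), the q-th term of the geometric
    expansion of S_r(W); ``grouping="by_power"`` instead groups by literal
    powers of W (coefficient of W^q is rho^q beta_r + rho^{q-1} theta_r),
    which forces the order-0 indirect contribution to zero.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if Q > max_Q:
        raise ValueError(f"Q={Q} exceeds configured maximum {max_Q}")
    if grouping not in ("resolvent", "by_power"):
        raise ValueError(f"unknown grouping {grouping!r}")
    _check_interior(results)
    w = results.model.weights
    if abs(results.rho) >= 1 and w.standardized:
        raise ArithmeticError("partitioning requires |rho| < 1")
    n = w.n
    beta, theta, rho = results.beta, results.theta, results.rho
    names = results.exog_names
    traces, colsums = _order_terms(w, Q)

    def terms(b, t, r):
        """direct/total per order for parameter arrays; r may be a vector of
        draws (then b, t are draws x p)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        b = np.atleast_2d(b)
        t = np.atleast_2d(t)
        d = np.empty((r.size, b.shape[1], Q + 1))
        tot = np.empty_like(d)
        for q in range(Q + 1):
            rq = r**q
            if grouping == "resolvent":
                d[:, :, q] = rq[:, None] * (b * traces[q] + t * traces[q + 1]) / n
                tot[:, :, q] = rq[:, None] * (b * colsums[q] + t * colsums[q + 1]) / n
            else:
                if q == 0:
                    coef = b
                else:
                    coef = rq[:, None] * b + (r ** (q - 1))[:, None] * t
                d[:, :, q] = coef * traces[q] / n
                tot[:, :, q] = coef * colsums[q] / n
        return d, tot

    d_pt, tot_pt = terms(beta, theta, rho)
    d_pt, tot_pt = d_pt[0], tot_pt[0]
    i_pt = tot_pt - d_pt

    cols = [f"W_{q}" for q in range(Q + 1)]
    direct = pd.DataFrame(d_pt, index=names, columns=cols)
    indirect = pd.DataFrame(i_pt, index=names, columns=cols)

    # exact total (solve-based) for the remainder of the geometric tail
    tr_i, tr_w, sum_i, sum_w = _solve_traces(w, rho)
    total_exact = (beta * sum_i + theta * sum_w) / n
    remainder = pd.Series(
        total_exact - (d_pt + i_pt).sum(axis=1), index=names, name="remainder"
    )

    betas, thetas, rhos, _ = _draw_parameters(results, draws, seed)
    d_draws, tot_draws = terms(betas, thetas, rhos)
    i_draws = tot_draws - d_draws
    dp = np.empty((len(names), Q + 1))
    ip = np.empty_like(dp)
    for q in range(Q + 1):
        _, _, dp[:, q] = _mc_pvalues(d_draws[:, :, q], pvalue_method)
        _, _, ip[:, q] = _mc_pvalues(i_draws[:, :, q], pvalue_method)
    return ImpactPartition(
        direct=direct,
        indirect=indirect,
        direct_p=pd.DataFrame(dp, index=names, columns=cols),
        indirect_p=pd.DataFrame(ip, index=names, columns=cols),
        remainder=remainder,
        Q=Q,
        grouping=grouping,
        draws=draws,
        seed=seed,
        alpha=alpha,
    )
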