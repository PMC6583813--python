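"""Exploratory spatial data analysis: global Moran's I and quintile classes.

Moran's I measures global spatial autocorrelation of an area attribute,

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,    z = x - mean(x),

with expectation -1/(n-1) under spatial randomness.  Inference is by random
permutation of the attribute over areas: the two-sided pseudo p-value is

    p = (#{|I_perm - E[I]| >= |I_obs - E[I]|} + 1) / (permutations + 1).

Quintile classification (labels 1-5 by empirical quantile, ties sharing a
class) reproduces the usual choropleth-map binning of county attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .weights import SpatialWeights


@dataclass
class MoranResult:
    """Observed Moran's I with its permutation-test summary."""

    I: float
    expected: float       # -1/(n-1)
    p_perm: float         # two-sided pseudo p-value, >= 1/(permutations+1)
    permutations: int
    seed: int | None
    perm_mean: float      # mean of the permutation distribution
    perm_sd: float

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "expected": self.expected,
            "p_perm": self.p_perm,
            "permutations": self.permutations,
            "seed": self.seed,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
        }


def morans_i(
    x, weights: SpatialWeights, permutations: int = 999, seed=None
) -> MoranResult:
    """Global Moran's I of ``x`` with a two-sided permutation test.

    Raises ``ValueError`` for constant ``x`` or n < 3.  Island areas carry
    no weight and are therefore excluded from S0 (warned).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("morans_i needs at least 3 areas")
    if n != weights.n:
        raise ValueError(f"x has {n} values but W is {weights.n}x{weights.n}")
    if not np.isfinite(x).all():
        raise ValueError("x contains missing/non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for a constant attribute")
    if weights.islands.size:
        warnings.warn(
            f"{weights.islands.size} island(s) contribute no weight to S0",
            UserWarning,
            stacklevel=2,
        )
    if permutations < 1:
        raise ValueError("permutations must be >= 1")

    w = weights.sparse
    s0 = weights.s0
    z = x - x.mean()
    denom = float(z @ z)
    i_obs = n / s0 * float(z @ (w @ z)) / denom

    rng = np.random.default_rng(seed)
    # vectorized permutations: each row an independent shuffle of z
    order = np.argsort(rng.random((permutations, n)), axis=1)
    zp = z[order]
    num = np.einsum("ij,ij->i", zp, (w @ zp.T).T)
    i_perm = n / s0 * num / denom

    expected = -1.0 / (n - 1)
    extreme = np.abs(i_perm - expected) >= np.abs(i_obs - expected)
    p = (int(extreme.sum()) + 1) / (permutations + 1)
    return MoranResult(
        I=float(i_obs),
        expected=expected,
        p_perm=float(p),
        permutations=permutations,
        seed=None if seed is None else int(seed),
        perm_mean=float(i_perm.mean()),
        perm_sd=float(i_perm.std(ddof=1)),
    )


def quintile_classes(x, method: str = "linear") -> np.ndarray:
    """Quintile class labels 1..5 by empirical quantiles (type-7 default).

    Equal values always share a class.  A constant vector yields all-1
    labels with a degenerate-distribution warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("quintile_classes needs at least 5 values")
    if np.ptp(x) == 0:
        warnings.warn(
            "degenerate distribution: all values equal, single class assigned",
            UserWarning,
            stacklevel=2,
        )
        return np.ones(x.size, dtype=int)
    cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8], method=method)
    return 1 + np.searchsorted(cuts, x, side="left").astype(int)
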