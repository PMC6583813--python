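import numpy as np
import pandas as pd
import pytest

import spdurbin as sd
from spdurbin.impacts import _solve_traces


def dense_impact(res, r):
    """Brute-force oracle: explicit dense inverse."""
    w = res.model.weights.sparse.toarray()
    n = w.shape[0]
    return np.linalg.inv(np.eye(n) - res.rho * w) @ (
        res.beta[r] * np.eye(n) + res.theta[r] * w
    )


def test_rho_zero_impact_matrix_is_exact(queen5, forge):
    res = forge(queen5, beta=[0.7], theta=[-0.3], rho=0.0)
    S = sd.impact_matrix(res, 0)
    expected = 0.7 * np.eye(25) - 0.3 * queen5.sparse.toarray()
    assert np.allclose(S, expected, atol=1e-14)


def test_theta_zero_row_sums_geometric(queen5, forge):
    res = forge(queen5, beta=[0.8], theta=[0.0], rho=0.5)
    S = sd.impact_matrix(res, 0)
    assert np.allclose(S.sum(axis=1), 0.8 / (1 - 0.5), atol=1e-10)


def test_impact_matrix_matches_dense_oracle(queen5, forge):
    res = forge(queen5, beta=[-0.1], theta=[-0.25], rho=0.4)
    assert np.abs(sd.impact_matrix(res, 0) - dense_impact(res, 0)).max() < 1e-10


def test_solve_traces_match_dense(queen10, forge):
    res = forge(queen10, beta=[1.0], theta=[0.5], rho=0.45)
    tr_i, tr_w, sum_i, sum_w = _solve_traces(queen10, 0.45)
    winv = np.linalg.inv(np.eye(100) - 0.45 * queen10.sparse.toarray())
    assert tr_i == pytest.approx(np.trace(winv), abs=1e-10)
    assert tr_w == pytest.approx(np.trace(winv @ queen10.sparse.toarray()), abs=1e-10)
    assert sum_i == pytest.approx(winv.sum(), abs=1e-8)
    assert sum_w == pytest.approx((winv @ queen10.sparse.toarray()).sum(), abs=1e-8)


def test_rho_zero_direct_is_beta_indirect_is_theta(queen5, forge):
    res = forge(queen5, beta=[0.7, -1.2], theta=[-0.3, 0.4], rho=0.0)
    imp = sd.summarize_impacts(res, draws=200, seed=1)
    assert np.allclose(imp.frame["direct"], [0.7, -1.2], atol=1e-12)
    assert np.allclose(imp.frame["indirect"], [-0.3, 0.4], atol=1e-12)


def test_summary_matches_dense_oracle_and_signs(sim_fit_10x10):
    res, truth = sim_fit_10x10
    imp = sd.summarize_impacts(res, draws=200, seed=2)
    S = dense_impact(res, 0)
    n = S.shape[0]
    direct_o = np.trace(S) / n
    indirect_o = (S.sum() - np.trace(S)) / n
    row = imp.frame.loc["social_capital"]
    assert row["direct"] == pytest.approx(direct_o, abs=1e-10)
    assert row["indirect"] == pytest.approx(indirect_o, abs=1e-10)
    ratio = sd.spillover_ratio(row["indirect"], row["direct"])
    assert ratio == pytest.approx(indirect_o / direct_o, abs=1e-8)
    assert row["direct"] < 0 and row["indirect"] < 0


def test_total_is_direct_plus_indirect(sim_fit_10x10):
    res, _ = sim_fit_10x10
    imp = sd.summarize_impacts(res, draws=200, seed=3)
    gap = imp.frame["total"] - imp.frame["direct"] - imp.frame["indirect"]
    assert np.abs(gap).max() < 1e-10
    assert ((imp.frame["direct_p"] < 0.05) == imp.frame["direct_sig"]).all()


def test_published_effects_table_arithmetic():
    # feeding a published direct/indirect decomposition through the
    # reporting arithmetic reproduces its printed totals and ratios
    tab = sd.effects_table(
        direct={"social_capital": -0.087, "ses_index": -1.263},
        indirect={"social_capital": -0.234, "ses_index": -0.532},
    )
    assert round(tab.loc["social_capital", "total"], 3) == -0.321
    assert round(tab.loc["ses_index", "total"], 3) == -1.795
    assert round(sd.spillover_ratio(-0.234, -0.087), 2) == 2.69


def test_partition_order_zero_identities(sim_fit_10x10):
    res, _ = sim_fit_10x10
    part = res.partition_impacts(Q=4, draws=200, seed=4)
    assert np.allclose(part.direct["W_0"], res.beta, atol=1e-12)
    assert np.allclose(part.indirect["W_0"], res.theta, atol=1e-12)


def test_partition_series_converges_to_oracle(sim_fit_10x10):
    res, _ = sim_fit_10x10
    assert abs(res.rho) < 0.7
    part = res.partition_impacts(Q=50, draws=200, seed=5, max_Q=50)
    S = dense_impact(res, 0)
    n = S.shape[0]
    assert part.direct.loc["social_capital"].sum() == pytest.approx(
        np.trace(S) / n, abs=1e-8
    )
    assert abs(part.remainder["social_capital"]) < 1e-8


def test_partition_tail_bound(sim_fit_10x10):
    res, _ = sim_fit_10x10
    Q = 4
    part = res.partition_impacts(Q=Q, draws=200, seed=6)
    imp = sd.summarize_impacts(res, draws=200, seed=6)
    rho = abs(res.rho)
    for r, name in enumerate(res.exog_names):
        tail = abs(imp.frame.loc[name, "direct"] - part.direct.loc[name].sum())
        bound = (abs(res.beta[r]) * rho ** (Q + 1) / (1 - rho)
                 + abs(res.theta[r]) * rho ** Q * rho / (1 - rho))
        assert tail <= bound + 1e-12


def test_partition_alternative_grouping(sim_fit_10x10):
    res, _ = sim_fit_10x10
    part = res.partition_impacts(Q=3, draws=200, seed=7, grouping="by_power")
    assert np.allclose(part.indirect["W_0"], 0.0, atol=1e-14)
    assert np.allclose(part.direct["W_0"], res.beta, atol=1e-12)
    # both groupings resum to the same effects
    part_r = res.partition_impacts(Q=50, draws=200, seed=7, max_Q=50)
    part_p = res.partition_impacts(Q=50, draws=200, seed=7, max_Q=50,
                                   grouping="by_power")
    assert np.allclose(part_r.direct.sum(axis=1), part_p.direct.sum(axis=1),
                       atol=1e-8)


def test_spatial_lag_total_closed_form(queen5, forge):
    res = forge(queen5, beta=[0.9], theta=None, rho=0.35, model_form="lag")
    imp = sd.summarize_impacts(res, draws=200, seed=8)
    assert imp.frame.loc["x1", "total"] == pytest.approx(0.9 / (1 - 0.35),
                                                         abs=1e-10)


def test_mc_sd_stable_under_doubling(sim_fit_10x10):
    res, _ = sim_fit_10x10
    a = sd.summarize_impacts(res, draws=5000, seed=10)
    b = sd.summarize_impacts(res, draws=10000, seed=11)
    rel = np.abs(b.frame["direct_mc_sd"] / a.frame["direct_mc_sd"] - 1)
    assert rel.max() < 0.05


def test_mc_rejection_warns(queen5, forge):
    res = forge(queen5, beta=[1.0], theta=[0.0], rho=0.9, vcov_scale=0.5)
    with pytest.warns(UserWarning, match="rejected"):
        sd.summarize_impacts(res, draws=200, seed=12)


def test_validation_errors(sim_fit_10x10):
    res, _ = sim_fit_10x10
    with pytest.raises(ValueError, match="draws"):
        sd.summarize_impacts(res, draws=10)
    with pytest.raises(ValueError, match="Q"):
        res.partition_impacts(Q=-1)
    with pytest.raises(ValueError, match="maximum"):
        res.partition_impacts(Q=11)
    with pytest.raises(ValueError, match="grouping"):
        res.partition_impacts(Q=2, grouping="nope")


def test_empirical_pvalues_in_range(sim_fit_10x10):
    res, _ = sim_fit_10x10
    imp = sd.summarize_impacts(res, draws=500, seed=13,
                               pvalue_method="empirical")
    p = imp.frame[["direct_p", "indirect_p", "total_p"]].to_numpy()
    assert ((p > 0) & (p <= 1)).all()
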