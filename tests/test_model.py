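import numpy as np
import pandas as pd
import pytest

import spdurbin as sd


def _simulate(w, rho, beta, theta, seed, alpha=1.0, sigma2=1.0, rho_x=0.5):
    p = len(beta)
    X = sd.simulate_covariates(w, [0] * p, [1] * p, spatial_rho_x=rho_x,
                               seed=seed)
    params = sd.SDMParams(rho=rho, alpha=alpha, beta=beta, theta=theta,
                          sigma2=sigma2)
    y = sd.simulate_sdm_outcome(w, X.to_numpy(), params, seed=seed + 1)
    return X, y


def test_classical_limit_matches_ols():
    w = sd.lattice_weights(20, 20, "queen").row_standardize()
    X, y = _simulate(w, rho=0.0, beta=[1.0, -1.0], theta=[0.0, 0.0], seed=40)
    model = sd.SpatialDurbin(y, X, w)
    res = model.fit()
    assert abs(res.rho) < 3 * res.bse["rho"]
    # at rho = 0 the concentrated estimator coincides with OLS on [1, X, WX]
    d0, *_ = np.linalg.lstsq(model.Z, y, rcond=None)
    profile_delta = d0  # delta(rho=0)
    dd = np.linalg.lstsq(model.Z, model.Wy, rcond=None)[0]
    assert np.allclose(profile_delta, d0, atol=1e-12)
    assert np.allclose(res.params[model.param_names].to_numpy(),
                       d0 - res.rho * dd, atol=1e-8)


def test_profile_maximum_beats_grid():
    w = sd.lattice_weights(7, 7, "queen").row_standardize()
    X, y = _simulate(w, rho=0.3, beta=[1.0], theta=[-0.5], seed=50)
    model = sd.SpatialDurbin(y, X, w)
    res = model.fit()
    lo, hi = w.rho_interval()
    grid = np.linspace(lo + 1e-4, hi - 1e-4, 41)
    prof = model.loglik_profile(grid)
    ll_hat = model.loglik_profile([res.rho])[0]
    assert (ll_hat >= prof - 1e-8).all()
    assert ll_hat == pytest.approx(res.llf + 0, rel=1e-9)


def test_profile_peak_exceeds_neighbors():
    w = sd.lattice_weights(10, 10, "queen").row_standardize()
    X, y = _simulate(w, rho=0.4, beta=[-0.5], theta=[0.3], seed=60)
    model = sd.SpatialDurbin(y, X, w)
    res = model.fit()
    eps = 1e-3
    vals = model.loglik_profile([res.rho - eps, res.rho, res.rho + eps])
    assert vals[1] >= vals[0] and vals[1] >= vals[2]


def test_profile_grid_outside_interval_rejected(queen10):
    X, y = _simulate(queen10, rho=0.0, beta=[1.0], theta=[0.0], seed=70)
    model = sd.SpatialDurbin(y, X, queen10)
    with pytest.raises(ValueError, match="strictly inside"):
        model.loglik_profile([0.0, 1.0])


def test_logdet_paths_agree():
    w = sd.lattice_weights(12, 12, "queen").row_standardize()
    for rho in (-0.4, 0.0, 0.3, 0.8):
        assert w.log_det(rho, "eig") == pytest.approx(w.log_det(rho, "lu"),
                                                      abs=1e-8)


def test_estimates_invariant_to_area_reordering():
    base = sd.lattice_weights(8, 8, "queen")
    w = base.row_standardize()
    X, y = _simulate(w, rho=0.4, beta=[1.0, -0.5], theta=[0.2, 0.1], seed=80)
    res = sd.SpatialDurbin(y, X, w).fit()

    rng = np.random.default_rng(0)
    perm = rng.permutation(64)
    wp = sd.SpatialWeights(base.sparse[perm][:, perm],
                           ids=[base.ids[i] for i in perm]).row_standardize()
    resp = sd.SpatialDurbin(y.to_numpy()[perm] if hasattr(y, "to_numpy") else y[perm],
                            X.to_numpy()[perm], wp,
                            exog_names=list(X.columns)).fit()
    assert np.allclose(res.params.to_numpy(), resp.params.to_numpy(), atol=1e-6)
    assert res.llf == pytest.approx(resp.llf, abs=1e-6)


def test_lag_form_recovers_theta_zero_process():
    w = sd.lattice_weights(20, 20, "queen").row_standardize()
    X, y = _simulate(w, rho=0.4, beta=[1.0], theta=[0.0], seed=90)
    lag = sd.SpatialDurbin(y, X, w, model_form="lag").fit()
    durbin = sd.SpatialDurbin(y, X, w, model_form="durbin").fit()
    assert abs(lag.params["rho"] - 0.4) < 3 * lag.bse["rho"]
    assert abs(durbin.params["W.x1"]) < 3 * durbin.bse["W.x1"]
    assert durbin.llf >= lag.llf - 1e-8   # lag is nested in durbin


def test_ols_form(queen10):
    X, y = _simulate(queen10, rho=0.0, beta=[2.0], theta=[0.0], seed=95)
    res = sd.SpatialDurbin(y, X, queen10, model_form="ols").fit()
    assert res.rho == 0.0
    assert "rho" not in res.params.index
    coef = np.linalg.lstsq(np.column_stack([np.ones(100), X.to_numpy()]), y,
                           rcond=None)[0]
    assert np.allclose(res.params.to_numpy(), coef, atol=1e-10)


def test_input_validation(queen10):
    X, y = _simulate(queen10, rho=0.0, beta=[1.0], theta=[0.0], seed=96)
    ybad = np.array(y, copy=True)
    ybad[3] = np.nan
    with pytest.raises(ValueError, match="missing"):
        sd.SpatialDurbin(ybad, X, queen10)
    # unstandardized weights refused for spatial forms
    raw = sd.lattice_weights(10, 10, "queen")
    with pytest.raises(ValueError, match="row-standardize"):
        sd.SpatialDurbin(y, X, raw)
    # too few observations for the parameter count
    tiny = sd.lattice_weights(2, 2, "queen").row_standardize()
    with pytest.raises(ValueError, match="n > 2p"):
        sd.SpatialDurbin(np.arange(4.0), np.arange(4.0)[:, None], tiny)
    with pytest.raises(ValueError, match="model_form"):
        sd.SpatialDurbin(y, X, queen10, model_form="sarar")


def test_singular_design_is_structured_failure(queen10):
    X, y = _simulate(queen10, rho=0.2, beta=[1.0], theta=[0.0], seed=97)
    Xdup = np.column_stack([X.to_numpy(), X.to_numpy()])
    with pytest.raises(sd.ConvergenceError, match="singular"):
        sd.SpatialDurbin(y, Xdup, queen10).fit()


def test_from_dataframe_and_summary(queen10):
    X, y = _simulate(queen10, rho=0.3, beta=[1.0, -1.0], theta=[0.5, 0.0],
                     seed=98)
    df = X.copy()
    df["outcome"] = y
    res = sd.fit_sdm(df, queen10, "outcome", list(X.columns))
    txt = res.summary()
    assert "rho" in txt and "W.x1" in txt
    with pytest.raises(KeyError):
        sd.SpatialDurbin.from_dataframe(df, "nope", ["x1"], queen10)
    ci = res.conf_int()
    assert (ci["lower"] < ci["upper"]).all()
    assert res.vcov.to_numpy() == pytest.approx(res.vcov.to_numpy().T)


def test_sigma2_positive_and_vcov_psd(sim_fit_10x10):
    res, _ = sim_fit_10x10
    assert res.sigma2 > 0
    ev = np.linalg.eigvalsh(res.vcov.to_numpy())
    assert ev.min() > -1e-10
    lo, hi = res.model.weights.rho_interval()
    assert lo < res.rho < hi
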