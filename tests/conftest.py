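import numpy as np
import pandas as pd
import pytest

import spdurbin as sd


@pytest.fixture(scope="session")
def queen5():
    return sd.lattice_weights(5, 5, "queen").row_standardize()


@pytest.fixture(scope="session")
def queen10():
    return sd.lattice_weights(10, 10, "queen").row_standardize()


@pytest.fixture(scope="session")
def rook8():
    return sd.lattice_weights(8, 8, "rook").row_standardize()


@pytest.fixture(scope="session")
def sim_fit_10x10(queen10):
    """A Durbin fit on data simulated at known truth, shared across tests."""
    truth = sd.SDMParams(rho=0.4, alpha=1.0, beta=[-0.1, -1.3],
                         theta=[-0.25, -0.5], sigma2=1.0)
    X = sd.simulate_covariates(queen10, [0, 0], [1, 1], spatial_rho_x=0.5,
                               names=["social_capital", "ses_index"], seed=21)
    y = sd.simulate_sdm_outcome(queen10, X.to_numpy(), truth, seed=22)
    res = sd.SpatialDurbin(y, X, queen10).fit()
    return res, truth


def forge_results(w, beta, theta, rho, model_form="durbin", vcov_scale=1e-6,
                  seed=0):
    """SDMResults with prescribed parameters on weights ``w`` (for closed-form
    impact checks that need exact rho/beta/theta, not estimates)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if theta is None:
        theta = np.zeros_like(beta)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    p = beta.size
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((w.n, p))
    y = rng.standard_normal(w.n)
    model = sd.SpatialDurbin(y, X, w, model_form=model_form)
    if model_form == "durbin":
        vals = np.concatenate([[0.0], beta, theta, [rho]])
    else:
        vals = np.concatenate([[0.0], beta, [rho]])
    names = model.param_names + ["rho"]
    params = pd.Series(vals, index=names)
    vcov = pd.DataFrame(np.eye(len(names)) * vcov_scale, index=names,
                        columns=names)
    return sd.SDMResults(model, params, 1.0, 0.0, vcov)


@pytest.fixture(scope="session")
def forge():
    return forge_results
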