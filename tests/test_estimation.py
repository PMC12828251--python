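"""Survey-weighted fits: point estimates, fit statistics and covariances."""

import numpy as np
import pytest
import statsmodels.api as sm

from svyjoinpoint import (
    JoinpointSpec,
    SingletonStratumError,
    SurveyDataset,
    fit_lognormal,
    fit_logistic,
    score_meat,
)
from svyjoinpoint.estimation import compress

from conftest import make_clustered_dataset, make_iid_dataset


def spec_ln(taus=(), parameterization="standard"):
    return JoinpointSpec(taus, link="lognormal", parameterization=parameterization)


def spec_lg(taus=(), parameterization="standard"):
    return JoinpointSpec(taus, link="logistic", parameterization=parameterization)


# ----------------------------------------------------------------- lognormal

def test_lognormal_k0_equals_ols():
    """Equal weights, one stratum, no joinpoints: WLS reduces to OLS."""
    ds = make_iid_dataset(n=120, T=6, seed=1)
    fit = fit_lognormal(ds, spec_ln())
    X = sm.add_constant(ds.time)
    ols = sm.OLS(np.log(ds.y), X).fit()
    assert fit.theta == pytest.approx(ols.params, abs=1e-8)
    assert fit.J == pytest.approx(ols.cov_params(), rel=1e-6)


def test_lognormal_perfect_fit():
    n, T = 60, 6
    times = 2000.0 + (np.arange(n) % T)
    y = np.exp(0.7 + 0.02 * times)
    ds = SurveyDataset.from_arrays(
        np.zeros(n, int), np.arange(n), np.ones(n), times, y, link="lognormal"
    )
    fit = fit_lognormal(ds, spec_ln())
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    assert fit.mse == pytest.approx(0.0, abs=1e-12)


def test_lognormal_weight_scale_invariance():
    ds = make_clustered_dataset(seed=2)
    ds_scaled = SurveyDataset.from_arrays(
        ds.stratum_ids, ds.psu_ids, 7.5 * ds.weight, ds.time, ds.y, link="lognormal"
    )
    f1 = fit_lognormal(ds, spec_ln())
    f2 = fit_lognormal(ds_scaled, spec_ln())
    assert f2.theta == pytest.approx(f1.theta, rel=1e-12)
    assert f2.r2 == pytest.approx(f1.r2, rel=1e-12)
    assert f2.mse == pytest.approx(f1.mse, rel=1e-12)
    assert f2.V == pytest.approx(f1.V, rel=1e-9)
    assert f2.J == pytest.approx(f1.J, rel=1e-9)


def test_lognormal_joinpoint_fit_recovers_kink():
    ds = make_iid_dataset(
        n=2000, T=10, seed=3, slope=0.02, slope_change=-0.05, tau=2004.0, sigma=0.02
    )
    fit = fit_lognormal(ds, spec_ln((2004.0,)))
    assert fit.theta[1] == pytest.approx(0.02, abs=0.005)
    assert fit.theta[2] == pytest.approx(-0.05, abs=0.01)


def test_compressed_path_matches_direct_call():
    ds = make_clustered_dataset(seed=4)
    comp = compress(ds, "lognormal")
    f1 = fit_lognormal(ds, spec_ln((2003.0,)))
    f2 = fit_lognormal(None, spec_ln((2003.0,)), comp)
    assert np.array_equal(f1.theta, f2.theta)
    assert np.array_equal(f1.V, f2.V)


# ----------------------------------------------------------------- logistic

def test_logistic_matches_statsmodels():
    """Unweighted single-stratum fit equals generic ML logistic regression."""
    ds = make_iid_dataset(n=600, T=8, seed=5, link="logistic", intercept=-1.0, slope=0.05)
    fit = fit_logistic(ds, spec_lg())
    X = sm.add_constant(ds.time)
    glm = sm.GLM(ds.y, X, family=sm.families.Binomial()).fit(tol=1e-12)
    assert fit.theta == pytest.approx(glm.params, abs=1e-8)
    assert fit.neg2logl == pytest.approx(-2 * glm.llf, rel=1e-10)


def test_logistic_doubled_weights():
    ds = make_iid_dataset(n=300, T=6, seed=6, link="logistic", intercept=-0.5)
    ds2 = SurveyDataset.from_arrays(
        ds.stratum_ids, ds.psu_ids, 2.0 * ds.weight, ds.time, ds.y, link="logistic"
    )
    f1, f2 = fit_logistic(ds, spec_lg()), fit_logistic(ds2, spec_lg())
    assert f2.theta == pytest.approx(f1.theta, rel=1e-10)
    assert f2.neg2logl == pytest.approx(2.0 * f1.neg2logl, rel=1e-12)
    assert f2.J == pytest.approx(f1.J, rel=1e-9)
    assert f2.V == pytest.approx(f1.V, rel=1e-9)


def test_logistic_flat_rate():
    ds = make_iid_dataset(n=4000, T=8, seed=7, link="logistic", intercept=-1.2, slope=0.0)
    fit = fit_logistic(ds, spec_lg())
    pbar = ds.y.mean()
    assert fit.theta[1] == pytest.approx(0.0, abs=0.06)
    assert fit.theta[0] + fit.theta[1] * 2003.5 == pytest.approx(np.log(pbar / (1 - pbar)), abs=0.2)


# ----------------------------------------------------------------- sandwich

def brute_force_sandwich(ds, spec, link="lognormal"):
    """Independent per-record sandwich: explicit loops, no shared code paths.

    Treats each (PSU, time) pair as a with-replacement sampling unit and
    centers unit score totals within (stratum, time).
    """
    k = len(spec.taus)
    X = np.array([[1.0, t] + [max(0.0, t - tau) for tau in spec.taus] for t in ds.time])
    w = ds.weight
    if link == "lognormal":
        z = np.log(ds.y)
        WX = X * w[:, None]
        theta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        resid = z - X @ theta
        bread = np.linalg.inv(X.T @ WX)
        u = (w * resid)[:, None] * X
    else:
        raise NotImplementedError
    # unit = (stratum, psu, time); centering cell = (stratum, time)
    cells = {}
    for i in range(ds.n):
        cell = (int(ds.stratum[i]), float(ds.time[i]))
        unit = (int(ds.psu[i]),)
        cells.setdefault(cell, {}).setdefault(unit, np.zeros(X.shape[1]))
        cells[cell][unit] = cells[cell][unit] + u[i]
    G = np.zeros((X.shape[1],) * 2)
    for cell, units in cells.items():
        Z = np.array(list(units.values()))
        m = Z.shape[0]
        d = Z - Z.mean(axis=0)
        G += (m / (m - 1.0)) * d.T @ d
    return bread @ G @ bread


def test_sandwich_matches_bruteforce_12_records():
    rng = np.random.default_rng(11)
    n = 12
    times = np.tile([1.0, 2.0, 3.0], 4)
    ds = SurveyDataset.from_arrays(
        np.zeros(n, int),
        np.arange(n),                      # one record per PSU
        np.ones(n),
        times,
        np.exp(rng.standard_normal(n)),
        link="lognormal",
    )
    spec = spec_ln()
    fit = fit_lognormal(ds, spec)
    V_oracle = brute_force_sandwich(ds, spec)
    assert np.max(np.abs(fit.V - V_oracle)) < 1e-10


def test_duplicating_psus_shrinks_variance():
    ds = make_clustered_dataset(seed=8, n_psu=16, per_psu=6)
    dup = SurveyDataset.from_arrays(
        np.concatenate([ds.stratum_ids, ds.stratum_ids]),
        np.concatenate([ds.psu_ids, ds.psu_ids + 1000]),
        np.concatenate([ds.weight, ds.weight]),
        np.concatenate([ds.time, ds.time]),
        np.concatenate([ds.y, ds.y]),
    )
    f1, f2 = fit_lognormal(ds, spec_ln()), fit_lognormal(dup, spec_ln())
    assert np.trace(f2.V) < np.trace(f1.V)


def test_trace_ratio_near_one_iid():
    """Design effect ~ 1 under iid equal-weight sampling (Monte Carlo)."""
    ratios = []
    for rep in range(200):
        ds = make_iid_dataset(n=160, T=8, seed=1000 + rep, sigma=0.15)
        fit = fit_lognormal(ds, spec_ln())
        ratios.append(np.trace(np.linalg.solve(fit.J, fit.V)) / fit.p)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_singleton_stratum_raises():
    with pytest.raises(SingletonStratumError):
        ds = SurveyDataset.from_arrays(
            [0, 0, 1, 1],
            [0, 1, 2, 3],
            np.ones(4),
            [2000.0, 2000.0, 2000.0, 2001.0],
            [1.0, 2.0, 3.0, 4.0],
        )
        fit_lognormal(ds, spec_ln())  # stratum 1 has one PSU per year


def test_score_meat_additive_over_strata():
    rng = np.random.default_rng(12)
    scores = rng.standard_normal((20, 3))
    stratum = np.repeat([0, 1], 10)
    psu = np.arange(20)
    G_all = score_meat(scores, stratum, psu)
    G0 = score_meat(scores[:10], stratum[:10], psu[:10])
    G1 = score_meat(scores[10:], stratum[10:], psu[10:])
    assert G_all == pytest.approx(G0 + G1, rel=1e-12)
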