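"""Grid search, A_k reparameterization, design effects and m.dAIC."""

import dataclasses
import itertools

import numpy as np
import pytest

from svyjoinpoint import (
    FitResult,
    GridRules,
    JoinpointSpec,
    SurveyDataset,
    ak_matrix,
    best_model_for_k,
    constrained_design_effect,
    default_k_max,
    fit_lognormal,
    grid_candidates,
    m_daic,
    select_model,
    select_models,
    unconstrained_design_effect,
)

from conftest import make_iid_dataset


def exhaustive_candidates(time_points, k, min_end=2, min_between=2):
    """Independent re-implementation of the feasibility rules."""
    tp = sorted(set(float(t) for t in time_points))
    if k == 0:
        return [()]
    out = []
    for taus in itertools.combinations(tp, k):
        n_before = sum(t < taus[0] for t in tp)
        n_after = sum(t > taus[-1] for t in tp)
        if n_before < min_end or n_after < min_end:
            continue
        ok = True
        for a, b in zip(taus, taus[1:]):
            if sum(a < t < b for t in tp) < min_between:
                ok = False
        if ok:
            out.append(taus)
    return out


def test_grid_candidates_t20_k1():
    cands = grid_candidates(np.arange(1.0, 21.0), 1)
    assert cands == [(float(t),) for t in range(3, 19)]
    assert len(cands) == 16


def test_grid_candidates_trivial_cases():
    assert grid_candidates(np.arange(5.0), 0) == [()]
    assert grid_candidates(np.arange(1.0, 6.0), 2) == []  # infeasible


@pytest.mark.parametrize("T", [6, 8, 10, 12])
@pytest.mark.parametrize("k", [1, 2])
def test_grid_matches_exhaustive_enumeration(T, k):
    tp = 1997.0 + np.arange(T)
    assert grid_candidates(tp, k) == exhaustive_candidates(tp, k)


@pytest.mark.parametrize(
    "T, expected", [(5, 0), (6, 0), (7, 1), (11, 1), (12, 2), (16, 2), (17, 3), (26, 4), (27, 5)]
)
def test_default_k_max(T, expected):
    assert default_k_max(T) == expected


def test_best_model_matches_bruteforce_search():
    ds = make_iid_dataset(n=100, T=10, seed=9, sigma=0.3)
    spec, fit = best_model_for_k(ds, 1)
    best_tau, best_r2 = None, -np.inf
    for (tau,) in exhaustive_candidates(ds.time_points, 1):
        f = fit_lognormal(ds, JoinpointSpec((tau,), link="lognormal"))
        if f.r2 > best_r2:
            best_tau, best_r2 = tau, f.r2
    assert spec.taus == (best_tau,)
    assert fit.r2 == pytest.approx(best_r2)


def test_low_noise_recovery_and_selection():
    ds = make_iid_dataset(
        n=400, T=20, t0=1997.0, seed=10, slope=0.005, slope_change=-0.3,
        tau=2006.0, sigma=1e-3,
    )
    spec, _ = best_model_for_k(ds, 1)
    assert spec.taus == (2006.0,)
    res = select_model(ds, GridRules(k_max=2), approach="constrained")
    assert res.chosen_k == 1
    assert res.chosen.spec.taus == (2006.0,)


# ------------------------------------------------------------------- A_k

def reparameterize(beta_seg):
    """Independent map: per-segment coefficients -> (b0, b1, d_1..d_k)."""
    b = np.asarray(beta_seg)
    intercepts, slopes = b[0::2], b[1::2]
    return np.concatenate([[intercepts[0], slopes[0]], np.diff(slopes)])


def test_ak_matrix_small_cases():
    assert np.array_equal(ak_matrix(0), np.eye(2))
    assert ak_matrix(1).tolist() == [
        [1, 0, 0, 0],
        [0, 1, 0, 0],
        [0, -1, 0, 1],
    ]


@pytest.mark.parametrize("k", [0, 1, 2, 3, 4])
def test_ak_matrix_equals_numerical_jacobian(k):
    rng = np.random.default_rng(k)
    A = ak_matrix(k)
    assert A.shape == (k + 2, 2 * (k + 1))
    beta = rng.standard_normal(2 * (k + 1))
    eps = 1e-6
    J = np.zeros_like(A)
    for j in range(beta.shape[0]):
        up, dn = beta.copy(), beta.copy()
        up[j] += eps
        dn[j] -= eps
        J[:, j] = (reparameterize(up) - reparameterize(dn)) / (2 * eps)
    assert np.max(np.abs(A - J)) < 1e-8
    # structure: one nonzero in rows 1-2, two in every slope-change row
    nz = (np.abs(A) > 0).sum(axis=1)
    assert nz[0] == nz[1] == 1 and np.all(nz[2:] == 2)


# ----------------------------------------------------------- design effects

def _dummy_fit(J, V, k, link="lognormal", mse=0.5, n=100, neg2logl=None, sum_w=None):
    taus = tuple(2000.0 + i for i in range(1, k + 1))
    return FitResult(
        spec=JoinpointSpec(taus, link=link),
        theta=np.zeros(k + 2),
        J=J,
        V=V,
        r2=None,
        neg2logl=neg2logl,
        mse=mse,
        n_used=n,
        sum_w_used=sum_w if sum_w is not None else float(n),
        column_roles=(),
    )


@pytest.mark.parametrize("k", [0, 1, 2])
@pytest.mark.parametrize("c", [1.0, 3.5])
def test_constrained_design_effect_trace_identity(k, c):
    rng = np.random.default_rng(k)
    L = rng.standard_normal((k + 2, k + 2))
    J = L @ L.T + (k + 2) * np.eye(k + 2)
    fit = _dummy_fit(J, c * J, k)
    assert constrained_design_effect(fit) == pytest.approx(c * (k + 1), rel=1e-10)
    assert constrained_design_effect(fit, drop_intercept=False) == pytest.approx(
        c * (k + 2), rel=1e-10
    )


def test_unconstrained_design_effect_k0_scalar():
    ds = make_iid_dataset(n=150, T=8, seed=13)
    db = unconstrained_design_effect(ds, JoinpointSpec((), link="lognormal"))
    fit = fit_lognormal(ds, JoinpointSpec((), link="lognormal", parameterization="general"))
    assert db == pytest.approx(fit.V[1, 1] / fit.J[1, 1], rel=1e-10)


def test_delta_bar_near_param_count_iid():
    """Under iid equal-weight sampling delta-bar approaches k+1 (both routes)."""
    k = 1
    vals_c, vals_u = [], []
    for rep in range(120):
        ds = make_iid_dataset(n=200, T=10, seed=2000 + rep, sigma=0.2)
        spec = JoinpointSpec((2004.0,), link="lognormal")
        vals_c.append(constrained_design_effect(fit_lognormal(ds, spec)))
        vals_u.append(unconstrained_design_effect(ds, spec))
    assert np.mean(vals_c) == pytest.approx(k + 1, rel=0.1)
    assert np.mean(vals_u) == pytest.approx(k + 1, rel=0.1)


# ------------------------------------------------------------------ m.dAIC

def test_m_daic_lognormal_plugin():
    fit = _dummy_fit(np.eye(2), np.eye(2), k=0, mse=0.5, n=100)
    assert m_daic(fit, 1.0) == pytest.approx(52.0)


def test_m_daic_logistic_self_weighting():
    fit = _dummy_fit(
        np.eye(2), np.eye(2), k=0, link="logistic", mse=None, neg2logl=120.0, n=100, sum_w=100.0
    )
    assert m_daic(fit, 2.0) == pytest.approx(120.0 + 4.0)


def test_m_daic_penalty_monotone():
    for k in range(3):
        fit = _dummy_fit(np.eye(k + 2), np.eye(k + 2), k=k, mse=0.3, n=50)
        assert m_daic(fit, 2.0) > m_daic(fit, 1.0)
    f0 = _dummy_fit(np.eye(2), np.eye(2), k=0, mse=0.3, n=50)
    f1 = _dummy_fit(np.eye(3), np.eye(3), k=1, mse=0.3, n=50)
    assert m_daic(f1, 1.0) > m_daic(f0, 1.0)


def test_logistic_m_daic_weight_scale_invariant():
    ds = make_iid_dataset(n=400, T=10, seed=14, link="logistic", intercept=-1.0)
    scaled = SurveyDataset.from_arrays(
        ds.stratum_ids, ds.psu_ids, 9.0 * ds.weight, ds.time, ds.y, link="logistic"
    )
    r1 = select_model(ds, GridRules(k_max=1), approach="constrained")
    r2 = select_model(scaled, GridRules(k_max=1), approach="constrained")
    for c1, c2 in zip(r1.per_k, r2.per_k):
        assert c2.m_daic == pytest.approx(c1.m_daic, rel=1e-8)
    assert r1.chosen_k == r2.chosen_k


# --------------------------------------------------------------- selection

def test_selection_invariant_to_record_order():
    ds = make_iid_dataset(n=300, T=12, seed=15, sigma=0.3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.n)
    ds2 = SurveyDataset.from_arrays(
        ds.stratum_ids[perm], ds.psu_ids[perm], ds.weight[perm], ds.time[perm], ds.y[perm],
        link="lognormal",
    )
    r1 = select_model(ds, GridRules(k_max=2))
    r2 = select_model(ds2, GridRules(k_max=2))
    assert r1.chosen_k == r2.chosen_k
    assert r1.chosen.spec.taus == r2.chosen.spec.taus
    for c1, c2 in zip(r1.per_k, r2.per_k):
        assert c2.m_daic == pytest.approx(c1.m_daic, rel=1e-9)


def test_flat_trend_prefers_k0():
    hits = 0
    for rep in range(30):
        ds = make_iid_dataset(n=200, T=12, seed=3000 + rep, slope=0.0, sigma=0.2)
        res = select_model(ds, GridRules(k_max=2), approach="constrained")
        hits += res.chosen_k == 0
    assert hits >= 24  # large majority under a true flat trend


def test_select_models_shares_grid_between_approaches():
    ds = make_iid_dataset(n=250, T=12, seed=16, sigma=0.25)
    both = select_models(ds, GridRules(k_max=1))
    assert set(both) == {"constrained", "unconstrained"}
    single = select_model(ds, GridRules(k_max=1), approach="unconstrained")
    assert both["unconstrained"].chosen_k == single.chosen_k
    for c1, c2 in zip(both["unconstrained"].per_k, single.per_k):
        assert c1.m_daic == pytest.approx(c2.m_daic, rel=1e-12)
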