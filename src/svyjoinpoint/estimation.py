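"""Survey-weighted fitting of segmented log-normal and logistic models.

Point estimates maximize the weighted pseudo-(log-)likelihood: weighted least
squares of log y on the segmented design for the log-normal link, and
iteratively reweighted least squares for the logistic link.  Two covariance
matrices accompany every fit:

* ``J`` — the model-based covariance, the inverse information of the fit with
  weights normalized to mean one (so that under independent equal-weight
  sampling with a correctly specified model, ``trace(J^-1 V) ~ p``):

  - log-normal:  ``J = [SS_err / (n - p)] (X' W X)^-1``
  - logistic:    ``J = (sum_w / n) (X' W D X)^-1``,  D = diag(pi (1 - pi))

* ``V`` — the design-based (Taylor linearization / sandwich) covariance
  ``B G B`` with bread ``B = (X'WX)^-1`` (log-normal, residual scale absorbed
  in the scores) or ``(X'WDX)^-1`` (logistic), and meat ``G`` built from
  between-PSU variation of estimating-equation score totals.  Each time
  point's PSU sample is treated as an independent with-replacement draw
  (the PSU roster may vary by time), so score totals are formed per
  (PSU, time) and centered within (stratum, time), with the m/(m-1)
  small-sample factor per centering cell.

Both are invariant to rescaling all weights by a constant.

Fit statistics follow the survey-weighted definitions: R^2 uses the weighted
total sum of squares around stratum-by-time weighted means of log y; MSE is
the weighted mean squared error SS_err / sum_w; -2logL is the weighted
binomial deviance.

Because the segmented design depends on the record only through its time
value, every quantity above is a function of per-(PSU, time) sufficient
statistics (weight totals, weighted first/second moments of log y, weighted
event totals).  Fitting therefore runs on a :class:`CompressedData` summary
— algebraically identical to the per-record computation but independent of
the raw record count, which keeps grid searches over joinpoint locations
cheap even for samples with tens of thousands of records per year.  Log
outcomes are centered by their overall weighted mean before forming second
moments, so the moment-based error sum of squares does not lose precision
to cancellation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit, logit

from .design import (
    JoinpointSpec,
    general_matrix,
    standard_matrix,
)
from .survey_data import SurveyDataset, ValidationError

__all__ = [
    "FitResult",
    "CompressedData",
    "compress",
    "SingularFitError",
    "SingletonStratumError",
    "ConvergenceError",
    "SeparationWarning",
    "fit_lognormal",
    "fit_logistic",
    "fit_model",
    "robust_cov",
    "score_meat",
]

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100
SEPARATION_ETA = 30.0


class SingularFitError(np.linalg.LinAlgError):
    """The design matrix is rank-deficient on the records used."""


class SingletonStratumError(ValueError):
    """A stratum contains a single PSU; PSU totals cannot be centered."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class SeparationWarning(UserWarning):
    """The logistic fit shows signs of (quasi-)complete separation."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Coefficients and covariances of one survey-weighted segmented fit.

    ``theta`` and both covariances are reported on the original time scale
    (fitting is done internally on times shifted to start at zero for
    numerical conditioning, then mapped back exactly).
    """

    spec: JoinpointSpec
    theta: np.ndarray
    J: np.ndarray
    V: np.ndarray
    r2: float | None
    neg2logl: float | None
    mse: float | None
    n_used: int
    sum_w_used: float
    column_roles: tuple

    @property
    def p(self) -> int:
        return self.theta.shape[0]


@dataclasses.dataclass(frozen=True)
class CompressedData:
    """Per-(PSU, time) sufficient statistics of a survey dataset.

    One "group" per sampled (PSU, time) pair.  ``swz``/``swz2`` are weighted
    first/second moments of ``log y - z_center`` (log-normal link); ``swy``
    weighted event totals (logistic link).
    """

    link: str
    times: np.ndarray          # (T,) sorted unique times
    time_idx: np.ndarray       # (G,) time index per group
    psu: np.ndarray            # (G,) compact PSU code per group
    stratum_of_psu: np.ndarray  # (P,)
    sw: np.ndarray             # (G,)
    n_g: np.ndarray            # (G,) record counts
    swz: np.ndarray | None
    swz2: np.ndarray | None
    z_center: float
    swy: np.ndarray | None
    sstot_t: np.ndarray | None  # (T,) per-time weighted SS around stratum-time means
    design_df: int

    @property
    def T(self) -> int:
        return self.times.shape[0]


def compress(dataset: SurveyDataset, link: str | None = None) -> CompressedData:
    """Collapse a dataset to its per-(PSU, time) sufficient statistics."""
    link = link or dataset.link or "lognormal"
    tp = dataset.time_points
    T = tp.shape[0]
    t_idx = np.searchsorted(tp, dataset.time)
    key = dataset.psu * T + t_idx
    uniq, g_idx = np.unique(key, return_inverse=True)
    G = uniq.shape[0]
    psu_g = uniq // T
    time_g = uniq % T

    n_psu = int(dataset.psu.max()) + 1
    strat_of_psu = np.empty(n_psu, dtype=np.int64)
    strat_of_psu[dataset.psu] = dataset.stratum

    sw = np.bincount(g_idx, weights=dataset.weight, minlength=G)
    n_g = np.bincount(g_idx, minlength=G)

    swz = swz2 = swy = sstot_t = None
    z_center = 0.0
    if link == "lognormal":
        if np.any(dataset.y <= 0):
            raise ValidationError("log-normal link requires strictly positive outcomes")
        z = np.log(dataset.y)
        z_center = float((dataset.weight @ z) / dataset.weight.sum())
        zc = z - z_center
        swz = np.bincount(g_idx, weights=dataset.weight * zc, minlength=G)
        swz2 = np.bincount(g_idx, weights=dataset.weight * zc**2, minlength=G)
        # per-(stratum, time) total SS around the stratum-time weighted mean
        skey = strat_of_psu[psu_g] * T + time_g
        s_uniq, s_idx = np.unique(skey, return_inverse=True)
        s_sw = np.bincount(s_idx, weights=sw)
        s_swz = np.bincount(s_idx, weights=swz)
        s_swz2 = np.bincount(s_idx, weights=swz2)
        term = s_swz2 - s_swz**2 / s_sw
        sstot_t = np.bincount(s_uniq % T, weights=term, minlength=T)
    else:
        if not np.all(np.isin(dataset.y, (0.0, 1.0))):
            raise ValidationError("logistic link requires 0/1 outcomes")
        swy = np.bincount(g_idx, weights=dataset.weight * dataset.y, minlength=G)

    return CompressedData(
        link=link,
        times=tp,
        time_idx=time_g,
        psu=psu_g,
        stratum_of_psu=strat_of_psu,
        sw=sw,
        n_g=n_g,
        swz=swz,
        swz2=swz2,
        z_center=z_center,
        swy=swy,
        sstot_t=sstot_t,
        design_df=dataset.design_df,
    )


# ----------------------------------------------------------------------
# internal helpers
# ----------------------------------------------------------------------

def _time_design(comp: CompressedData, spec: JoinpointSpec):
    """Per-unique-time design rows on shifted time, plus the back-transform.

    Returns (Xt, kept_time_mask, M, roles): ``Xt`` has one row per *kept*
    unique time; ``theta_orig = M @ theta_shift`` (the log-outcome centering
    shift is handled separately by the callers).
    """
    spec.validate_against(comp.times)
    t0 = float(comp.times[0])
    ts = comp.times - t0
    taus_s = np.asarray(spec.taus, dtype=float) - t0
    k = spec.k
    if spec.parameterization == "standard":
        dm = standard_matrix(ts, taus_s)
        M = np.eye(k + 2)
        M[0, 1] = -t0
    else:
        dm = general_matrix(ts, taus_s)
        M = np.eye(2 * (k + 1))
        for s in range(k + 1):
            M[2 * s, 2 * s + 1] = -t0
    return dm.X, dm.kept_mask, M, dm.column_roles


def _inv_psd(A: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(A)):
        raise SingularFitError("non-finite normal-equation matrix")
    if np.linalg.cond(A) > 1e12:
        raise SingularFitError("design matrix is numerically rank-deficient")
    return np.linalg.inv(A)


def _solve_psd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(str(exc)) from exc


def score_meat(scores: np.ndarray, stratum: np.ndarray, psu: np.ndarray) -> np.ndarray:
    """Between-PSU score covariance G (the sandwich "meat").

    ``G = sum_i [m_i/(m_i-1)] sum_j (z_ij - zbar_i)(z_ij - zbar_i)'`` where
    ``z_ij`` is the total of per-record (or per-group) scores over PSU j of
    stratum i and ``m_i`` the number of sampled PSUs in stratum i.
    Additive over strata.
    """
    scores = np.asarray(scores, dtype=float)
    p = scores.shape[1]
    psu_u, psu_idx = np.unique(psu, return_inverse=True)
    totals = np.zeros((psu_u.shape[0], p))
    np.add.at(totals, psu_idx, scores)
    strat_of_psu = np.empty(psu_u.shape[0], dtype=np.int64)
    strat_of_psu[psu_idx] = stratum
    G = np.zeros((p, p))
    for s in np.unique(strat_of_psu):
        z = totals[strat_of_psu == s]
        m = z.shape[0]
        if m < 2:
            raise SingletonStratumError(
                f"stratum {s} has a single PSU; between-PSU variance undefined"
            )
        d = z - z.mean(axis=0)
        G += (m / (m - 1.0)) * d.T @ d
    return G


def robust_cov(scores: np.ndarray, stratum: np.ndarray, psu: np.ndarray, bread: np.ndarray) -> np.ndarray:
    """Design-based sandwich covariance ``bread @ G @ bread``."""
    G = score_meat(scores, stratum, psu)
    return bread @ G @ bread


def _variance_units(comp: CompressedData, g_keep: np.ndarray):
    """(stratum, unit) codes for the sandwich, per kept group.

    Each time point's sample of PSUs is treated as an independent
    with-replacement draw within its stratum (the PSU roster varies by time),
    so the variance unit is the (PSU, time) pair and score totals are
    centered within (stratum, time).  A PSU reused across years therefore
    contributes one unit per year; the cross-year covariance such reuse
    induces is the aggregate module's concern, not the per-fit sandwich.
    """
    strat = comp.stratum_of_psu[comp.psu[g_keep]] * comp.T + comp.time_idx[g_keep]
    units = np.arange(int(g_keep.sum()))
    return strat, units


def _group_view(comp: CompressedData, kept_time: np.ndarray):
    """Kept-group mask and the row index into the kept-time design."""
    pos = np.full(comp.T, -1, dtype=np.int64)
    pos[kept_time] = np.arange(int(kept_time.sum()))
    g_keep = kept_time[comp.time_idx]
    return g_keep, pos[comp.time_idx[g_keep]]


# ----------------------------------------------------------------------
# public fitting operations
# ----------------------------------------------------------------------

def fit_lognormal(
    dataset: SurveyDataset | None,
    spec: JoinpointSpec,
    compressed: CompressedData | None = None,
) -> FitResult:
    """Weighted least squares of log y on the segmented design.

    Minimizes ``sum w (log y - x'theta)^2``; reports the weighted R^2 (total
    sum of squares around stratum-by-time weighted means of log y), the
    weighted MSE ``SS_err / sum_w`` and both covariance matrices.  A
    pre-computed :class:`CompressedData` may be supplied to amortize the
    per-record pass across many candidate fits.
    """
    if spec.link != "lognormal":
        raise ValueError("spec.link must be 'lognormal'")
    comp = compressed if compressed is not None else compress(dataset, "lognormal")
    if comp.link != "lognormal":
        raise ValueError("compressed data was built for a different link")

    Xt, kept_time, M, roles = _time_design(comp, spec)
    p = Xt.shape[1]
    g_keep, g_row = _group_view(comp, kept_time)
    sw, swz, swz2 = comp.sw[g_keep], comp.swz[g_keep], comp.swz2[g_keep]
    n_used = int(comp.n_g[g_keep].sum())
    sum_w = float(sw.sum())

    # per-kept-time totals
    Tk = Xt.shape[0]
    SwT = np.bincount(g_row, weights=sw, minlength=Tk)
    SwzT = np.bincount(g_row, weights=swz, minlength=Tk)
    Swz2T = np.bincount(g_row, weights=swz2, minlength=Tk)

    XtWX = Xt.T @ (SwT[:, None] * Xt)
    B = _inv_psd(XtWX)
    theta_s = B @ (Xt.T @ SwzT)
    fitted = Xt @ theta_s
    ss_err = max(float(np.sum(Swz2T - 2.0 * fitted * SwzT + fitted**2 * SwT)), 0.0)
    ss_tot = float(comp.sstot_t[kept_time].sum())
    # degenerate (deterministic within stratum-time) data: both sums ~ 0
    eps = 1e-12 * sum_w
    if ss_tot > eps:
        r2 = 1.0 - ss_err / ss_tot
    else:
        r2 = 1.0 if ss_err <= eps else np.nan
    mse = ss_err / sum_w

    J_s = (ss_err / max(n_used - p, 1)) * B
    scores = (swz - fitted[g_row] * sw)[:, None] * Xt[g_row]
    V_s = robust_cov(scores, *_variance_units(comp, g_keep), B)

    theta = M @ theta_s
    theta[0] += comp.z_center
    if spec.parameterization == "general":
        theta[0::2] = M[0::2] @ theta_s + comp.z_center
        theta[1::2] = theta_s[1::2]
    return FitResult(
        spec=spec,
        theta=theta,
        J=M @ J_s @ M.T,
        V=M @ V_s @ M.T,
        r2=r2,
        neg2logl=None,
        mse=mse,
        n_used=n_used,
        sum_w_used=sum_w,
        column_roles=roles,
    )


def fit_logistic(
    dataset: SurveyDataset | None,
    spec: JoinpointSpec,
    compressed: CompressedData | None = None,
) -> FitResult:
    """Weighted pseudo-likelihood logistic fit via IRLS.

    Maximizes ``sum w [y log pi + (1-y) log(1-pi)]`` with ``logit pi =
    x'theta``; convergence at relative coefficient change below 1e-10, at
    most 100 iterations.  Reports the weighted -2logL and both covariances.
    """
    if spec.link != "logistic":
        raise ValueError("spec.link must be 'logistic'")
    comp = compressed if compressed is not None else compress(dataset, "logistic")
    if comp.link != "logistic":
        raise ValueError("compressed data was built for a different link")

    Xt, kept_time, M, roles = _time_design(comp, spec)
    p = Xt.shape[1]
    g_keep, g_row = _group_view(comp, kept_time)
    sw, swy = comp.sw[g_keep], comp.swy[g_keep]
    n_used = int(comp.n_g[g_keep].sum())
    sum_w = float(sw.sum())

    Tk = Xt.shape[0]
    SwT = np.bincount(g_row, weights=sw, minlength=Tk)
    SwyT = np.bincount(g_row, weights=swy, minlength=Tk)

    pbar = float(np.clip(SwyT.sum() / sum_w, 1e-6, 1 - 1e-6))
    theta_s = np.zeros(p)
    if spec.parameterization == "standard":
        theta_s[0] = logit(pbar)
    else:
        theta_s[0::2] = logit(pbar)

    for _ in range(IRLS_MAX_ITER):
        eta = Xt @ theta_s
        pi = expit(eta)
        d = np.clip(pi * (1.0 - pi), 1e-12, None)
        XtWDX = Xt.T @ ((SwT * d)[:, None] * Xt)
        grad = Xt.T @ (SwyT - SwT * pi)
        step = _solve_psd(XtWDX, grad)
        theta_s = theta_s + step
        if np.max(np.abs(step)) < IRLS_TOL * (1.0 + np.max(np.abs(theta_s))):
            break
    else:
        raise ConvergenceError("IRLS did not converge in 100 iterations")

    eta = Xt @ theta_s
    if np.max(np.abs(eta)) > SEPARATION_ETA:
        warnings.warn(
            "fitted linear predictor exceeds +/-30; possible separation",
            SeparationWarning,
        )
    pi = expit(eta)
    d = np.clip(pi * (1.0 - pi), 1e-12, None)
    XtWDX = Xt.T @ ((SwT * d)[:, None] * Xt)
    pi_c = np.clip(pi, 1e-300, 1 - 1e-16)
    neg2logl = -2.0 * float(
        SwyT @ np.log(pi_c) + (SwT - SwyT) @ np.log1p(-pi_c)
    )

    B = _inv_psd(XtWDX)
    J_s = (sum_w / n_used) * B
    scores = (swy - pi[g_row] * sw)[:, None] * Xt[g_row]
    V_s = robust_cov(scores, *_variance_units(comp, g_keep), B)

    return FitResult(
        spec=spec,
        theta=M @ theta_s,
        J=M @ J_s @ M.T,
        V=M @ V_s @ M.T,
        r2=None,
        neg2logl=neg2logl,
        mse=None,
        n_used=n_used,
        sum_w_used=sum_w,
        column_roles=roles,
    )


def fit_model(
    dataset: SurveyDataset | None,
    spec: JoinpointSpec,
    compressed: CompressedData | None = None,
) -> FitResult:
    """Dispatch to :func:`fit_lognormal` or :func:`fit_logistic` by link."""
    if spec.link == "lognormal":
        return fit_lognormal(dataset, spec, compressed)
    return fit_logistic(dataset, spec, compressed)
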