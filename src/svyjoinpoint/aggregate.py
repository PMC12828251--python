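"""Aggregate-level joinpoint comparator: yearly estimates, their full
cross-year covariance, GLS segmented fits, and WBIC model selection.

Repeated cross-sectional surveys that reuse the same PSUs across years yield
*correlated* yearly estimates.  This module computes the weighted yearly mean
(continuous outcome) or proportion (binary outcome) per time point and the
full T x T covariance of the log-transformed estimates by joint Taylor
linearization of the ratio estimators: per-year PSU totals of the linearized
contributions are centered within strata, and the covariance between two
years accumulates cross-products over PSUs present in *both* years (years
with disjoint PSU sets get exactly zero covariance).

Joinpoint models are then fit to the log estimates by generalized least
squares, either with the full covariance (``use_cov=True``) or with its
diagonal only, and the number of joinpoints is selected by a weighted-BIC
criterion on the (co)variance-weighted residual sum of squares:

    WBIC(k) = ln(WSSE_k / T) + (2k + 2) ln(T) / T.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from .design import JoinpointSpec, standard_matrix
from .selection import GridRules, grid_candidates
from .survey_data import SurveyDataset, ValidationError

__all__ = [
    "YearlySeries",
    "AggregateFit",
    "AggregateCandidate",
    "AggregateSelection",
    "SingularCovarianceError",
    "yearly_series",
    "fit_aggregate",
    "wbic_select",
]


class SingularCovarianceError(np.linalg.LinAlgError):
    """The estimated yearly covariance matrix is not invertible."""


@dataclasses.dataclass(frozen=True)
class YearlySeries:
    """Log-transformed yearly estimates with their T x T covariance.

    ``estimates`` are the raw weighted means/proportions; ``log_estimates``
    and ``Sigma`` are on the log scale (delta method).
    """

    times: np.ndarray
    estimates: np.ndarray
    log_estimates: np.ndarray
    Sigma: np.ndarray

    @property
    def T(self) -> int:
        return self.times.shape[0]

    def to_frames(self):
        """Estimate table plus covariance table (for external cross-checks)."""
        import pandas as pd

        est = pd.DataFrame(
            {"time": self.times, "estimate": self.estimates,
             "log_estimate": self.log_estimates, "log_se": np.sqrt(np.diag(self.Sigma))}
        )
        cov = pd.DataFrame(self.Sigma, index=self.times, columns=self.times)
        return est, cov


@dataclasses.dataclass(frozen=True)
class AggregateFit:
    """GLS fit of the segmented model to the yearly log estimates."""

    spec: JoinpointSpec
    theta: np.ndarray
    cov: np.ndarray
    wsse: float
    use_cov: bool


@dataclasses.dataclass(frozen=True)
class AggregateCandidate:
    k: int
    taus: tuple
    fit: AggregateFit
    wbic: float


@dataclasses.dataclass(frozen=True)
class AggregateSelection:
    per_k: tuple
    chosen_k: int
    use_cov: bool

    @property
    def chosen(self) -> AggregateCandidate:
        for c in self.per_k:
            if c.k == self.chosen_k:
                return c
        raise LookupError(f"k={self.chosen_k} not among candidates")


def yearly_series(dataset: SurveyDataset) -> YearlySeries:
    """Weighted yearly means with full cross-year linearization covariance.

    The per-record influence for year t is ``(w / W_t)(y - yhat_t)``; PSU
    totals of influences are centered within (stratum, year), and
    ``Cov(t, t')`` sums within-stratum cross-products over PSUs present in
    both years, scaled by ``sqrt(m_t/(m_t - 1)) sqrt(m_t'/(m_t' - 1))``.
    The delta method maps to the log scale.
    """
    tp = dataset.time_points
    T = tp.shape[0]
    t_idx = np.searchsorted(tp, dataset.time)
    W = np.bincount(t_idx, weights=dataset.weight, minlength=T)
    est = np.bincount(t_idx, weights=dataset.weight * dataset.y, minlength=T) / W
    if np.any(est <= 0):
        raise ValidationError("yearly estimate <= 0; log transform undefined")

    n_psu = dataset.psu.max() + 1
    # PSU totals of linearized contributions, per year
    infl = dataset.weight * (dataset.y - est[t_idx]) / W[t_idx]
    Z = np.zeros((n_psu, T))
    np.add.at(Z, (dataset.psu, t_idx), infl)
    present = np.zeros((n_psu, T), dtype=bool)
    present[dataset.psu, t_idx] = True

    strat_of_psu = np.empty(n_psu, dtype=np.int64)
    strat_of_psu[dataset.psu] = dataset.stratum

    Sigma = np.zeros((T, T))
    for s in np.unique(strat_of_psu):
        sel = strat_of_psu == s
        Zs, Ps = Z[sel], present[sel]
        m = Ps.sum(axis=0)  # PSUs of this stratum present per year
        active = m > 0
        if np.any(m[active] < 2):
            bad = tp[active][m[active] < 2]
            raise ValidationError(
                f"stratum {s} has a single PSU in year(s) {bad}; variance undefined"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(m > 0, Zs.sum(axis=0) / np.where(m > 0, m, 1), 0.0)
        D = np.where(Ps, Zs - means, 0.0)
        f = np.where(m > 1, m / np.maximum(m - 1.0, 1.0), 0.0)
        Sigma += np.sqrt(np.outer(f, f)) * (D.T @ D)

    Sigma_log = Sigma / np.outer(est, est)
    return YearlySeries(times=tp, estimates=est, log_estimates=np.log(est), Sigma=Sigma_log)


def _weight_matrix(series: YearlySeries, use_cov: bool) -> np.ndarray:
    if use_cov:
        try:
            c, low = linalg.cho_factor(series.Sigma)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "yearly covariance matrix is singular; cannot weight by it"
            ) from exc
        return linalg.cho_solve((c, low), np.eye(series.T))
    d = np.diag(series.Sigma)
    if np.any(d <= 0):
        raise SingularCovarianceError("zero variance on the diagonal")
    return np.diag(1.0 / d)


def fit_aggregate(series: YearlySeries, spec: JoinpointSpec, use_cov: bool = True) -> AggregateFit:
    """GLS of the log yearly estimates on the standard segmented design.

    ``use_cov=True`` weights by the inverse full covariance; otherwise by
    the inverse diagonal.  The coefficient covariance is the GLS sandwich
    ``(X'Om X)^-1 X'Om Sigma Om X (X'Om X)^-1`` (which collapses to
    ``(X'Sigma^-1 X)^-1`` when Om = Sigma^-1).
    """
    spec.validate_against(series.times)
    t0 = float(series.times[0])
    X = standard_matrix(series.times - t0, np.asarray(spec.taus) - t0).X
    T, p = X.shape
    if T <= p:
        raise ValueError(f"need more time points ({T}) than parameters ({p})")
    Om = _weight_matrix(series, use_cov)
    XtO = X.T @ Om
    A = XtO @ X
    theta_s = np.linalg.solve(A, XtO @ series.log_estimates)
    resid = series.log_estimates - X @ theta_s
    wsse = float(resid @ Om @ resid)
    Ainv = np.linalg.inv(A)
    cov_s = Ainv @ (XtO @ series.Sigma @ XtO.T) @ Ainv
    M = np.eye(p)
    M[0, 1] = -t0
    return AggregateFit(
        spec=spec, theta=M @ theta_s, cov=M @ cov_s @ M.T, wsse=wsse, use_cov=use_cov
    )


def wbic_select(
    series: YearlySeries,
    rules: GridRules | None = None,
    use_cov: bool = True,
    link: str = "lognormal",
) -> AggregateSelection:
    """Grid search per k by weighted SSE, then pick k minimizing WBIC.

    ``WBIC(k) = ln(WSSE_k / T) + (2k + 2) ln(T) / T``; ties break toward
    smaller k.
    """
    rules = rules or GridRules()
    T = series.T
    K = rules.resolve_k_max(T)
    per_k = []
    for k in range(K + 1):
        cands = grid_candidates(series.times, k, rules)
        best = None
        for taus in cands:
            spec = JoinpointSpec(taus, link=link, parameterization="standard")
            if T <= spec.k + 2:
                continue
            try:
                fit = fit_aggregate(series, spec, use_cov)
            except np.linalg.LinAlgError:
                continue
            if best is None or fit.wsse < best.wsse:
                best = fit
        if best is None:
            continue
        wbic = float(np.log(max(best.wsse, 1e-300) / T) + (2 * k + 2) * np.log(T) / T)
        per_k.append(AggregateCandidate(k=k, taus=best.spec.taus, fit=best, wbic=wbic))
    if not per_k:
        raise SingularCovarianceError("no aggregate model could be fit")
    chosen = min(per_k, key=lambda c: (c.wbic, c.k)).k
    return AggregateSelection(per_k=tuple(per_k), chosen_k=chosen, use_cov=use_cov)
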