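"""Joinpoint-number selection: grid search plus modified design-based AIC.

For each candidate number of joinpoints k, a grid search over all feasible
joinpoint locations on the observed time grid picks the best-fitting
constrained model (largest weighted R^2 for the log-normal link, smallest
weighted -2logL for the logistic link).  The number of joinpoints is then
chosen by minimizing the modified design-based AIC

    m.dAIC = n * MSE           + 2 (2k + 1) * delta_bar   (log-normal)
    m.dAIC = (n/N) * (-2logL)  + 2 (2k + 1) * delta_bar   (logistic)

where ``delta_bar`` is an average design effect, ``trace(J^-1 V)`` over the
retained coefficients, N = sum of weights, and 2k + 1 counts the non-intercept
unknowns (k slope changes, k locations, one baseline slope).

``delta_bar`` can be computed two ways:

* **constrained**: from the standard-parameterization fit at the selected
  locations; by default the trace runs over the non-intercept coefficients
  (b1, d_1..d_k), matching the parameters the penalty counts;
* **unconstrained**: fit the general (per-segment) model at the selected
  locations, map its covariances through the linear reparameterization A_k
  to the constrained coordinates, drop the intercept row/column, and take
  the trace over the remaining (k+1) coefficients.  This route propagates
  the extra variability due to estimating the joinpoint locations.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np

from .design import JoinpointSpec
from .estimation import CompressedData, FitResult, compress, fit_model
from .survey_data import SurveyDataset

__all__ = [
    "GridRules",
    "SelectionResult",
    "CandidateResult",
    "grid_candidates",
    "default_k_max",
    "best_model_for_k",
    "ak_matrix",
    "constrained_design_effect",
    "unconstrained_design_effect",
    "m_daic",
    "select_model",
    "select_models",
]


@dataclasses.dataclass(frozen=True)
class GridRules:
    """Feasibility rules for candidate joinpoint locations.

    ``min_obs_end`` observed time points are required strictly outside the
    outermost joinpoints on each side, and ``min_obs_between`` strictly
    between consecutive joinpoints — the defaults (2 and 2) match the NCI
    Joinpoint software conventions.  ``k_max`` may be an integer or "auto"
    (a cap growing with the number of time points T).
    """

    min_obs_between: int = 2
    min_obs_end: int = 2
    k_max: int | str = "auto"

    def __post_init__(self):
        if self.min_obs_between < 0 or self.min_obs_end < 1:
            raise ValueError("min_obs_between >= 0 and min_obs_end >= 1 required")
        if self.k_max != "auto" and int(self.k_max) < 0:
            raise ValueError("k_max must be >= 0 or 'auto'")

    def resolve_k_max(self, n_time_points: int) -> int:
        if self.k_max == "auto":
            return default_k_max(n_time_points)
        return int(self.k_max)


def default_k_max(n_time_points: int) -> int:
    """Default cap on the number of joinpoints as a function of T."""
    bounds = [(6, 0), (11, 1), (16, 2), (21, 3), (26, 4)]
    for upper, k in bounds:
        if n_time_points <= upper:
            return k
    return 5


@dataclasses.dataclass(frozen=True)
class CandidateResult:
    """Best model for one value of k, with its design effect and m.dAIC."""

    k: int
    spec: JoinpointSpec
    fit: FitResult
    delta_bar: float
    m_daic: float


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    """Per-k best models, their m.dAIC values, and the overall choice."""

    per_k: tuple
    chosen_k: int
    approach: str

    @property
    def chosen(self) -> CandidateResult:
        for c in self.per_k:
            if c.k == self.chosen_k:
                return c
        raise LookupError(f"k={self.chosen_k} not among candidates")


def grid_candidates(time_points, k: int, rules: GridRules | None = None) -> list:
    """All feasible strictly-increasing k-tuples of interior time points.

    Feasibility: at least ``min_obs_end`` observed points strictly before the
    first and strictly after the last joinpoint, and at least
    ``min_obs_between`` observed points strictly between consecutive
    joinpoints.  Returned in lexicographic order; ``k=0`` yields ``[()]``.
    """
    rules = rules or GridRules()
    tp = np.unique(np.asarray(time_points, dtype=float))
    T = tp.shape[0]
    if k == 0:
        return [()]
    out = []
    for idx in combinations(range(T), k):
        if idx[0] < rules.min_obs_end or (T - 1 - idx[-1]) < rules.min_obs_end:
            continue
        if any(idx[j + 1] - idx[j] - 1 < rules.min_obs_between for j in range(k - 1)):
            continue
        out.append(tuple(float(tp[i]) for i in idx))
    return out


def best_model_for_k(
    dataset: SurveyDataset,
    k: int,
    rules: GridRules | None = None,
    link: str | None = None,
    compressed: CompressedData | None = None,
) -> tuple[JoinpointSpec, FitResult]:
    """Grid search: fit the constrained model at every feasible location.

    Returns the candidate with the largest weighted R^2 (log-normal) or the
    smallest weighted -2logL (logistic); ties break toward the
    lexicographically smallest joinpoint tuple.
    """
    link = link or (dataset.link if dataset is not None else None) or "lognormal"
    comp = compressed if compressed is not None else compress(dataset, link)
    cands = grid_candidates(comp.times, k, rules)
    if not cands:
        raise ValueError(f"no feasible joinpoint locations for k={k}")
    best = None
    n_singular = 0
    for taus in cands:
        spec = JoinpointSpec(taus, link=link, parameterization="standard")
        try:
            fit = fit_model(dataset, spec, comp)
        except np.linalg.LinAlgError:
            n_singular += 1
            continue
        crit = fit.neg2logl if link == "logistic" else -fit.r2
        if best is None or crit < best[0]:
            best = (crit, spec, fit)
    if best is None:
        raise np.linalg.LinAlgError(
            f"all {n_singular} candidate fits singular for k={k}"
        )
    return best[1], best[2]


def ak_matrix(k: int) -> np.ndarray:
    """Linear map A_k from per-segment coefficients to constrained ones.

    Maps (b_{1,0}, b_{1,1}, ..., b_{k+1,0}, b_{k+1,1}) to (b0, b1,
    d_1, ..., d_k): the first two rows select the first segment's intercept
    and slope; row 2+s is the slope difference b_{s+1,1} - b_{s,1}.
    Shape (k+2) x (2k+2).
    """
    A = np.zeros((k + 2, 2 * (k + 1)))
    A[0, 0] = 1.0
    A[1, 1] = 1.0
    for s in range(1, k + 1):
        A[1 + s, 2 * (s + 1) - 1] = 1.0
        A[1 + s, 2 * s - 1] = -1.0
    return A


def constrained_design_effect(fit: FitResult, drop_intercept: bool = True) -> float:
    """Average design effect ``trace(J^-1 V)`` from a constrained fit.

    By default the intercept row/column is removed before the trace,
    mirroring the unconstrained route and matching the criterion's penalty,
    which counts only the 2k+1 non-intercept unknowns; with long-lived
    cluster effects the intercept's design effect is huge but carries no
    information about trend shape, and retaining it makes the criterion
    unable to detect even large slope changes.  ``drop_intercept=False``
    keeps the full trace over (b0, b1, d_1..d_k).
    """
    J, V = fit.J, fit.V
    if drop_intercept:
        J, V = J[1:, 1:], V[1:, 1:]
    return float(np.trace(np.linalg.solve(J, V)))


def unconstrained_design_effect(
    dataset: SurveyDataset,
    spec: JoinpointSpec,
    compressed: CompressedData | None = None,
) -> float:
    """Average design effect from the general (per-segment) fit at given taus.

    Fits the unconstrained model, transforms its model-based and robust
    covariances through A_k, removes the intercept row/column, and returns
    ``trace(Jtilde^-1 Vtilde)`` over the remaining k+1 coefficients.
    """
    fit = fit_model(dataset, spec.with_parameterization("general"), compressed)
    A = ak_matrix(spec.k)
    Jt = (A @ fit.J @ A.T)[1:, 1:]
    Vt = (A @ fit.V @ A.T)[1:, 1:]
    return float(np.trace(np.linalg.solve(Jt, Vt)))


def m_daic(fit: FitResult, delta_bar: float) -> float:
    """Modified design-based AIC for one fitted model.

    Log-normal: ``n * MSE + 2(2k+1) delta_bar``; logistic:
    ``(n/N) * (-2logL) + 2(2k+1) delta_bar`` with N the sum of weights over
    the records used (the estimated population size).
    """
    k = fit.spec.k
    penalty = 2.0 * (2 * k + 1) * delta_bar
    if fit.spec.link == "lognormal":
        return fit.n_used * fit.mse + penalty
    return (fit.n_used / fit.sum_w_used) * fit.neg2logl + penalty


def select_models(
    dataset: SurveyDataset,
    rules: GridRules | None = None,
    approaches: tuple = ("constrained", "unconstrained"),
    link: str | None = None,
    compressed: CompressedData | None = None,
) -> dict:
    """Run the full selection once, scoring several delta-bar approaches.

    The per-k grid search (the expensive part) is shared; each approach only
    recomputes its design effect and criterion.  Returns a dict mapping
    approach name to :class:`SelectionResult`.
    """
    rules = rules or GridRules()
    link = link or (dataset.link if dataset is not None else None) or "lognormal"
    comp = compressed if compressed is not None else compress(dataset, link)
    K = rules.resolve_k_max(comp.T)
    base = []  # (k, spec, fit)
    for k in range(K + 1):
        if not grid_candidates(comp.times, k, rules):
            continue
        spec, fit = best_model_for_k(dataset, k, rules, link, comp)
        base.append((k, spec, fit))
    if not base:
        raise ValueError("no fittable candidate models")
    out = {}
    for approach in approaches:
        per_k = []
        for k, spec, fit in base:
            if approach == "constrained":
                db = constrained_design_effect(fit)
            else:
                db = unconstrained_design_effect(dataset, spec, comp)
            per_k.append(
                CandidateResult(k=k, spec=spec, fit=fit, delta_bar=db, m_daic=m_daic(fit, db))
            )
        chosen = min(per_k, key=lambda c: (c.m_daic, c.k)).k
        # parsimony on exact ties: the scan order already favors smaller k
        out[approach] = SelectionResult(per_k=tuple(per_k), chosen_k=chosen, approach=approach)
    return out


def select_model(
    dataset: SurveyDataset,
    rules: GridRules | None = None,
    approach: str = "constrained",
    link: str | None = None,
) -> SelectionResult:
    """Grid search over k = 0..K and pick the model minimizing m.dAIC."""
    if approach not in ("constrained", "unconstrained"):
        raise ValueError(f"unknown approach {approach!r}")
    return select_models(dataset, rules, (approach,), link)[approach]
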