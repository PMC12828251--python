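"""Design matrices for segmented (joinpoint) regression.

Two parameterizations of a k-joinpoint piecewise-linear mean are used:

* **standard** (constrained): the mean is continuous at every joinpoint,
  ``m(t) = b0 + b1*t + sum_u d_u * (t - tau_u)_+`` with the hinge indicator
  strict (``(t - tau)_+ = t - tau`` iff ``t > tau``, else 0).  Columns are
  ``(b0, b1, d_1, ..., d_k)``, p = k + 2.
* **general** (unconstrained): each of the k+1 segments gets its own
  intercept and slope, ``m(t) = b_{s,0} + b_{s,1} t`` for t in segment s.
  Segments are the half-open bins ``B_1 = [t_min, tau_1)``, ``B_s =
  [tau_{s-1}, tau_s)``, ``B_{k+1} = [tau_k, t_max]``; records whose time
  equals a joinpoint ("offending observations") are dropped.  Columns are
  ``(b_{1,0}, b_{1,1}, ..., b_{k+1,0}, b_{k+1,1})``, p = 2(k+1).

Joinpoint locations are restricted to the observed time grid and must be
interior (strictly between the first and last observed times).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "JoinpointSpec",
    "DesignMatrix",
    "RankDeficiencyError",
    "standard_row",
    "standard_matrix",
    "general_matrix",
    "segment_slopes_from_standard",
    "segment_intercepts_from_standard",
]

#: Relative tolerance for "time equals joinpoint" when times carry noise.
TIME_EQ_RTOL = 1e-9


class RankDeficiencyError(ValueError):
    """A segment has too few distinct time values to identify its line."""


@dataclasses.dataclass(frozen=True)
class JoinpointSpec:
    """Number and location of joinpoints plus link and parameterization.

    ``taus`` must be strictly increasing; validity against an observed time
    grid (membership and interiority) is checked by :meth:`validate_against`.
    """

    taus: tuple
    link: str = "lognormal"
    parameterization: str = "standard"

    def __post_init__(self):
        taus = tuple(float(t) for t in self.taus)
        object.__setattr__(self, "taus", taus)
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("joinpoints must be strictly increasing")
        if self.link not in ("lognormal", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.parameterization not in ("standard", "general"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    @property
    def k(self) -> int:
        return len(self.taus)

    def validate_against(self, time_points: np.ndarray) -> None:
        """Check every joinpoint is an interior observed time point."""
        tp = np.asarray(time_points, dtype=float)
        for tau in self.taus:
            if not np.any(np.isclose(tp, tau, rtol=TIME_EQ_RTOL, atol=0.0)):
                raise ValueError(f"joinpoint {tau} is not an observed time point")
        if self.taus and (self.taus[0] <= tp[0] or self.taus[-1] >= tp[-1]):
            raise ValueError("joinpoints must be strictly interior to the time range")

    def with_parameterization(self, parameterization: str) -> "JoinpointSpec":
        return JoinpointSpec(self.taus, self.link, parameterization)


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """A design matrix together with the record-inclusion mask.

    ``kept_mask`` is all-true for the standard parameterization; the general
    parameterization drops records lying exactly on a joinpoint.
    """

    X: np.ndarray
    kept_mask: np.ndarray
    column_roles: tuple

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standard_row(t: float, taus) -> np.ndarray:
    """Design row [1, t, (t - tau_1)_+, ..., (t - tau_k)_+] for one time.

    The hinge is strict: the term is 0 when ``t <= tau``.
    """
    taus = np.asarray(taus, dtype=float)
    hinges = np.where(t > taus, t - taus, 0.0)
    return np.concatenate([[1.0, float(t)], hinges])


def standard_matrix(times, taus) -> DesignMatrix:
    """Stack :func:`standard_row` over all records; every record is kept."""
    times = np.asarray(times, dtype=float)
    taus = np.asarray(taus, dtype=float)
    n, k = times.shape[0], taus.shape[0]
    X = np.empty((n, 2 + k))
    X[:, 0] = 1.0
    X[:, 1] = times
    if k:
        diff = times[:, None] - taus[None, :]
        X[:, 2:] = np.where(diff > 0, diff, 0.0)
    roles = ("b0", "b1") + tuple(f"d{u + 1}" for u in range(k))
    return DesignMatrix(X=X, kept_mask=np.ones(n, dtype=bool), column_roles=roles)


def _is_offending(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    if taus.size == 0:
        return np.zeros(times.shape[0], dtype=bool)
    return np.isclose(times[:, None], taus[None, :], rtol=TIME_EQ_RTOL, atol=0.0).any(axis=1)


def general_matrix(times, taus) -> DesignMatrix:
    """Per-segment intercept/slope design for the unconstrained model.

    Records with time exactly equal to a joinpoint are dropped.  Raises
    :class:`RankDeficiencyError` if any segment retains fewer than two
    distinct time values.
    """
    times = np.asarray(times, dtype=float)
    taus = np.asarray(taus, dtype=float)
    k = taus.shape[0]
    kept = ~_is_offending(times, taus)
    tk = times[kept]
    # Segment index: number of joinpoints strictly below t (offenders removed).
    seg = np.searchsorted(taus, tk, side="left") if k else np.zeros(tk.shape[0], dtype=int)
    X = np.zeros((tk.shape[0], 2 * (k + 1)))
    rows = np.arange(tk.shape[0])
    X[rows, 2 * seg] = 1.0
    X[rows, 2 * seg + 1] = tk
    for s in range(k + 1):
        if np.unique(tk[seg == s]).shape[0] < 2:
            raise RankDeficiencyError(
                f"segment {s + 1} has fewer than 2 distinct kept time values"
            )
    roles = tuple(
        f"b{s + 1},{c}" for s in range(k + 1) for c in (0, 1)
    )
    return DesignMatrix(X=X, kept_mask=kept, column_roles=roles)


def segment_slopes_from_standard(theta) -> np.ndarray:
    """Per-segment slopes (b_{1,1}, ..., b_{k+1,1}) from (b0, b1, d_1..d_k).

    ``b_{s,1} = b1 + d_1 + ... + d_{s-1}`` (cumulative slope changes).
    """
    theta = np.asarray(theta, dtype=float)
    return np.concatenate([[theta[1]], theta[1] + np.cumsum(theta[2:])])


def segment_intercepts_from_standard(theta, taus) -> np.ndarray:
    """Per-segment intercepts ``b_{s,0} = b0 - sum_{u<s} d_u * tau_u``."""
    theta = np.asarray(theta, dtype=float)
    taus = np.asarray(taus, dtype=float)
    return np.concatenate([[theta[0]], theta[0] - np.cumsum(theta[2:] * taus)])
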