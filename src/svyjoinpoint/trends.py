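"""Annual percent change (APC) and average APC (AAPC) with survey-design CIs.

For a log-scale (or logit-scale) segment slope b, the annual percent change
of the mean (or of the odds, for the logistic link) is ``100 (e^b - 1)``.
Confidence intervals use the t distribution with the survey design degrees
of freedom d (sampled PSUs minus strata), switching to a z interval for
large d.  The AAPC over a fixed interval is the segment-length-weighted
geometric average of the per-segment factors,
``100 (exp(sum gamma~_s b_s) - 1)``, with a z interval built from the
covariance of the slope estimates on the log scale.

Following the recommended practice for joinpoint inference, point estimates
come from the constrained (continuous) fit while standard errors come from
the unconstrained per-segment fit at the same joinpoints — the latter
reflects the extra uncertainty due to estimating the joinpoint locations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .design import JoinpointSpec, segment_slopes_from_standard
from .estimation import fit_model
from .selection import SelectionResult, ak_matrix
from .survey_data import SurveyDataset

__all__ = ["SegmentTrend", "TrendSummary", "apc", "aapc", "summarize"]

#: Above this many design degrees of freedom a z interval replaces the t.
Z_DF_THRESHOLD = 200


@dataclasses.dataclass(frozen=True)
class SegmentTrend:
    """One segment's range, slope, APC (or OAPC) and confidence interval."""

    start: float
    end: float
    slope: float
    se: float
    apc: float
    ci_low: float
    ci_high: float


@dataclasses.dataclass(frozen=True)
class TrendSummary:
    """Per-segment APC/OAPC plus the interval-averaged AAPC/OAAPC."""

    segments: tuple
    aapc: float
    aapc_ci: tuple
    df: int
    interval: tuple
    gammas: np.ndarray
    link: str

    @property
    def gammas_normalized(self) -> np.ndarray:
        return self.gammas / self.gammas.sum()

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per segment plus an AAPC/OAAPC row."""
        label = "OAPC" if self.link == "logistic" else "APC"
        rows = [
            {
                "segment": i + 1,
                "range": f"{s.start:g}-{s.end:g}",
                "measure": label,
                "estimate": s.apc,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
            for i, s in enumerate(self.segments)
        ]
        rows.append(
            {
                "segment": "",
                "range": f"{self.interval[0]:g}-{self.interval[1]:g}",
                "measure": "OAAPC" if self.link == "logistic" else "AAPC",
                "estimate": self.aapc,
                "ci_low": self.aapc_ci[0],
                "ci_high": self.aapc_ci[1],
            }
        )
        return pd.DataFrame(rows)


def _quantile(df: int) -> float:
    if df > Z_DF_THRESHOLD:
        return float(stats.norm.ppf(0.975))
    return float(stats.t.ppf(0.975, df))


def apc(slope: float, se: float, df: int) -> tuple[float, tuple[float, float]]:
    """Annual percent change ``100 (e^slope - 1)`` with a 95% t/z interval.

    The half-width on the log scale is ``se * t_{df,0.975}`` (z beyond
    ``Z_DF_THRESHOLD`` degrees of freedom).
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    phi = se * _quantile(df)
    point = 100.0 * np.expm1(slope)
    return float(point), (float(100.0 * np.expm1(slope - phi)), float(100.0 * np.expm1(slope + phi)))


def aapc(slopes, gammas, V) -> tuple[float, tuple[float, float]]:
    """Average APC over segments weighted by interval lengths gamma.

    ``AAPC = 100 (exp(sum gamma~_s b_s) - 1)`` with ``gamma~`` the
    normalized lengths; the 95% CI uses ``z_0.975 sqrt(gamma~' V gamma~)``
    on the log scale, V being the covariance of the slope estimates from the
    unconstrained fit.
    """
    slopes = np.asarray(slopes, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if not (slopes.shape[0] == gammas.shape[0] == V.shape[0] == V.shape[1]):
        raise ValueError("slopes, gammas and V must have matching dimensions")
    gt = gammas / gammas.sum()
    mean_slope = float(gt @ slopes)
    half = float(stats.norm.ppf(0.975)) * float(np.sqrt(max(gt @ V @ gt, 0.0)))
    point = 100.0 * np.expm1(mean_slope)
    return float(point), (
        float(100.0 * np.expm1(mean_slope - half)),
        float(100.0 * np.expm1(mean_slope + half)),
    )


def summarize(
    selection: SelectionResult,
    dataset: SurveyDataset,
    interval: tuple | None = None,
) -> TrendSummary:
    """Full trend summary for the selected model.

    Slopes come from the chosen constrained fit; their standard errors and
    covariance come from the unconstrained fit at the same joinpoints (slope
    entries of its robust covariance).  ``interval`` defaults to the full
    observed range; segment weights gamma are overlap lengths with it.
    """
    chosen = selection.chosen
    spec = chosen.spec
    tp = dataset.time_points
    t_lo, t_hi = float(tp[0]), float(tp[-1])
    if interval is None:
        interval = (t_lo, t_hi)
    a, b = float(interval[0]), float(interval[1])
    if a >= b or a < t_lo - 1e-9 or b > t_hi + 1e-9:
        raise ValueError(f"interval {interval} outside observed range [{t_lo}, {t_hi}]")

    slopes = segment_slopes_from_standard(chosen.fit.theta)
    k = spec.k

    # slope covariance from the unconstrained fit at the same joinpoints
    ufit = fit_model(dataset, spec.with_parameterization("general"))
    slope_idx = np.arange(1, 2 * (k + 1), 2)
    Vs = ufit.V[np.ix_(slope_idx, slope_idx)]
    ses = np.sqrt(np.clip(np.diag(Vs), 0.0, None))

    df = dataset.design_df
    bounds = np.concatenate([[t_lo], np.asarray(spec.taus, dtype=float), [t_hi]])
    segments = []
    gammas = np.empty(k + 1)
    for s in range(k + 1):
        lo, hi = bounds[s], bounds[s + 1]
        gammas[s] = max(0.0, min(hi, b) - max(lo, a))
        point, ci = apc(slopes[s], ses[s], df)
        segments.append(
            SegmentTrend(
                start=float(lo), end=float(hi), slope=float(slopes[s]),
                se=float(ses[s]), apc=point, ci_low=ci[0], ci_high=ci[1],
            )
        )
    if gammas.sum() <= 0:
        raise ValueError("summary interval does not overlap any segment")

    # segments with zero overlap contribute nothing; drop them for stability
    mask = gammas > 0
    aapc_point, aapc_ci = aapc(slopes[mask], gammas[mask], Vs[np.ix_(mask, mask)])

    return TrendSummary(
        segments=tuple(segments),
        aapc=aapc_point,
        aapc_ci=aapc_ci,
        df=df,
        interval=(a, b),
        gammas=gammas,
        link=spec.link,
    )
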