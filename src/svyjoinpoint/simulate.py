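"""Finite-target-population generator and repeated cluster-sampling engine.

The generator emulates a national household survey design: a finite target
population (FTP) of equal-sized clusters observed over 20 calendar years,
with a single-joinpoint time trend and controllable intra-cluster
correlation (ICC).  Outcomes:

* continuous ("lognormal"): ``log y = mu(t) + u_c + e``, cluster effect
  ``u_c ~ N(0, icc * sigma^2)`` and individual noise ``e ~ N(0,
  (1 - icc) * sigma^2)``; defaults resemble body-mass-index data (baseline
  geometric mean 27, sigma = 0.2).
* binary ("logistic"): ``y ~ Bernoulli(pi_c(t))`` with ``logit pi_c(t) =
  eta(t) + u_c`` and the cluster-effect variance solved from the
  latent-threshold relation ``icc = s_u^2 / (s_u^2 + pi^2 / 3)``; defaults
  resemble obesity prevalence (baseline 0.20).

The trend is segmented-linear on the link scale with one slope change at
``joinpoint_year``; per-segment slopes are ``log(1 + APC / 100)`` so the
configured annual-percent-change difference maps exactly onto the slope
change (a difference of 0 encodes a true 0-joinpoint trend).

Sampling mimics PSU reuse across years: the year range is split into blocks
(by default two 10-year halves); within a block the same randomly drawn
clusters serve every year, and a fresh set is drawn for the next block.
Within each sampled cluster and year, individuals are drawn by simple random
sampling at a fixed or uniformly redrawn rate; weights are inverse inclusion
probabilities, so they sum to the population size for every year.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit, logit

from .survey_data import SurveyDataset

__all__ = [
    "ScenarioConfig",
    "FinitePopulation",
    "apc_to_slope",
    "slope_change_from_apc_diff",
    "generate_ftp",
    "draw_sample",
    "empirical_icc",
]

#: Latent logistic residual variance pi^2 / 3 (threshold model).
_LOGISTIC_VAR = np.pi**2 / 3.0


def apc_to_slope(apc: float) -> float:
    """Link-scale slope per year implied by an annual percent change."""
    return float(np.log1p(apc / 100.0))


def slope_change_from_apc_diff(base_apc: float, apc_diff: float) -> float:
    """Slope change at the joinpoint for a given APC (or OAPC) difference.

    The post-joinpoint APC is ``base_apc + apc_diff`` percentage points.
    """
    return apc_to_slope(base_apc + apc_diff) - apc_to_slope(base_apc)


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    The full-scale study uses 1000 clusters of 1000 individuals, years
    1997-2016, 80 clusters sampled per year in two 10-year overlap blocks;
    :meth:`desk_scale` shrinks the population (200 x 200, 16 clusters/year)
    while preserving the 8% cluster-sampling fraction and within-cluster
    rates.
    """

    icc: float
    link: str = "lognormal"
    n_clusters: int = 1000
    cluster_size: int = 1000
    years: tuple = tuple(range(1997, 2017))
    joinpoint_year: float = 2006.0
    base_slope: float = apc_to_slope(0.5)
    slope_change: float = 0.0
    baseline: float = float(np.log(27.0))  # link-scale level at the first year
    sigma: float = 0.2                     # total log-scale SD (continuous)
    clusters_per_year: int = 80
    n_blocks: int = 2
    within_rate: float | str = 0.05        # fraction or "uniform" (U(0.05, 0.15))
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must be in [0, 1)")
        if self.link not in ("lognormal", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.clusters_per_year > self.n_clusters:
            raise ValueError("clusters_per_year cannot exceed n_clusters")
        if isinstance(self.within_rate, str):
            if self.within_rate != "uniform":
                raise ValueError("within_rate must be a fraction or 'uniform'")
        elif not (0.0 < self.within_rate <= 1.0):
            raise ValueError("within_rate must be in (0, 1]")

    @property
    def true_k(self) -> int:
        return 0 if self.slope_change == 0.0 else 1

    @property
    def true_tau(self) -> float:
        return float(self.joinpoint_year)

    def blocks(self) -> list:
        """Year indices per overlap block (contiguous, near-equal split)."""
        idx = np.arange(len(self.years))
        return [list(b) for b in np.array_split(idx, self.n_blocks)]

    @classmethod
    def continuous(cls, icc, apc_diff, rate, seed=0, base_apc=0.5, **kw):
        """Continuous-outcome scenario keyed by the APC difference."""
        return cls(
            icc=icc, link="lognormal", within_rate=rate, seed=seed,
            base_slope=apc_to_slope(base_apc),
            slope_change=slope_change_from_apc_diff(base_apc, apc_diff),
            **kw,
        )

    @classmethod
    def binary(cls, icc, oapc_diff, rate, seed=0, base_oapc=4.0, baseline_prev=0.20, **kw):
        """Binary-outcome scenario keyed by the OAPC (odds APC) difference."""
        return cls(
            icc=icc, link="logistic", within_rate=rate, seed=seed,
            base_slope=apc_to_slope(base_oapc),
            slope_change=slope_change_from_apc_diff(base_oapc, oapc_diff),
            baseline=float(logit(baseline_prev)),
            **kw,
        )

    def desk_scale(self) -> "ScenarioConfig":
        """Reduced population preserving the cluster-sampling fraction."""
        return dataclasses.replace(
            self, n_clusters=200, cluster_size=200, clusters_per_year=16
        )


@dataclasses.dataclass(frozen=True)
class FinitePopulation:
    """A generated census: outcome per (cluster, individual, year)."""

    config: ScenarioConfig
    values: np.ndarray        # (n_clusters, cluster_size, T)
    cluster_effects: np.ndarray

    @property
    def true_k(self) -> int:
        return self.config.true_k

    @property
    def true_tau(self) -> float:
        return self.config.true_tau

    def yearly_means(self) -> np.ndarray:
        """Population mean outcome per year."""
        return self.values.mean(axis=(0, 1))


def _mean_path(config: ScenarioConfig) -> np.ndarray:
    t = np.asarray(config.years, dtype=float)
    t0 = t[0]
    hinge = np.where(t > config.joinpoint_year, t - config.joinpoint_year, 0.0)
    return config.baseline + config.base_slope * (t - t0) + config.slope_change * hinge


def generate_ftp(config: ScenarioConfig, rng: np.random.Generator | None = None) -> FinitePopulation:
    """Generate the finite target population for one scenario.

    Deterministic given ``config.seed`` (or a caller-supplied generator).
    """
    rng = rng or np.random.default_rng(config.seed)
    C, S, T = config.n_clusters, config.cluster_size, len(config.years)
    mu = _mean_path(config)

    if config.link == "lognormal":
        s_u = np.sqrt(config.icc) * config.sigma
        s_e = np.sqrt(1.0 - config.icc) * config.sigma
        u = rng.normal(0.0, s_u, size=C) if s_u > 0 else np.zeros(C)
        e = rng.normal(0.0, s_e, size=(C, S, T))
        values = np.exp(mu[None, None, :] + u[:, None, None] + e)
    else:
        s_u2 = config.icc * _LOGISTIC_VAR / (1.0 - config.icc)
        u = rng.normal(0.0, np.sqrt(s_u2), size=C) if s_u2 > 0 else np.zeros(C)
        pi = expit(mu[None, :] + u[:, None])  # (C, T)
        values = (rng.random((C, S, T)) < pi[:, None, :]).astype(np.int8)
    return FinitePopulation(config=config, values=values, cluster_effects=u)


def draw_sample(
    ftp: FinitePopulation,
    config: ScenarioConfig | None = None,
    replicate_seed: int = 0,
) -> SurveyDataset:
    """Draw one repeated cross-sectional cluster sample from the FTP.

    Per overlap block, ``clusters_per_year`` clusters are drawn by SRS
    without replacement and reused for every year of the block; the PSU
    identity is block-scoped, so a cluster reused for ten years is one PSU.
    Within each sampled cluster-year, individuals are drawn by SRS at the
    configured rate (redrawn per cluster-year for the "uniform" variant).
    Weights are products of the inverse cluster and within-cluster
    inclusion probabilities; the design uses a single stratum.
    """
    config = config or ftp.config
    rng = np.random.default_rng(replicate_seed)
    C, S = config.n_clusters, config.cluster_size
    years = np.asarray(config.years, dtype=float)
    cluster_w = C / config.clusters_per_year

    psu_ids, times, weights, ys = [], [], [], []
    for b, year_idx in enumerate(config.blocks()):
        clusters = rng.choice(C, size=config.clusters_per_year, replace=False)
        for ti in year_idx:
            for c in clusters:
                rate = (
                    rng.uniform(0.05, 0.15)
                    if config.within_rate == "uniform"
                    else float(config.within_rate)
                )
                m = max(1, int(round(rate * S)))
                idx = rng.choice(S, size=m, replace=False)
                vals = ftp.values[c, idx, ti]
                w = cluster_w * (S / m)
                psu_ids.append(np.full(m, b * C + c, dtype=np.int64))
                times.append(np.full(m, years[ti]))
                weights.append(np.full(m, w))
                ys.append(vals.astype(float))

    psu = np.concatenate(psu_ids)
    return SurveyDataset.from_arrays(
        stratum_ids=np.zeros(psu.shape[0], dtype=np.int64),
        psu_ids=psu,
        weight=np.concatenate(weights),
        time=np.concatenate(times),
        y=np.concatenate(ys),
        link=config.link,
    )


def empirical_icc(ftp: FinitePopulation, year_index: int = 0) -> float:
    """One-way ANOVA intra-cluster correlation of the generated outcomes.

    Computed on log outcomes for the continuous link and on the 0/1 values
    for the binary link, for one year of the population.
    """
    v = ftp.values[:, :, year_index].astype(float)
    if ftp.config.link == "lognormal":
        v = np.log(v)
    C, m = v.shape
    grand = v.mean()
    cluster_means = v.mean(axis=1)
    msb = m * ((cluster_means - grand) ** 2).sum() / (C - 1)
    msw = ((v - cluster_means[:, None]) ** 2).sum() / (C * (m - 1))
    return float((msb - msw) / (msb + (m - 1) * msw))
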