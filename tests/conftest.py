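"""Shared fixtures: small synthetic survey datasets built in memory."""

import numpy as np
import pytest
from scipy.special import expit

from svyjoinpoint import SurveyDataset


def make_iid_dataset(
    n=200,
    T=10,
    seed=0,
    link="lognormal",
    intercept=3.3,
    slope=0.005,
    slope_change=0.0,
    tau=None,
    sigma=0.1,
    weight=1.0,
    t0=2000.0,
):
    """Independent records, one per PSU, single stratum, equal weights.

    The mean path is segmented-linear on the link scale with an optional
    slope change at ``tau``.
    """
    rng = np.random.default_rng(seed)
    times = t0 + (np.arange(n) % T).astype(float)
    eta = intercept + slope * (times - t0)
    if tau is not None:
        eta = eta + slope_change * np.clip(times - tau, 0.0, None)
    if link == "lognormal":
        y = np.exp(eta + sigma * rng.standard_normal(n))
    else:
        y = (rng.random(n) < expit(eta)).astype(float)
    return SurveyDataset.from_arrays(
        stratum_ids=np.zeros(n, dtype=np.int64),
        psu_ids=np.arange(n),
        weight=np.full(n, float(weight)),
        time=times,
        y=y,
        link=link,
    )


def make_clustered_dataset(
    n_psu=24,
    per_psu=8,
    T=8,
    seed=0,
    icc=0.2,
    sigma=0.2,
    slope=0.01,
    intercept=3.0,
    weight=1.0,
):
    """Log-normal records clustered in PSUs, each PSU observed at one time."""
    rng = np.random.default_rng(seed)
    psu = np.repeat(np.arange(n_psu), per_psu)
    times = 2000.0 + (np.repeat(np.arange(n_psu), per_psu) % T).astype(float)
    u = rng.normal(0.0, np.sqrt(icc) * sigma, n_psu)
    e = rng.normal(0.0, np.sqrt(1 - icc) * sigma, n_psu * per_psu)
    z = intercept + slope * (times - 2000.0) + u[psu] + e
    return SurveyDataset.from_arrays(
        stratum_ids=np.zeros(psu.shape[0], dtype=np.int64),
        psu_ids=psu,
        weight=np.full(psu.shape[0], float(weight)),
        time=times,
        y=np.exp(z),
    )


@pytest.fixture
def kinked_csv(tmp_path):
    """A 20-year CSV with an obvious joinpoint at 2006 (for CLI tests)."""
    rng = np.random.default_rng(5)
    rows = []
    for year in range(1997, 2017):
        for p in range(6):
            for _ in range(20):
                mu = 3.3 + 0.005 * (year - 1997) - 0.1 * max(0, year - 2006)
                rows.append((0, p, 1.0, year, float(np.exp(mu + 0.05 * rng.standard_normal()))))
    path = tmp_path / "kinked.csv"
    with open(path, "w") as fh:
        fh.write("stratum,psu,weight,time,y\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")
    return path
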