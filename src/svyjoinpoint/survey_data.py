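"""Data model and I/O for individual-level complex survey records.

A :class:`SurveyDataset` holds the per-record design information of a
stratified multistage cluster sample — stratum, primary sampling unit (PSU),
sampling weight, time point and outcome — as flat numpy arrays, together with
integer codes for strata and PSUs used by the variance-estimation routines.

PSU identifiers are scoped *within* stratum (the NHIS convention): the same
PSU label appearing under two strata is treated as two distinct PSUs.  The
design degrees of freedom are the total number of distinct sampled PSUs minus
the number of strata, the usual rule for Taylor-linearization variance
estimation in complex surveys.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "DegenerateDesignError",
    "SurveyDataset",
    "read_dataset",
    "write_dataset",
    "design_df",
    "DEFAULT_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """A record violates a dataset invariant (weight, outcome, design)."""


class DegenerateDesignError(ValidationError):
    """The design has fewer than one degree of freedom (PSUs - strata < 1)."""


#: Logical column names expected in delimited input, remappable by callers.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "stratum": "stratum",
    "psu": "psu",
    "weight": "weight",
    "time": "time",
    "y": "y",
}


@dataclasses.dataclass(frozen=True)
class SurveyDataset:
    """Individual-level survey records with design metadata.

    Attributes
    ----------
    stratum, psu : ndarray of int
        Zero-based integer codes per record.  PSU codes are globally unique
        and nested within strata (built from (stratum, psu) label pairs).
    weight : ndarray of float
        Positive sampling weights (inverse inclusion probabilities).
    time : ndarray of float
        Real-valued time point per record (e.g. calendar year).
    y : ndarray of float
        Outcome; positive and continuous for the log-normal link, 0/1 for
        the logistic link.
    stratum_ids, psu_ids : ndarray of object
        Original per-record labels, preserved for round-tripping.
    link : str or None
        "lognormal", "logistic" or None if not declared.
    n_rejected : int
        Count of input rows dropped for missing mapped fields.
    """

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray
    time: np.ndarray
    y: np.ndarray
    stratum_ids: np.ndarray
    psu_ids: np.ndarray
    link: str | None = None
    n_rejected: int = 0

    # ----- derived design quantities -------------------------------------
    @property
    def n(self) -> int:
        """Total record count."""
        return int(self.y.shape[0])

    @property
    def time_points(self) -> np.ndarray:
        """Sorted distinct observed times t_1 < ... < t_T."""
        return np.unique(self.time)

    @property
    def strata_count(self) -> int:
        return int(self.stratum.max()) + 1 if self.n else 0

    @property
    def psu_count(self) -> int:
        return int(self.psu.max()) + 1 if self.n else 0

    @property
    def sum_weights(self) -> float:
        """Estimated population size N = sum of weights."""
        return float(self.weight.sum())

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: sampled PSUs minus strata."""
        return self.psu_count - self.strata_count

    # ----- construction ---------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        stratum_ids,
        psu_ids,
        weight,
        time,
        y,
        link: str | None = None,
        n_rejected: int = 0,
    ) -> "SurveyDataset":
        """Build and validate a dataset from per-record label/value arrays."""
        stratum_ids = np.asarray(stratum_ids)
        psu_ids = np.asarray(psu_ids)
        weight = np.asarray(weight, dtype=float)
        time = np.asarray(time, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        if not (stratum_ids.shape[0] == psu_ids.shape[0] == weight.shape[0] == time.shape[0] == n):
            raise ValidationError("record arrays must have equal length")
        if n == 0:
            raise ValidationError("dataset is empty")
        if not np.all(np.isfinite(weight)) or np.any(weight <= 0):
            raise ValidationError("all sampling weights must be positive and finite")
        if not np.all(np.isfinite(time)):
            raise ValidationError("times must be finite")
        _validate_outcome(y, link)

        str_codes, _ = pd.factorize(stratum_ids, sort=True)
        # PSU scoped within stratum: factorize the (stratum, psu) pair.
        pair = pd.MultiIndex.from_arrays([stratum_ids, psu_ids])
        psu_codes, _ = pair.factorize(sort=True)
        ds = cls(
            stratum=np.asarray(str_codes, dtype=np.int64),
            psu=np.asarray(psu_codes, dtype=np.int64),
            weight=weight,
            time=time,
            y=y,
            stratum_ids=stratum_ids,
            psu_ids=psu_ids,
            link=link,
            n_rejected=n_rejected,
        )
        if ds.time_points.shape[0] < 2:
            raise ValidationError("at least two distinct time points are required")
        if ds.design_df < 1:
            raise DegenerateDesignError(
                f"design degrees of freedom = {ds.design_df} < 1 "
                f"({ds.psu_count} PSUs, {ds.strata_count} strata)"
            )
        return ds

    def to_frame(self, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS)
        if column_map:
            cols.update(column_map)
        return pd.DataFrame(
            {
                cols["stratum"]: self.stratum_ids,
                cols["psu"]: self.psu_ids,
                cols["weight"]: self.weight,
                cols["time"]: self.time,
                cols["y"]: self.y,
            }
        )


def _validate_outcome(y: np.ndarray, link: str | None) -> None:
    if not np.all(np.isfinite(y)):
        raise ValidationError("outcomes must be finite")
    if link == "lognormal":
        if np.any(y <= 0):
            raise ValidationError("log-normal link requires strictly positive outcomes")
    elif link == "logistic":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValidationError("logistic link requires 0/1 outcomes")
    elif link is not None:
        raise ValidationError(f"unknown link {link!r}")


def read_dataset(
    path,
    column_map: Mapping[str, str] | None = None,
    link: str | None = None,
) -> SurveyDataset:
    """Read individual-level survey records from a delimited text file.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    column_map : mapping, optional
        Maps the logical names ``stratum, psu, weight, time, y`` to the
        column names actually present in the file.
    link : str, optional
        "lognormal" or "logistic"; enables outcome validation.

    Rows with missing values in any mapped column are rejected; the count is
    recorded on the returned dataset as ``n_rejected``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    sub = df[[cols[k] for k in ("stratum", "psu", "weight", "time", "y")]]
    keep = sub.notna().all(axis=1)
    n_rejected = int((~keep).sum())
    sub = sub[keep]
    if sub.empty:
        raise ValidationError("no complete records in input")
    return SurveyDataset.from_arrays(
        sub.iloc[:, 0].to_numpy(),
        sub.iloc[:, 1].to_numpy(),
        sub.iloc[:, 2].to_numpy(dtype=float),
        sub.iloc[:, 3].to_numpy(dtype=float),
        sub.iloc[:, 4].to_numpy(dtype=float),
        link=link,
        n_rejected=n_rejected,
    )


def write_dataset(dataset: SurveyDataset, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a dataset back to CSV in the same dialect ``read_dataset`` accepts.

    Times and weights are written as shortest round-tripping decimal text, so
    read-write-read preserves all fields bit-exactly.
    """
    dataset.to_frame(column_map).to_csv(path, index=False)


def design_df(dataset: SurveyDataset) -> int:
    """Design degrees of freedom: total sampled PSUs minus total strata.

    Raises :class:`DegenerateDesignError` if the result is below 1 (a design
    with no replication for variance estimation).
    """
    d = dataset.design_df
    if d < 1:
        raise DegenerateDesignError(f"design degrees of freedom = {d} < 1")
    return d
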