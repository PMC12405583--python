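"""Labelled-fraction time courses.

The common input of every kinetic fit is a table of percent-labelled cells
(photoconverted Dred+, BrdU+ or EdU+) measured at a handful of time points in
a few biological replicates.  :class:`LabelTimeCourse` holds that table with an
explicit time unit and performs the validation every estimator relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

HOURS_PER_DAY = 24.0

#: Accepted time-unit vocabulary.  Conversions are always explicit.
TIME_UNITS = ("days", "hours")


@dataclass
class LabelTimeCourse:
    """Replicate measurements of a percent-labelled fraction over time.

    Parameters
    ----------
    times : array-like of float
        Measurement times, one per observation (replicates repeat the time).
        Must be non-negative.
    values : array-like of float
        Percent labelled, in [0, 100], one per observation.
    replicates : array-like of int, optional
        Replicate id per observation.  Defaults to all zeros.
    unit : {"days", "hours"}
        Unit of ``times``.
    population : str
        Free-text population label (e.g. ``"total cDC"``, ``"cDC1"``).
    meta : dict
        Free-form provenance (generator parameters, clipping counts, ...).
    """

    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray | None = None
    unit: str = "days"
    population: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.replicates is None:
            self.replicates = np.zeros(self.times.size, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates, dtype=int).ravel()
        if not (self.times.size == self.values.size == self.replicates.size):
            raise InvalidInputError(
                "times, values and replicates must have equal length "
                f"(got {self.times.size}, {self.values.size}, {self.replicates.size})"
            )
        if self.times.size == 0:
            raise InvalidInputError("empty time course")
        if self.unit not in TIME_UNITS:
            raise InvalidInputError(
                f"unit must be one of {TIME_UNITS}, got {self.unit!r}"
            )
        if np.any(self.times < 0) or not np.all(np.isfinite(self.times)):
            raise InvalidInputError("times must be finite and non-negative")
        if (
            np.any(self.values < 0)
            or np.any(self.values > 100)
            or not np.all(np.isfinite(self.values))
        ):
            raise InvalidInputError("values must be finite percentages in [0, 100]")

    # -- basic queries -----------------------------------------------------

    @property
    def distinct_times(self) -> np.ndarray:
        """Sorted unique time points."""
        return np.unique(self.times)

    @property
    def n_distinct_times(self) -> int:
        return self.distinct_times.size

    def require_distinct_times(self, n: int, what: str = "fit") -> None:
        if self.n_distinct_times < n:
            raise InvalidInputError(
                f"{what} requires at least {n} distinct time points; "
                f"time course {self.population!r} has {self.n_distinct_times}"
            )

    # -- transforms --------------------------------------------------------

    def to_days(self) -> "LabelTimeCourse":
        """Return an equivalent time course with times in days."""
        if self.unit == "days":
            return self
        return LabelTimeCourse(
            self.times / HOURS_PER_DAY,
            self.values,
            self.replicates,
            unit="days",
            population=self.population,
            meta=dict(self.meta),
        )

    def to_hours(self) -> "LabelTimeCourse":
        if self.unit == "hours":
            return self
        return LabelTimeCourse(
            self.times * HOURS_PER_DAY,
            self.values,
            self.replicates,
            unit="hours",
            population=self.population,
            meta=dict(self.meta),
        )

    def complement(self) -> "LabelTimeCourse":
        """Swap label channels: Dred+ <-> Dred- (percent -> 100 - percent).

        Photoconversion conserves Dred+ % + Dred- % = 100, so a fit on either
        channel carries the same information (slopes negate).
        """
        return LabelTimeCourse(
            self.times.copy(),
            100.0 - self.values,
            self.replicates.copy(),
            unit=self.unit,
            population=self.population,
            meta=dict(self.meta),
        )

    def mean_by_time(self) -> pd.DataFrame:
        """Replicate means per distinct time point (for reports/plots)."""
        df = self.to_dataframe()
        return (
            df.groupby("time", as_index=False)["percent_labelled"]
            .mean()
            .sort_values("time", ignore_index=True)
        )

    # -- conversion --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "unit": self.unit,
                "replicate": self.replicates,
                "population": self.population,
                "percent_labelled": self.values,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabelTimeCourse":
        required = {"time", "unit", "replicate", "population", "percent_labelled"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(
                f"time-course table missing column(s): {sorted(missing)}; "
                f"required vocabulary is {sorted(required)}"
            )
        units = df["unit"].unique()
        if len(units) != 1:
            raise InvalidInputError(f"mixed time units in one table: {list(units)}")
        populations = df["population"].unique()
        population = str(populations[0]) if len(populations) == 1 else "mixed"
        return cls(
            df["time"].to_numpy(dtype=float),
            df["percent_labelled"].to_numpy(dtype=float),
            df["replicate"].to_numpy(dtype=int),
            unit=str(units[0]),
            population=population,
        )


def as_timecourse(
    times: Iterable[float],
    values: Iterable[float],
    unit: str = "days",
    **kwargs,
) -> LabelTimeCourse:
    """Convenience constructor used throughout the tests and examples."""
    return LabelTimeCourse(np.asarray(list(times)), np.asarray(list(values)),
                           unit=unit, **kwargs)
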