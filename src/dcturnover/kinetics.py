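"""Descriptive kinetic fits of labelled-fraction time courses.

Four estimators cover the empirical analyses of label-dilution experiments in
the gut cDC system:

* :class:`LinearTurnoverRegressor` — ordinary least squares of percent
  labelled on time for the near-linear decline of photoconverted (Dred+)
  cells in the small-intestinal lamina propria; derives the half-replacement
  time T50 and the extrapolated complete-turnover time.
* :class:`ExponentialDecayRegressor` — nonlinear least squares of
  ``A * exp(-r t)`` for the fast replacement of migratory mesenteric-lymph-node
  cDCs, with half-life ``ln 2 / r``.
* :class:`BrduEgressRegressor` — linear decline of a BrdU+ fraction during
  chase, normalised by the labelled fraction at the first chase time point to
  yield a tissue egress rate in percent of the population per day.
* :func:`summarize_maturation_bins` — EdU+ percentages across ordered
  maturation bins (M1..M4 by surface MHCII, then CCR7+), with pattern flags.

All estimators follow scikit-learn conventions (``fit(X, y)``, fitted
attributes with trailing underscores, ``get_params``/``set_params``); the
module-level functions accept a :class:`~dcturnover.timecourse.LabelTimeCourse`
and return frozen result dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitFailureError, InvalidInputError
from .timecourse import LabelTimeCourse

__all__ = [
    "LinearTurnoverFit",
    "ExponentialDecayFit",
    "BrduEgressEstimate",
    "MaturationProfile",
    "LinearTurnoverRegressor",
    "ExponentialDecayRegressor",
    "BrduEgressRegressor",
    "fit_linear_turnover",
    "fit_exponential_decay",
    "estimate_egress_rate_brdu",
    "replaced_fraction_at",
    "summarize_maturation_bins",
    "MATURATION_BINS",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTurnoverFit:
    """Linear replacement kinetics, percent labelled = intercept + slope * t.

    ``t50`` is the time at which the fitted line crosses 50% — the time after
    which half the compartment has been replaced by unlabelled cells — and is
    only defined for a declining line starting above 50%.  The extrapolated
    complete-turnover time is ``2 * t50``.
    """

    slope: float  # percent per day, signed
    intercept: float  # percent at t = 0
    r_squared: float
    t50: float  # days; NaN when undefined
    daily_turnover_rate: float  # percent per day, = |slope|
    complete_turnover_time: float  # days; NaN when undefined
    t50_defined: bool
    unit: str = "days"

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ExponentialDecayFit:
    """Exponential replacement kinetics, percent labelled = A * exp(-r t).

    ``rate`` is per unit of the input time axis (``unit``); ``half_life`` is
    ``ln 2 / rate`` in the same unit.
    """

    amplitude: float  # percent at t = 0
    rate: float  # per `unit`, positive
    half_life: float  # same unit as `unit`
    residual_sse: float  # squared percent
    unit: str = "hours"

    @classmethod
    def from_half_life(cls, half_life: float, amplitude: float = 100.0,
                       unit: str = "hours") -> "ExponentialDecayFit":
        if half_life <= 0:
            raise InvalidInputError("half_life must be positive")
        return cls(amplitude=float(amplitude), rate=math.log(2) / half_life,
                   half_life=float(half_life), residual_sse=0.0, unit=unit)

    def predict(self, t):
        return self.amplitude * np.exp(-self.rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class BrduEgressEstimate:
    """Egress rate from the decline of a BrdU+ fraction during chase.

    The absolute decline (percentage points/day) divided by the labelled
    fraction at the first chase time point converts the decline into percent
    of the whole population leaving the tissue per day.
    """

    slope_pp_per_day: float  # percentage points per day (absolute decline)
    peak_labelled_fraction: float  # fitted percent at the first chase time
    egress_rate_percent_per_day: float
    physical: bool  # False when the BrdU+ fraction increased over chase


@dataclass(frozen=True)
class MaturationProfile:
    """EdU+ percentages across maturation bins with pattern flags."""

    bins: tuple
    means: dict
    values: dict = field(repr=False, default_factory=dict)
    monotone_rise_m1_m4: bool = False
    drop_at_ccr7: bool = False


# ---------------------------------------------------------------------------
# linear turnover
# ---------------------------------------------------------------------------


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InvalidInputError("X must be a single time column")
        X = X[:, 0]
    y = np.asarray(y, dtype=float).ravel()
    if X.size != y.size:
        raise InvalidInputError("X and y must have equal length")
    return X, y


#: slopes below this magnitude (pp per day) are numerical zero: percentages
#: are O(100) and times O(10) days, so real slopes are far larger
_SLOPE_EPS = 1e-10


def _ols_line(t, y):
    """Least-squares line with an r^2 that is well defined for flat data."""
    slope, intercept = np.polyfit(t, y, 1)
    if abs(slope) < _SLOPE_EPS:
        slope = 0.0
    resid = y - (intercept + slope * t)
    sse = float(np.dot(resid, resid))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else max(0.0, 1.0 - sse / sst)
    return float(slope), float(intercept), r2, sse


class LinearTurnoverRegressor(RegressorMixin, BaseEstimator):
    """OLS of percent labelled on time (days), pooling replicate points.

    Fitted attributes
    -----------------
    slope_ : percent per day (signed)
    intercept_ : percent at t = 0
    r_squared_ : coefficient of determination
    t50_ : days; NaN if the line does not decline through 50%
    daily_turnover_rate_ : ``abs(slope_)``
    complete_turnover_time_ : ``2 * t50_``
    t50_defined_ : bool
    """

    def fit(self, X, y):
        t, y = _validate_xy(X, y)
        if np.unique(t).size < 2:
            raise InvalidInputError(
                "linear turnover fit requires >= 2 distinct time points"
            )
        self.slope_, self.intercept_, self.r_squared_, self.sse_ = _ols_line(t, y)
        if self.slope_ < 0 and self.intercept_ > 50:
            self.t50_ = (self.intercept_ - 50.0) / abs(self.slope_)
            self.t50_defined_ = True
        else:
            self.t50_ = float("nan")
            self.t50_defined_ = False
        self.daily_turnover_rate_ = abs(self.slope_)
        self.complete_turnover_time_ = 2.0 * self.t50_
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return self.intercept_ + self.slope_ * t

    def result(self, unit: str = "days") -> LinearTurnoverFit:
        return LinearTurnoverFit(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            t50=self.t50_,
            daily_turnover_rate=self.daily_turnover_rate_,
            complete_turnover_time=self.complete_turnover_time_,
            t50_defined=self.t50_defined_,
            unit=unit,
        )


def fit_linear_turnover(tc: LabelTimeCourse) -> LinearTurnoverFit:
    """Fit linear replacement kinetics to a photoconversion time course.

    Times given in hours are converted to days; replicates are pooled so each
    measurement is one OLS point.
    """
    tc = tc.to_days()
    tc.require_distinct_times(2, "linear turnover fit")
    est = LinearTurnoverRegressor().fit(tc.times[:, None], tc.values)
    return est.result(unit="days")


# ---------------------------------------------------------------------------
# exponential decay
# ---------------------------------------------------------------------------


def _exp_model(t, amplitude, rate):
    return amplitude * np.exp(-rate * t)


class ExponentialDecayRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least squares of ``A * exp(-r t)``.

    The fit is initialised from a log-linear regression on the positive
    observations; the amplitude is free (photoconversion efficiency at t = 0
    is below 100%).  A small set of deterministic restarts guards against
    local minima before a :class:`FitFailureError` is raised.

    Parameters
    ----------
    max_amplitude : float
        Upper bound for the fitted amplitude (percent scale).
    """

    def __init__(self, max_amplitude: float = 200.0):
        self.max_amplitude = max_amplitude

    def fit(self, X, y):
        t, y = _validate_xy(X, y)
        pos = y > 0
        if np.unique(t).size < 3 or np.unique(t[pos]).size < 3:
            raise InvalidInputError(
                "exponential fit requires >= 3 distinct time points with "
                "positive values"
            )
        # log-linear initialisation on the positive points
        b, log_a = np.polyfit(t[pos], np.log(y[pos]), 1)
        starts = [
            (float(np.exp(log_a)), max(-float(b), 1e-6)),
            (float(np.max(y)), max(-float(b), 1e-6)),
            (float(np.max(y)), math.log(2) / max(np.ptp(t), 1e-6)),
        ]
        best = None
        for a0, r0 in starts:
            a0 = min(a0, self.max_amplitude)
            try:
                popt, _ = optimize.curve_fit(
                    _exp_model, t, y, p0=[a0, r0],
                    bounds=([0.0, 1e-12], [self.max_amplitude, np.inf]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((y - _exp_model(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            raise FitFailureError(
                f"exponential decay fit did not converge on data with "
                f"{t.size} points spanning t in [{t.min()}, {t.max()}]"
            )
        sse, (amplitude, rate) = best
        self.amplitude_ = float(amplitude)
        self.rate_ = float(rate)
        self.half_life_ = math.log(2) / self.rate_
        self.residual_sse_ = sse
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return _exp_model(t, self.amplitude_, self.rate_)

    def result(self, unit: str = "hours") -> ExponentialDecayFit:
        return ExponentialDecayFit(
            amplitude=self.amplitude_,
            rate=self.rate_,
            half_life=self.half_life_,
            residual_sse=self.residual_sse_,
            unit=unit,
        )


def fit_exponential_decay(tc: LabelTimeCourse) -> ExponentialDecayFit:
    """Fit exponential replacement kinetics; rate/half-life carry the input unit."""
    tc.require_distinct_times(3, "exponential decay fit")
    est = ExponentialDecayRegressor().fit(tc.times[:, None], tc.values)
    return est.result(unit=tc.unit)


def replaced_fraction_at(fit: ExponentialDecayFit, t: float):
    """Percent of the compartment replaced by unlabelled cells at time ``t``.

    ``100 * (1 - exp(-rate t)) = 100 * (1 - 2**(-t / half_life))``, in the
    time unit of the fit.  Monotone increasing in t, 0 at t = 0, approaching
    100% as t grows.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("replaced fraction is only defined for t >= 0")
    out = 100.0 * (1.0 - np.exp(-fit.rate * t))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# BrdU egress
# ---------------------------------------------------------------------------


class BrduEgressRegressor(RegressorMixin, BaseEstimator):
    """Egress rate from a BrdU pulse-chase series (times in days).

    Fits a line to the BrdU+ percentage during chase.  The absolute slope
    (percentage points/day) is divided by the fitted labelled fraction at the
    first chase time point — i.e. the fraction of labelled cells lost per day
    is re-expressed as a percent of the whole population leaving per day.
    """

    def fit(self, X, y):
        t, y = _validate_xy(X, y)
        if np.unique(t).size < 2:
            raise InvalidInputError("egress estimate requires >= 2 chase time points")
        slope, intercept, self.r_squared_, _ = _ols_line(t, y)
        self.slope_pp_per_day_ = abs(slope)
        first = float(np.min(t))
        self.peak_labelled_fraction_ = intercept + slope * first
        self.physical_ = bool(slope <= 0 and self.peak_labelled_fraction_ > 0)
        if self.physical_ and self.peak_labelled_fraction_ > 0:
            self.egress_rate_percent_per_day_ = (
                100.0 * self.slope_pp_per_day_ / self.peak_labelled_fraction_
            )
        else:
            self.egress_rate_percent_per_day_ = float("nan")
        self._slope_signed = slope
        self._intercept = intercept
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        t = X[:, 0] if X.ndim == 2 else X
        return self._intercept + self._slope_signed * t

    def result(self) -> BrduEgressEstimate:
        return BrduEgressEstimate(
            slope_pp_per_day=self.slope_pp_per_day_,
            peak_labelled_fraction=self.peak_labelled_fraction_,
            egress_rate_percent_per_day=self.egress_rate_percent_per_day_,
            physical=self.physical_,
        )


def estimate_egress_rate_brdu(tc: LabelTimeCourse) -> BrduEgressEstimate:
    """Estimate the daily tissue egress rate from a BrdU chase time course.

    An increasing BrdU+ fraction yields an estimate flagged non-physical
    (``physical=False``) rather than an exception, so batch analyses do not
    abort.
    """
    tc = tc.to_days()
    tc.require_distinct_times(2, "BrdU egress estimate")
    est = BrduEgressRegressor().fit(tc.times[:, None], tc.values)
    return est.result()


# ---------------------------------------------------------------------------
# maturation bins
# ---------------------------------------------------------------------------

#: Ordered maturation bins: MHCII-surface quartiles of the CCR7- compartment,
#: then the pre-migratory CCR7+ cells.
MATURATION_BINS = ("M1", "M2", "M3", "M4", "CCR7+")


def summarize_maturation_bins(bins: dict | "pd.DataFrame") -> MaturationProfile:
    """Summarise per-replicate EdU+ percentages across maturation bins.

    Parameters
    ----------
    bins : mapping or DataFrame
        Either ``{bin label: sequence of per-replicate EdU+ percents}`` or a
        long-format DataFrame with columns ``bin`` and ``percent_edu``.

    Returns
    -------
    MaturationProfile
        Per-bin means plus two pattern flags: a non-strict monotone rise of
        the means across M1..M4, and a drop of the CCR7+ mean below M4 —
        the signature of proliferation increasing with maturation and shutting
        down in pre-migratory cells.
    """
    import pandas as pd

    if isinstance(bins, pd.DataFrame):
        missing = {"bin", "percent_edu"} - set(bins.columns)
        if missing:
            raise InvalidInputError(
                f"maturation table missing column(s): {sorted(missing)}"
            )
        grouped = {
            str(b): g["percent_edu"].to_numpy(dtype=float)
            for b, g in bins.groupby("bin")
        }
    else:
        grouped = {str(k): np.asarray(v, dtype=float).ravel() for k, v in bins.items()}

    absent = [b for b in MATURATION_BINS if b not in grouped or grouped[b].size == 0]
    if absent:
        raise InvalidInputError(f"missing maturation bin(s): {absent}")

    means = {b: float(np.mean(grouped[b])) for b in MATURATION_BINS}
    m = [means[b] for b in MATURATION_BINS[:4]]
    monotone = bool(all(m[i] <= m[i + 1] for i in range(3)))
    drop = bool(means["CCR7+"] < means["M4"])
    return MaturationProfile(
        bins=MATURATION_BINS,
        means=means,
        values={b: grouped[b] for b in MATURATION_BINS},
        monotone_rise_m1_m4=monotone,
        drop_at_ccr7=drop,
    )
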