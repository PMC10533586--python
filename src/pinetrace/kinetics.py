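"""Tracer kinetics: residence time, label arrival, transport velocity.

The washout of pulse-derived 13C from the needle pool is described by a
single-pool first-order model

    N(t) = N0 * exp(-lambda * t),    tau = 1 / lambda,

fitted from the labelling peak onward. The whole-path transport velocity
from crown to rhizosphere is the tree height divided by the arrival lag of
the 13C signal in soil pore CO2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .isotope import ExcessSeries

__all__ = [
    "ExponentialDecayModel", "DecayResults", "NonDecayingSeriesError",
    "ArrivalLag", "detect_arrival", "transport_velocity", "TransportVelocity",
    "fraction_allocated", "cumulative_released", "peak_time",
]


class NonDecayingSeriesError(RuntimeError):
    """The best-fitting decay constant is not positive; no residence time."""


@dataclass
class DecayResults:
    """Fitted first-order washout: estimates, uncertainties, diagnostics."""

    n0: float              # mg 13C m-2 at the labelling peak
    lam: float             # day-1
    n0_se: float
    lam_se: float
    rss: float
    n_points: int
    times: np.ndarray
    values: np.ndarray

    @property
    def tau(self) -> float:
        """Mean residence time, days (1 / lambda)."""
        return 1.0 / self.lam

    @property
    def tau_se(self) -> float:
        # delta method: var(1/lam) ~ var(lam) / lam^4
        return self.lam_se / self.lam ** 2

    def predict(self, t):
        return self.n0 * np.exp(-self.lam * np.asarray(t, dtype=float))

    def summary(self) -> str:
        lines = [
            "First-order washout fit  N(t) = N0 exp(-lambda t)",
            f"  n points (from peak): {self.n_points}",
            f"  N0     = {self.n0:10.4f} +/- {self.n0_se:.4f}  mg 13C m-2",
            f"  lambda = {self.lam:10.4f} +/- {self.lam_se:.4f}  day-1",
            f"  tau    = {self.tau:10.4f} +/- {self.tau_se:.4f}  days",
            f"  RSS    = {self.rss:.6g}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Least-squares model for first-order tracer washout of one series.

    Points before the observed series maximum are excluded (N0 is the
    excess at the labelling peak). The fit is nonlinear least squares on
    the linear scale, initialized from a log-linear regression of the
    positive excess values, so legitimate near-zero or slightly negative
    noisy observations still inform the fit.
    """

    def __init__(self, series: ExcessSeries, from_peak: bool = True):
        if series.kind != "pool":
            raise ValueError("decay fitting expects a pool (mg m-2) series")
        post = series.after(0.0)
        if from_peak and len(post):
            i_peak = int(np.argmax(post.values))
            post = ExcessSeries(post.compartment, post.mesocosm_id,
                                post.times[i_peak:], post.values[i_peak:],
                                post.kind, dict(post.meta))
        if len(post) < 3:
            raise ValueError("need >= 3 points at or after the series maximum")
        if not np.max(post.values) > 0:
            raise ValueError("series maximum must be positive")
        self.series = post

    def _initial_guess(self):
        t, y = self.series.times, self.series.values
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            lam0 = max(-slope, 1e-3)
            n0 = float(np.exp(intercept))
        else:
            lam0, n0 = 0.5, float(np.max(y))
        return n0, lam0

    def fit(self) -> DecayResults:
        t, y = self.series.times, self.series.values
        n0_0, lam0 = self._initial_guess()

        def model(tt, n0, lam):
            return n0 * np.exp(-lam * tt)

        popt, pcov = curve_fit(model, t, y, p0=(n0_0, lam0), maxfev=20000)
        n0, lam = popt
        if lam <= 0:
            raise NonDecayingSeriesError(
                f"fitted decay constant {lam:.4g} day-1 is not positive; "
                "no mean residence time for a non-decaying series")
        resid = y - model(t, *popt)
        se = np.sqrt(np.diag(pcov))
        return DecayResults(n0=float(n0), lam=float(lam),
                            n0_se=float(se[0]), lam_se=float(se[1]),
                            rss=float(resid @ resid), n_points=len(t),
                            times=t, values=y)


@dataclass
class ArrivalLag:
    """First sampled time with a sustained signal above background."""

    lag_days: float | None
    threshold: float
    k: float
    detected: bool

    def __bool__(self):
        return self.detected


def detect_arrival(series: ExcessSeries, baseline_mean: float,
                   baseline_sd: float, k: float = 3.0,
                   require_persistence: bool = True) -> ArrivalLag:
    """Earliest post-label sampled time exceeding background + k * SD.

    The exceedance must persist at the following sample (an exceedance at
    the final sample is accepted as-is). The lag is reported as the sampled
    time point, not an interpolated crossing. A series that never exceeds
    the threshold yields a "no arrival" result, not an exception.
    """
    if baseline_sd < 0 or not np.isfinite(baseline_mean):
        raise ValueError("baseline statistics must be finite, SD >= 0")
    thr = baseline_mean + k * baseline_sd
    post = series.after(0.0)
    above = post.values > thr
    for i in np.flatnonzero(above):
        if (not require_persistence) or i + 1 >= len(post) or above[i + 1]:
            return ArrivalLag(lag_days=float(post.times[i]), threshold=thr,
                              k=k, detected=True)
    return ArrivalLag(lag_days=None, threshold=thr, k=k, detected=False)


@dataclass
class TransportVelocity:
    velocity_cm_d: float
    height_cm: float
    lag_days: float


def transport_velocity(height_cm: float, lag: "ArrivalLag | float") -> TransportVelocity:
    """Whole-path transport velocity: tree height / arrival lag (cm day-1)."""
    lag_days = lag.lag_days if isinstance(lag, ArrivalLag) else float(lag)
    if lag_days is None or not lag_days > 0:
        raise ValueError("transport velocity requires a positive arrival lag")
    if not height_cm > 0:
        raise ValueError("tree height must be positive")
    return TransportVelocity(velocity_cm_d=height_cm / lag_days,
                             height_cm=height_cm, lag_days=lag_days)


def fraction_allocated(series: ExcessSeries, needle_reference: float) -> ExcessSeries:
    """Compartment excess normalized by the total label assimilated.

    The reference is the needle 13C excess measured 45 min after labelling
    (the maximum needle excess), so the needle series itself maps to 1 at
    that time. Slightly negative noisy excess values are truncated at zero
    for fraction reporting.
    """
    if not needle_reference > 0:
        raise ValueError("needle reference excess must be positive")
    frac = np.clip(series.values, 0.0, None) / needle_reference
    return ExcessSeries(series.compartment, series.mesocosm_id, series.times,
                        frac, "pool", {**series.meta, "fraction_of": needle_reference})


def cumulative_released(series: ExcessSeries, t0: float, t1: float) -> float:
    """Trapezoidal integral of a rate series over [t0, t1], mg 13C m-2.

    The series carries mg m-2 h-1 against a time axis in days; the
    day->hour conversion is explicit here.
    """
    if series.kind != "rate":
        raise ValueError("cumulative release needs a rate series (mg m-2 h-1)")
    m = (series.times >= t0) & (series.times <= t1)
    if m.sum() < 2:
        raise ValueError(f"need >= 2 points inside [{t0}, {t1}]")
    return float(np.trapezoid(series.values[m], series.times[m] * 24.0))


def peak_time(series: ExcessSeries) -> float:
    """Sampled time of the series maximum; ties resolve to the earliest."""
    if len(series) == 0 or not np.any(np.isfinite(series.values)):
        raise ValueError("peak time of an empty/all-null series is undefined")
    return float(series.times[int(np.nanargmax(series.values))])
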