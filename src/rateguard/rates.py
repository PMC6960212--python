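"""Specific growth-rate estimators.

Three estimators are compared throughout the package:

* ``stepwise_mu`` — the log-difference of total biomass between consecutive
  samples, mu_i = ln(X_{i+1}/X_i) / dt, the field's standard "integral"
  method.  It assumes mu constant on each interval and propagates the full
  measurement error of both samples into every rate value.
* ``moving_average`` — post-smoothing of a stepwise series with a fixed
  window; the series shortens by window - 1 points (the endpoint problem)
  and rate changes appear delayed.
* ``spline_mu`` — the logarithmic derivative f'(t)/f(t) of a penalized cubic
  smoothing spline f fitted to total biomass, giving a rate value at every
  sample time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import ObservedDataset
from .smoothing import fit_smoothing_spline

__all__ = ["RateSeries", "stepwise_mu", "moving_average", "spline_mu"]

_METHODS = ("stepwise", "stepwise_ma", "spline", "qs_opt1", "qs_opt2", "qs_opt3")


@dataclass
class RateSeries:
    """Estimated rates on a time grid, tagged with the estimator used.

    ``value`` is in 1/h for growth rates and g/g/h for uptake rates.
    """

    t: np.ndarray
    value: np.ndarray
    method: str
    window: Optional[int] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.t.shape != self.value.shape or self.t.ndim != 1:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time_h": self.t, "rate": self.value,
                              "method": self.method})
        frame["window"] = self.window if self.window is not None else pd.NA
        frame["p"] = self.p if self.p is not None else pd.NA
        return frame


def stepwise_mu(obs: ObservedDataset, align: str = "midpoint") -> RateSeries:
    """Stepwise integral estimate of mu from consecutive total-biomass samples.

    Each rate mu_i = ln(X_{i+1}/X_i) / (t_{i+1} - t_i) is timestamped at the
    midpoint of its interval (default), which minimizes phase bias against a
    continuously varying true rate; ``align="end"`` stamps it at the interval
    end, when the value becomes available during a running process.
    """
    if obs.t_sample.size < 2:
        raise ValueError("need at least 2 samples")
    if align not in ("midpoint", "end"):
        raise ValueError("align must be 'midpoint' or 'end'")
    X = obs.total_biomass
    bad = np.flatnonzero(X <= 0)
    if bad.size:
        raise ValueError(f"non-positive total biomass at sample index {bad[0]}")
    dt = np.diff(obs.t_sample)
    mu = np.diff(np.log(X)) / dt
    t = obs.t_sample[:-1] + dt / 2.0 if align == "midpoint" else obs.t_sample[1:]
    return RateSeries(t=t, value=mu, method="stepwise")


def moving_average(series: RateSeries, window: int,
                   align: str = "center") -> RateSeries:
    """Smooth a rate series with a full-window arithmetic moving average.

    Only complete windows are used, so the output has
    ``len(series) - window + 1`` points; the lost endpoints are the price of
    the smoothing.  With ``align="center"`` (default) each value is
    timestamped at the mean time of its window, the phase-neutral choice for
    retrospective comparison against a continuously varying true rate.  With
    ``align="trailing"`` it is stamped at the window's last timestamp — the
    moment the value actually becomes available during a running process —
    which exposes the apparent delay of rate changes under this filter.
    """
    window = int(window)
    if window < 2:
        raise ValueError("window must be at least 2")
    if window > len(series):
        raise ValueError("window exceeds series length")
    if align not in ("center", "trailing"):
        raise ValueError("align must be 'center' or 'trailing'")
    kernel = np.full(window, 1.0 / window)
    value = np.convolve(series.value, kernel, mode="valid")
    if align == "center":
        t = np.convolve(series.t, kernel, mode="valid")
    else:
        t = series.t[window - 1:]
    return RateSeries(t=t, value=value, method="stepwise_ma", window=window,
                      p=series.p)


def spline_mu(obs: ObservedDataset, p: float,
              eval_times: np.ndarray | None = None) -> RateSeries:
    """Growth rate from the smoothing-spline fit of total biomass.

    mu(t) = f'(t) / f(t) with f the penalized spline of x*V at parameter p,
    evaluated at the sample times (or ``eval_times`` if given).
    """
    fit = fit_smoothing_spline(obs.t_sample, obs.total_biomass, p,
                               fitted_variable="total_biomass")
    t_eval = obs.t_sample if eval_times is None else np.asarray(eval_times, float)
    f = fit(t_eval)
    if np.any(f <= 0):
        t_bad = t_eval[np.flatnonzero(f <= 0)[0]]
        raise ValueError(
            f"spline fit of total biomass is non-positive at t = {t_bad:.3f} h; "
            "the fit is over-smoothed or the data pathological")
    mu = fit.derivative(t_eval) / f
    return RateSeries(t=t_eval, value=mu, method="spline", p=p)
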