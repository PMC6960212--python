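"""Specific substrate-uptake-rate estimation (three spline formulations).

All three options rest on the supernatant substrate balance

    d(SV)/dt = -qS * xV + uf * Sf

and differ only in which signal is smoothed and where the feed enters:

* Option 1 smooths the *total consumption* C(t) = SV - S0V0 - int(uf Sf dt);
  the feed is incorporated before the fit, so pump noise is integrated away.
* Option 2 smooths SV and subtracts the instantaneous feed uf*Sf afterwards;
  any spot error of the feed reading propagates straight into the rate.
* Option 3 smooths the concentration S and uses the dilution rate D = uf/V:
  qS = |dS/dt - D(Sf - S)| / x.  (Dividing the volume-reduced balance by
  biomass *concentration* is the dimensionally consistent form.)

qS is reported as a positive uptake magnitude in g/g/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import RateSeries
from .simulate import ObservedDataset, TrueTrajectory
from .smoothing import fit_smoothing_spline

__all__ = ["FeedRecord", "qs_option1", "qs_option2", "qs_option3"]


@dataclass
class FeedRecord:
    """Feed information aligned to the sampling grid of an observed dataset.

    ``cumulative_fed`` is the fed substrate (g) up to each sample time and
    ``D`` the dilution rate uf/V (1/h).  The two constructors model the two
    ways feed data arise: ``from_trajectory`` reads the pump totalizer (the
    delivered amount is metered accurately; short-term rate fluctuations
    average out in the integral), while ``from_observed`` has only the noisy
    spot rates and must integrate them by trapezoid.
    """

    t: np.ndarray
    uf: np.ndarray
    Sf: float
    cumulative_fed: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.uf = np.asarray(self.uf, dtype=float)
        self.cumulative_fed = np.asarray(self.cumulative_fed, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if np.any(np.diff(self.cumulative_fed) < -1e-9):
            raise ValueError("cumulative fed substrate must be non-decreasing")
        if np.any(self.D < 0):
            raise ValueError("dilution rate must be non-negative")

    @classmethod
    def from_trajectory(cls, traj: TrueTrajectory,
                        obs: ObservedDataset) -> "FeedRecord":
        """Totalizer feed record: exact cumulative feed, noisy spot rates."""
        idx = np.clip(np.searchsorted(traj.t, obs.t_sample - 1e-12),
                      0, traj.t.size - 1)
        return cls(t=obs.t_sample, uf=obs.uf_obs, Sf=obs.Sf,
                   cumulative_fed=traj.fed_substrate_integral[idx],
                   D=obs.uf_obs / obs.V_obs)

    @classmethod
    def from_observed(cls, obs: ObservedDataset) -> "FeedRecord":
        """Feed record from sampled rates only (trapezoidal integration)."""
        dt = np.diff(obs.t_sample)
        inc = dt * (obs.uf_obs[1:] + obs.uf_obs[:-1]) / 2.0
        cum = np.concatenate(([0.0], np.cumsum(inc))) * obs.Sf
        return cls(t=obs.t_sample, uf=obs.uf_obs, Sf=obs.Sf,
                   cumulative_fed=cum, D=obs.uf_obs / obs.V_obs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.t, "uf_Lh": self.uf,
                             "Sf_gL": self.Sf,
                             "cumulative_fed_g": self.cumulative_fed,
                             "D_per_h": self.D})


def _check_alignment(obs: ObservedDataset, feed: FeedRecord) -> None:
    if feed.t.shape != obs.t_sample.shape or not np.allclose(feed.t, obs.t_sample):
        raise ValueError("feed record is not aligned to the observation times")


def _biomass_fit(obs: ObservedDataset, p: float):
    fit = fit_smoothing_spline(obs.t_sample, obs.total_biomass, p,
                               fitted_variable="total_biomass")
    h = fit(obs.t_sample)
    if np.any(h <= 0):
        raise ValueError("biomass spline is non-positive on the sampling grid")
    return h


def qs_option1(obs: ObservedDataset, feed: FeedRecord, p: float) -> RateSeries:
    """Uptake rate from the smoothed total-consumption signal."""
    _check_alignment(obs, feed)
    consumption = (obs.total_substrate - obs.total_substrate[0]
                   - feed.cumulative_fed)
    g = fit_smoothing_spline(obs.t_sample, consumption, p,
                             fitted_variable="total_consumption")
    qs = np.abs(g.derivative(obs.t_sample)) / _biomass_fit(obs, p)
    return RateSeries(t=obs.t_sample, value=qs, method="qs_opt1", p=p)


def qs_option2(obs: ObservedDataset, feed: FeedRecord, p: float) -> RateSeries:
    """Uptake rate from smoothed total substrate minus instantaneous feed."""
    _check_alignment(obs, feed)
    g = fit_smoothing_spline(obs.t_sample, obs.total_substrate, p,
                             fitted_variable="total_substrate")
    qs = (np.abs(g.derivative(obs.t_sample) - feed.uf * feed.Sf)
          / _biomass_fit(obs, p))
    return RateSeries(t=obs.t_sample, value=qs, method="qs_opt2", p=p)


def qs_option3(obs: ObservedDataset, feed: FeedRecord, p: float) -> RateSeries:
    """Uptake rate from smoothed substrate concentration and dilution rate."""
    _check_alignment(obs, feed)
    g = fit_smoothing_spline(obs.t_sample, obs.S_obs, p,
                             fitted_variable="substrate_concentration")
    x_fit = _biomass_fit(obs, p) / obs.V_obs  # biomass concentration
    qs = np.abs(g.derivative(obs.t_sample)
                - feed.D * (feed.Sf - obs.S_obs)) / x_fit
    return RateSeries(t=obs.t_sample, value=qs, method="qs_opt3", p=p)
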