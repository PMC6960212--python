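"""Model/Results interface over the rate estimators.

``GrowthRateModel`` and ``SubstrateUptakeModel`` follow the familiar
two-object pattern: a model is constructed from data, ``fit()`` returns a
results object carrying the estimated rate series, diagnostics and a
``summary()`` table.  The underlying computations live in
:mod:`rateguard.rates` and :mod:`rateguard.substrate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .rates import RateSeries, moving_average, spline_mu, stepwise_mu
from .simulate import ObservedDataset, TrueTrajectory
from .smoothing import SplineFit, fit_smoothing_spline
from .substrate import FeedRecord, qs_option1, qs_option2, qs_option3
from .evaluation import mape, rmse

__all__ = ["GrowthRateModel", "SubstrateUptakeModel", "RateResults"]


@dataclass
class RateResults:
    """Estimated rates plus the fit context that produced them."""

    rates: RateSeries
    model: object
    spline_fit: Optional[SplineFit] = None

    @property
    def t(self) -> np.ndarray:
        return self.rates.t

    @property
    def values(self) -> np.ndarray:
        return self.rates.value

    def predict(self, t) -> np.ndarray:
        """Evaluate the rate at arbitrary times.

        Spline-based fits are re-evaluated analytically; discrete estimators
        are linearly interpolated between their timestamps.
        """
        t = np.asarray(t, dtype=float)
        if self.spline_fit is not None and self.rates.method == "spline":
            f = self.spline_fit(t)
            return self.spline_fit.derivative(t) / f
        return np.interp(t, self.rates.t, self.rates.value)

    def score(self, truth: TrueTrajectory) -> dict:
        """RMSE and MAPE against a known true trajectory."""
        return {"rmse": rmse(self.rates, truth),
                "mape_pct": mape(self.rates, truth, interior=True)}

    def to_frame(self) -> pd.DataFrame:
        return self.rates.to_frame()

    def summary(self) -> str:
        r = self.rates
        lines = [
            f"{type(self.model).__name__} results",
            "-" * 40,
            f"method:           {r.method}"
            + (f" (window={r.window})" if r.window else "")
            + (f" (p={r.p})" if r.p is not None else ""),
            f"rate points:      {len(r)}",
            f"time span:        {r.t[0]:.2f} .. {r.t[-1]:.2f} h",
            f"mean rate:        {r.value.mean():.4f}",
            f"min / max rate:   {r.value.min():.4f} / {r.value.max():.4f}",
        ]
        if self.spline_fit is not None:
            resid = self.spline_fit.residuals(self.model._fit_signal)
            lines.append(f"fit residual sd:  {resid.std(ddof=1):.4g}")
        return "\n".join(lines)

    def plot(self, ax=None, truth: TrueTrajectory | None = None):
        """Plot the estimated rate series (and the true rate if provided)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = self.rates.method
        ax.plot(self.rates.t, self.rates.value, "o-", ms=3, label=label)
        if truth is not None:
            key = "qS_true" if self.rates.method.startswith("qs") else "mu_true"
            ax.plot(truth.t, getattr(truth, key), "k--", lw=1, label="true")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("rate (1/h)" if not self.rates.method.startswith("qs")
                      else "qS (g/g/h)")
        ax.legend()
        return ax


class GrowthRateModel:
    """Specific growth rate estimated from an observed fed-batch dataset.

    Parameters
    ----------
    data : ObservedDataset or DataFrame
        Sampled measurements (DataFrames use the tidy CSV schema with
        columns time_h, x_gL, S_gL, V_L, uf_Lh, Sf_gL).
    method : {"stepwise", "stepwise_ma", "spline"}
    window : int, moving-average window (stepwise_ma only)
    p : float in [0, 1], smoothing parameter (spline only), default 0.4
    """

    def __init__(self, data, method: str = "spline", window: int | None = None,
                 p: float = 0.4):
        if isinstance(data, pd.DataFrame):
            data = ObservedDataset.from_frame(data)
        self.data = data
        self.method = method
        self.window = window
        self.p = p
        self._fit_signal = data.total_biomass

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GrowthRateModel":
        return cls(ObservedDataset.from_csv(path), **kwargs)

    def fit(self) -> RateResults:
        if self.method == "stepwise":
            return RateResults(stepwise_mu(self.data), self)
        if self.method == "stepwise_ma":
            if self.window is None:
                raise ValueError("stepwise_ma requires a window")
            rates = moving_average(stepwise_mu(self.data), self.window)
            return RateResults(rates, self)
        if self.method == "spline":
            fit = fit_smoothing_spline(self.data.t_sample, self._fit_signal,
                                       self.p, fitted_variable="total_biomass")
            rates = spline_mu(self.data, self.p)
            return RateResults(rates, self, spline_fit=fit)
        raise ValueError(f"unknown method {self.method!r}")


class SubstrateUptakeModel:
    """Specific substrate uptake rate from observations and a feed record.

    ``option`` selects how the feed enters: 1 incorporates the cumulative
    fed substrate before smoothing (recommended), 2 subtracts the
    instantaneous feed after smoothing total substrate, 3 works on the
    substrate concentration via the dilution rate.
    """

    _OPTIONS = {1: qs_option1, 2: qs_option2, 3: qs_option3}

    def __init__(self, data, feed: FeedRecord | None = None, option: int = 1,
                 p: float = 0.4):
        if isinstance(data, pd.DataFrame):
            data = ObservedDataset.from_frame(data)
        if option not in self._OPTIONS:
            raise ValueError("option must be 1, 2 or 3")
        self.data = data
        self.feed = FeedRecord.from_observed(data) if feed is None else feed
        self.option = option
        self.p = p
        self._fit_signal = data.total_substrate

    def fit(self) -> RateResults:
        rates = self._OPTIONS[self.option](self.data, self.feed, self.p)
        return RateResults(rates, self)
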