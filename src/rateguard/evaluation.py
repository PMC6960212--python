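"""Precision/accuracy scoring of rate estimators over simulated ensembles.

Precision is measured by the coefficient of variation of the estimated rate
across replicate processes at each timepoint; accuracy by RMSE and MAPE
against the noise-free true rate.  Grid summaries average over the interior
timepoints (the first and last estimates of every series are boundary
artifacts of all methods and are excluded); the reported maximum covers the
whole series.  The smoothing-parameter screen, by contrast, scores the
whole series including its endpoints: how a candidate p behaves at the edges
of the process is part of choosing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import BIOMASS_CVS, INTERVALS, KineticConfig, NoiseSpec
from .rates import RateSeries, moving_average, spline_mu, stepwise_mu
from .simulate import ObservedDataset, TrueTrajectory, make_ensemble, simulate

__all__ = [
    "cv", "rmse", "mape", "timepoint_cv", "interior_mean", "interior_max",
    "EvalGrid", "cv_grid", "screen_p", "change_detection_delay",
]

#: Default p screening grid, resolution 0.1.
P_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def cv(values) -> float:
    """Coefficient of variation in percent: sample sd over mean times 100."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / np.abs(mean) * 100.0)


def _truth_values(estimated: RateSeries, truth: TrueTrajectory) -> np.ndarray:
    if estimated.method.startswith("qs"):
        return truth.qs_at(estimated.t)
    return truth.mu_at(estimated.t)


def rmse(estimated: RateSeries, truth: TrueTrajectory) -> float:
    """Root mean squared error against the true rate at the estimate times."""
    if len(estimated) == 0:
        raise ValueError("empty rate series")
    err = estimated.value - _truth_values(estimated, truth)
    return float(np.sqrt(np.mean(err ** 2)))


def mape(estimated: RateSeries, truth: TrueTrajectory,
         interior: bool = False) -> float:
    """Mean absolute percentage error against the true rate, in percent."""
    if len(estimated) == 0:
        raise ValueError("empty rate series")
    y = _truth_values(estimated, truth)
    if np.any(y == 0):
        raise ValueError("true rate is zero at an evaluation time")
    pct = np.abs(y - estimated.value) / np.abs(y) * 100.0
    if interior and pct.size >= 3:
        pct = pct[1:-1]
    return float(np.mean(pct))


def timepoint_cv(ensemble: Sequence[RateSeries]) -> RateSeries:
    """Per-timepoint CV (%) of an ensemble of rate series on a shared grid."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 replicates")
    t0 = ensemble[0].t
    for series in ensemble[1:]:
        if series.t.shape != t0.shape or not np.allclose(series.t, t0):
            raise ValueError("rate series do not share timestamps")
    values = np.vstack([s.value for s in ensemble])
    means = values.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("zero ensemble mean at a timepoint")
    cvs = values.std(axis=0, ddof=1) / np.abs(means) * 100.0
    proto = ensemble[0]
    return RateSeries(t=t0, value=cvs, method=proto.method,
                      window=proto.window, p=proto.p)


def interior_mean(series: RateSeries) -> float:
    """Mean over interior timepoints (first and last excluded).

    Series with fewer than 3 points have no interior; the full mean is
    returned then.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    values = series.value[1:-1] if len(series) >= 3 else series.value
    return float(values.mean())


def interior_max(series: RateSeries) -> float:
    """Maximum over interior timepoints (first/last excluded; see interior_mean)."""
    if len(series) == 0:
        raise ValueError("empty series")
    values = series.value[1:-1] if len(series) >= 3 else series.value
    return float(values.max())


@dataclass
class EvalGrid:
    """Tidy table of summary scores over (interval x noise x method x p/window)."""

    table: pd.DataFrame

    def cell(self, **conditions) -> pd.DataFrame:
        mask = np.ones(len(self.table), dtype=bool)
        for key, val in conditions.items():
            mask &= np.isclose(self.table[key], val) if np.issubdtype(
                self.table[key].dtype, np.number) else (self.table[key] == val)
        return self.table[mask]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _estimator(method: str, window: int | None, p: float | None
               ) -> Callable[[ObservedDataset], RateSeries]:
    if method == "stepwise":
        return stepwise_mu
    if method == "stepwise_ma":
        if window is None:
            raise ValueError("moving average needs a window")
        return lambda obs: moving_average(stepwise_mu(obs), window)
    if method == "spline":
        if p is None:
            raise ValueError("spline needs a p")
        return lambda obs: spline_mu(obs, p)
    raise ValueError(f"unknown growth-rate method {method!r}")


def cv_grid(cfg: KineticConfig, methods: Sequence[dict], n: int = 100,
            base_seed: int = 0, intervals: Sequence[float] = INTERVALS,
            noise_levels: Sequence[float] = BIOMASS_CVS,
            traj: TrueTrajectory | None = None) -> EvalGrid:
    """Score estimators over the sampling-interval x biomass-noise grid.

    ``methods`` is a list of dicts like ``{"method": "spline", "p": 0.4}``.
    Each grid cell reports the interior mean and max of the per-timepoint CV
    and the ensemble-mean RMSE/MAPE against the true rate, over ``n``
    replicates with seeds ``base_seed + replicate``.
    """
    if traj is None:
        traj = simulate(cfg)
    rows = []
    for interval in intervals:
        for cv_b in noise_levels:
            noise = NoiseSpec(cv_biomass=cv_b, seed=base_seed)
            ensemble = make_ensemble(cfg, interval, noise, n, traj=traj)
            for spec in methods:
                est = _estimator(spec["method"], spec.get("window"),
                                 spec.get("p"))
                series = [est(obs) for obs in ensemble]
                cvs = timepoint_cv(series)
                rows.append({
                    "model": cfg.model, "interval_h": interval,
                    "cv_biomass_pct": cv_b, "method": spec["method"],
                    "window": spec.get("window"), "p": spec.get("p"),
                    "mean_cv_pct": interior_mean(cvs),
                    "max_cv_pct": float(cvs.value.max()),
                    "rmse": float(np.mean([rmse(s, traj) for s in series])),
                    "mape_pct": float(np.mean(
                        [mape(s, traj, interior=True) for s in series])),
                })
    return EvalGrid(pd.DataFrame(rows))


def screen_p(cfg: KineticConfig, intervals: Sequence[float] = INTERVALS,
             noise_levels: Sequence[float] = BIOMASS_CVS,
             p_grid: Sequence[float] = P_GRID, n: int = 100,
             base_seed: int = 0,
             traj: TrueTrajectory | None = None) -> EvalGrid:
    """RMSE of the spline growth-rate estimate as a function of p.

    For every (interval, noise) condition the mean RMSE over ``n`` replicates
    is computed for each p; the returned grid carries a per-condition
    ``argmin_p`` column, and ``EvalGrid.table.attrs["global_argmin_p"]``
    holds the argmin of the condition-averaged RMSE.
    """
    p_grid = [float(p) for p in p_grid]
    if any(p < 0 or p > 1 for p in p_grid):
        raise ValueError("p grid must lie within [0, 1]")
    if traj is None:
        traj = simulate(cfg)
    rows = []
    for interval in intervals:
        for cv_b in noise_levels:
            noise = NoiseSpec(cv_biomass=cv_b, seed=base_seed)
            ensemble = make_ensemble(cfg, interval, noise, n, traj=traj)
            scores = {}
            for p in p_grid:
                try:
                    series = [spline_mu(obs, p) for obs in ensemble]
                except ValueError:
                    # e.g. p = 0: the straight-line fit of growing biomass is
                    # non-positive early on, so no log-derivative exists
                    scores[p] = float("nan")
                    continue
                scores[p] = float(np.mean([rmse(s, traj) for s in series]))
            finite = {p: s for p, s in scores.items() if np.isfinite(s)}
            best = min(finite, key=finite.get)
            for p, score in scores.items():
                rows.append({"model": cfg.model, "interval_h": interval,
                             "cv_biomass_pct": cv_b, "p": p,
                             "rmse": score, "argmin_p": best})
    table = pd.DataFrame(rows)
    mean_by_p = table.groupby("p")["rmse"].mean()
    table.attrs["global_argmin_p"] = float(mean_by_p.idxmin())
    return EvalGrid(table)


def change_detection_delay(series: RateSeries, truth: TrueTrajectory,
                           drop_fraction: float = 0.15) -> float:
    """Timely deviation (%) in detecting a growth-rate drop.

    The reference time is when the true rate first falls below
    ``(1 - drop_fraction)`` of its pre-induction plateau; the detected time
    is the first crossing of the same threshold by the estimated series
    (linear interpolation between rate timestamps).  Returns
    (t_detected - t_reference) / t_reference * 100, or NaN when the series
    never crosses the threshold ("not detected").
    """
    cfg = truth.config
    pre = truth.mu_true[truth.t < cfg.t_induction]
    if pre.size == 0:
        raise ValueError("trajectory has no pre-induction phase")
    threshold = (1.0 - drop_fraction) * float(pre.mean())
    below = truth.mu_true <= threshold
    if not below.any():
        raise ValueError("true rate never drops by the requested fraction")
    i = int(np.argmax(below))
    # refine by interpolation between grid points
    t_true = float(np.interp(threshold,
                             truth.mu_true[[i, i - 1]], truth.t[[i, i - 1]])
                   ) if i > 0 else float(truth.t[0])

    v, t = series.value, series.t
    crossings = np.flatnonzero((v[:-1] > threshold) & (v[1:] <= threshold))
    if crossings.size == 0:
        return float("nan")
    j = int(crossings[0])
    t_est = float(np.interp(threshold, v[[j + 1, j]], t[[j + 1, j]]))
    return (t_est - t_true) / t_true * 100.0
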