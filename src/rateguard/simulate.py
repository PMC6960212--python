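"""Fed-batch process simulation and measurement-noise corruption.

Solves the total-mass balances of a fed-batch reactor

    d(xV)/dt = mu * xV
    d(SV)/dt = -(mu / Y_xs) * xV + uf * Sf
    dV/dt    = uf

with ``mu`` given by Monod kinetics, optionally attenuated by a
non-competitive inhibition factor K_i / (K_i + I) once an accumulating
inhibitor I appears after induction (d(IV)/dt = q_i * xV for t >= t_induction).
The noise-free solution is the ground truth against which all rate
estimators in this package are scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import KineticConfig, NoiseSpec

__all__ = [
    "TrueTrajectory",
    "ObservedDataset",
    "growth_rate_law",
    "simulate",
    "sample_and_corrupt",
    "make_ensemble",
]

#: Relative clamp floor applied to noisy observations (fraction of the
#: initial true value) so that measurements stay physically positive.
_CLAMP_FRACTION = 1e-6


def growth_rate_law(S, t, cfg: KineticConfig, inhibitor=0.0):
    """Specific growth rate (1/h) at substrate level ``S`` and time ``t``.

    Monod: mu = mu_max * S / (K_s + S).  For the non-competitive model the
    Monod term is multiplied by K_i / (K_i + I) where ``inhibitor`` is the
    inhibitor concentration; the factor is active from ``cfg.t_induction``
    (before induction no inhibitor exists and the factor is 1).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("negative substrate concentration is not a valid state")
    mu = cfg.mu_max * S / (cfg.K_s + S)
    if cfg.model == "noncompetitive":
        active = np.asarray(t, dtype=float) >= cfg.t_induction
        factor = cfg.K_i / (cfg.K_i + np.asarray(inhibitor, dtype=float))
        mu = mu * np.where(active, factor, 1.0)
    if mu.ndim == 0:
        return float(mu)
    return mu


@dataclass
class TrueTrajectory:
    """Dense noise-free solution of the fed-batch balances.

    Arrays share the grid ``t``; ``mu_true`` is the specific growth rate and
    ``qS_true`` the specific substrate uptake rate mu / Y_xs reported as a
    positive magnitude (g substrate / g biomass / h).
    """

    t: np.ndarray
    x: np.ndarray          # biomass concentration, g/L
    S: np.ndarray          # substrate concentration, g/L
    V: np.ndarray          # volume, L
    uf: np.ndarray         # nominal feed rate, L/h
    inhibitor: np.ndarray  # inhibitor concentration, g/L
    mu_true: np.ndarray
    qS_true: np.ndarray
    config: KineticConfig

    @property
    def total_biomass(self) -> np.ndarray:
        """x * V in grams."""
        return self.x * self.V

    @property
    def total_substrate(self) -> np.ndarray:
        """S * V in grams."""
        return self.S * self.V

    @property
    def fed_substrate_integral(self) -> np.ndarray:
        """Cumulative fed substrate (g): integral of uf * Sf on the grid."""
        increments = np.diff(self.t) * (self.uf[1:] + self.uf[:-1]) / 2.0
        return np.concatenate(([0.0], np.cumsum(increments))) * self.config.Sf

    def mu_at(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.mu_true)

    def qs_at(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.qS_true)

    def mass_balance_residual(self) -> float:
        """Max |S*V - S0*V0 - fed + consumed| relative to total substrate fed."""
        consumed_increments = (
            np.diff(self.t)
            * (self.qS_true[1:] * self.total_biomass[1:]
               + self.qS_true[:-1] * self.total_biomass[:-1]) / 2.0
        )
        consumed = np.concatenate(([0.0], np.cumsum(consumed_increments)))
        lhs = self.total_substrate - self.total_substrate[0]
        rhs = self.fed_substrate_integral - consumed
        scale = max(self.fed_substrate_integral[-1], 1.0)
        return float(np.max(np.abs(lhs - rhs)) / scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.t, "x_gL": self.x, "S_gL": self.S, "V_L": self.V,
            "uf_Lh": self.uf, "mu_per_h": self.mu_true, "qS_ggh": self.qS_true,
        })


@dataclass
class ObservedDataset:
    """Noise-corrupted measurements of one simulated cultivation replicate."""

    t_sample: np.ndarray
    x_obs: np.ndarray
    S_obs: np.ndarray
    V_obs: np.ndarray
    uf_obs: np.ndarray
    Sf: float
    interval: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.t_sample = np.asarray(self.t_sample, dtype=float)
        if self.t_sample.size < 3:
            raise ValueError("an observed dataset needs at least 3 samples")
        for name in ("x_obs", "S_obs", "V_obs", "uf_obs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t_sample.shape:
                raise ValueError(f"{name} does not match t_sample in length")
            setattr(self, name, arr)

    @property
    def total_biomass(self) -> np.ndarray:
        return self.x_obs * self.V_obs

    @property
    def total_substrate(self) -> np.ndarray:
        return self.S_obs * self.V_obs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.t_sample, "x_gL": self.x_obs, "S_gL": self.S_obs,
            "V_L": self.V_obs, "uf_Lh": self.uf_obs, "Sf_gL": self.Sf,
            "replicate": self.replicate_id,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservedDataset":
        t = frame["time_h"].to_numpy(dtype=float)
        interval = float(np.median(np.diff(t))) if t.size > 1 else 0.0
        replicate = int(frame["replicate"].iloc[0]) if "replicate" in frame else 0
        return cls(
            t_sample=t,
            x_obs=frame["x_gL"].to_numpy(dtype=float),
            S_obs=frame["S_gL"].to_numpy(dtype=float),
            V_obs=frame["V_L"].to_numpy(dtype=float),
            uf_obs=frame["uf_Lh"].to_numpy(dtype=float),
            Sf=float(frame["Sf_gL"].iloc[0]),
            interval=interval,
            replicate_id=replicate,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedDataset":
        return cls.from_frame(pd.read_csv(path))


def simulate(cfg: KineticConfig, grid_step: float = 0.01) -> TrueTrajectory:
    """Integrate the fed-batch balances on a dense grid.

    The state vector is total biomass xV, total substrate SV, volume V and
    total inhibitor IV; concentrations are recovered afterwards.  For the
    non-competitive model the integration is split at ``t_induction`` so the
    switch-on of inhibitor production is not smoothed over by the solver.
    """
    if grid_step <= 0 or grid_step > cfg.t_end:
        raise ValueError("grid_step must lie in (0, t_end]")

    def rhs(t, state):
        X, Z, V, W = state
        S = Z / V
        if S < -1e-9 * cfg.S0 * cfg.V0 - 1e-12:
            raise FloatingPointError(
                f"substrate driven below zero at t = {t:.4f} h")
        S = max(S, 0.0)
        mu = growth_rate_law(S, t, cfg, inhibitor=W / V)
        uf = float(cfg.feed_rate(t))
        dX = mu * X
        dZ = -(mu / cfg.Y_xs) * X + uf * cfg.Sf
        dW = cfg.q_i * X if (cfg.model == "noncompetitive"
                             and t >= cfg.t_induction) else 0.0
        return [dX, dZ, uf, dW]

    t_grid = np.arange(0.0, cfg.t_end + grid_step / 2.0, grid_step)
    t_grid[-1] = min(t_grid[-1], cfg.t_end)
    breaks = [0.0, cfg.t_end]
    if cfg.model == "noncompetitive" and 0.0 < cfg.t_induction < cfg.t_end:
        breaks = [0.0, cfg.t_induction, cfg.t_end]

    state = [cfg.x0 * cfg.V0, cfg.S0 * cfg.V0, cfg.V0, 0.0]
    pieces_t, pieces_y = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_eval = t_grid[(t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)]
        sol = solve_ivp(rhs, (a, b), state, t_eval=t_eval, method="LSODA",
                        rtol=1e-8, atol=1e-10, max_step=grid_step * 10)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed near t = {sol.t[-1] if sol.t.size else a:.3f} h: "
                               f"{sol.message}")
        # drop the duplicated break point of the next segment
        keep = slice(None) if not pieces_t else slice(1, None)
        pieces_t.append(sol.t[keep])
        pieces_y.append(sol.y[:, keep])
        state = sol.y[:, -1]

    t = np.concatenate(pieces_t)
    X, Z, V, W = np.concatenate(pieces_y, axis=1)
    S = np.maximum(Z / V, 0.0)
    inhibitor = W / V
    mu = growth_rate_law(S, t, cfg, inhibitor=inhibitor)
    return TrueTrajectory(
        t=t, x=X / V, S=S, V=V, uf=np.asarray(cfg.feed_rate(t)),
        inhibitor=inhibitor, mu_true=np.asarray(mu),
        qS_true=np.asarray(mu) / cfg.Y_xs, config=cfg,
    )


def sample_and_corrupt(traj: TrueTrajectory, interval: float,
                       noise: NoiseSpec, replicate_id: int = 0) -> ObservedDataset:
    """Sample a trajectory at a uniform interval and add measurement noise.

    Biomass, substrate and volume errors are multiplicative Gaussian with the
    per-variable CVs of ``noise`` (independent across variables and sampling
    times); the feed-rate reading gets one additive draw per sampling interval
    with sigma = cv_feed/100 of the process's maximum nominal rate.  All
    observations are clamped at a small positive floor.  Deterministic under
    ``noise.seed``.
    """
    t_end = float(traj.t[-1])
    grid_step = float(np.median(np.diff(traj.t)))
    if interval < grid_step:
        raise ValueError("sampling interval must not be finer than the simulation grid")
    if interval > t_end / 2.0:
        raise ValueError(
            f"interval {interval} h yields fewer than 3 samples on [0, {t_end}] h")

    t_sample = np.arange(0.0, t_end + 1e-9, interval)
    idx = np.searchsorted(traj.t, t_sample - 1e-12)
    idx = np.clip(idx, 0, traj.t.size - 1)
    x, S, V, uf = traj.x[idx], traj.S[idx], traj.V[idx], traj.uf[idx]
    n = t_sample.size

    rng = np.random.default_rng(int(noise.seed))
    x_obs = x * (1.0 + rng.normal(0.0, noise.cv_biomass / 100.0, n))
    S_obs = S * (1.0 + rng.normal(0.0, noise.cv_substrate / 100.0, n))
    V_obs = V * (1.0 + rng.normal(0.0, noise.cv_volume / 100.0, n))
    uf_scale = float(np.max(traj.uf))
    uf_obs = uf + uf_scale * rng.normal(0.0, noise.cv_feed / 100.0, n)

    x_obs = np.maximum(x_obs, _CLAMP_FRACTION * traj.x[0])
    S_obs = np.maximum(S_obs, _CLAMP_FRACTION * max(traj.S[0], grid_step))
    V_obs = np.maximum(V_obs, _CLAMP_FRACTION * traj.V[0])
    uf_obs = np.maximum(uf_obs, 0.0)

    return ObservedDataset(
        t_sample=t_sample, x_obs=x_obs, S_obs=S_obs, V_obs=V_obs,
        uf_obs=uf_obs, Sf=traj.config.Sf, interval=float(interval),
        replicate_id=replicate_id,
    )


def make_ensemble(cfg: KineticConfig, interval: float, noise: NoiseSpec,
                  n: int, traj: TrueTrajectory | None = None,
                  grid_step: float = 0.01) -> list[ObservedDataset]:
    """Generate ``n`` noisy replicates of one simulated cultivation.

    Every replicate shares the same noise-free trajectory and sampling grid;
    replicate ``i`` draws its noise with seed ``noise.seed + i``.  Pass a
    pre-computed ``traj`` to avoid re-solving the ODEs in parameter sweeps.
    """
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    if traj is None:
        traj = simulate(cfg, grid_step=grid_step)
    out = []
    for i in range(int(n)):
        spec = NoiseSpec(cv_biomass=noise.cv_biomass,
                         cv_substrate=noise.cv_substrate,
                         cv_volume=noise.cv_volume,
                         cv_feed=noise.cv_feed,
                         seed=int(noise.seed) + i)
        out.append(sample_and_corrupt(traj, interval, spec, replicate_id=i))
    return out
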