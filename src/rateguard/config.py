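"""Kinetic and noise configuration for in-silico fed-batch cultivations.

The two packaged configurations describe the study conditions used throughout
the package: a Monod-limited fed-batch held at a near-constant specific growth
rate by an exponential feed, and an induced process in which an accumulating
inhibitor (a non-competitive term) pulls the growth rate down after induction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "KineticConfig",
    "NoiseSpec",
    "monod_default",
    "noncompetitive_default",
    "load_config",
    "save_config",
]

#: Sampling intervals (h) used by the evaluation studies.
INTERVALS = (0.5, 1.0, 2.0, 3.0, 4.0)

#: Biomass measurement precisions (% CV) used by the evaluation studies.
BIOMASS_CVS = (2.5, 5.0, 7.5, 10.0, 12.5)

#: Base random seed of the shipped experiment recipes.
BASE_SEED = 20190920


@dataclass
class KineticConfig:
    """Parameters of a simulated fed-batch cultivation.

    The feed is exponential, ``uf(t) = uf0 * exp(feed_rate * t)``, sized so
    that substrate delivery matches consumption of a culture growing at
    ``mu_set``; the substrate level then settles at the quasi-steady
    concentration where the Monod term equals ``mu_set``.

    Units: rates 1/h, concentrations g/L, volumes L, times h, yields g/g.
    """

    model: str = "monod"  # "monod" | "noncompetitive"
    mu_max: float = 0.5
    K_s: float = 0.05
    Y_xs: float = 0.5
    x0: float = 2.0
    V0: float = 1.0
    Sf: float = 400.0
    t_end: float = 18.0
    mu_set: float = 0.20
    feed_scale: float = 1.0  # 0 turns the feed off (batch mode)
    S0: Optional[float] = None  # default: quasi-steady concentration S*
    # non-competitive inhibition (ignored for model == "monod")
    K_i: float = 1.0
    q_i: float = 0.006  # inhibitor formed per g biomass per h after induction
    t_induction: float = 6.0

    def __post_init__(self) -> None:
        if self.model not in ("monod", "noncompetitive"):
            raise ValueError(f"unknown kinetic model {self.model!r}")
        for name in ("mu_max", "K_s", "Y_xs", "x0", "V0", "Sf", "t_end", "K_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.mu_set < self.mu_max:
            raise ValueError("mu_set must lie in (0, mu_max)")
        if self.feed_scale < 0:
            raise ValueError("feed_scale must be non-negative")
        if self.S0 is None:
            self.S0 = self.quasi_steady_S
        if self.S0 <= 0:
            raise ValueError("S0 must be strictly positive")
        if self.model == "noncompetitive":
            if self.q_i < 0:
                raise ValueError("q_i must be non-negative")
            if not 0 <= self.t_induction < self.t_end:
                raise ValueError("t_induction must lie in [0, t_end)")

    @property
    def quasi_steady_S(self) -> float:
        """Substrate level S* at which the Monod term equals ``mu_set``."""
        return self.K_s * self.mu_set / (self.mu_max - self.mu_set)

    @property
    def uf0(self) -> float:
        """Initial feed rate (L/h) matching consumption at ``mu_set``."""
        return (self.mu_set / self.Y_xs) * self.x0 * self.V0 / self.Sf

    def feed_rate(self, t) -> "float":
        """Nominal feed profile uf(t) in L/h (exponential, vectorised)."""
        import numpy as np

        return (self.feed_scale * self.uf0
                * np.exp(self.mu_set * np.asarray(t, dtype=float)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class NoiseSpec:
    """Measurement-noise description for a sampled fed-batch dataset.

    Biomass, substrate and volume receive independent Gaussian errors with a
    standard deviation proportional to the instantaneous true value
    (sigma = CV/100 * value).  The feed rate receives an absolute error of
    ``cv_feed`` percent of the maximum nominal rate of the process, one draw
    per sampling interval: pump precision is specified on full scale, while
    the cumulative delivered amount is metered accurately.
    """

    cv_biomass: float = 2.5
    cv_substrate: float = 1.0
    cv_volume: float = 1.0
    cv_feed: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_biomass", "cv_substrate", "cv_volume", "cv_feed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= int(self.seed) < 2**63:
            raise ValueError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def monod_default() -> KineticConfig:
    """Monod-limited fed-batch with a near-constant growth rate (18 h).

    The exponential feed pins mu at 0.20 1/h; biomass climbs from 2 to
    roughly 54 g/L while residual substrate stays at ~0.03 g/L.
    """
    return KineticConfig(model="monod", mu_set=0.20, t_end=18.0)


def noncompetitive_default() -> KineticConfig:
    """Induced fed-batch whose growth rate declines after induction (24 h).

    From induction at 6 h an inhibitor accumulates in proportion to the
    biomass formed, attenuating growth non-competitively; mu falls from
    0.19 to ~0.13 1/h by harvest and substrate accumulates because the
    exponential feed keeps running at the uninhibited schedule.
    """
    return KineticConfig(model="noncompetitive", mu_set=0.19, t_end=24.0,
                         t_induction=6.0)


_BUILTIN = {"monod": monod_default, "noncompetitive": noncompetitive_default}


def load_config(source: str | Path) -> KineticConfig:
    """Load a :class:`KineticConfig` from a YAML/JSON file or builtin name."""
    if isinstance(source, str) and source in _BUILTIN:
        return _BUILTIN[source]()
    with open(source) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {source} does not contain a mapping")
    data.pop("noise", None)  # noise specs may share the file; ignored here
    return KineticConfig(**data)


def save_config(cfg: KineticConfig, path: str | Path,
                noise: NoiseSpec | None = None) -> None:
    """Write a config (and optionally a noise spec) as YAML."""
    data = cfg.to_dict()
    if noise is not None:
        data["noise"] = noise.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
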