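"""Synthetic trade worlds with the statistical structure the pipeline assumes.

Country economic masses are Pareto-distributed (heavy tail -> a few dominant
traders and a scale-free-like thresholded network); bilateral flows follow a
gravity form ``G * S_i^alpha * S_j^beta / d_ij^gamma * exp(noise)`` on random
planar coordinates; GDP is a configurable multiple of each country's trade
mass so dependence ratios land in a plausible band; CRI is identically 1 in
the pre-epidemic regime and log-normal in the epidemic regime.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, UnattainableDensityError
from .trade_data import CountryIndicatorTable, TradeFlowTable, clean_flows

__all__ = ["WorldConfig", "World", "generate_world", "calibrate_threshold",
           "country_codes"]


@dataclass
class WorldConfig:
    """Parameters of a generated world; every draw is reproducible from seed."""

    n_countries: int = 100
    year: int = 2019
    size_exponent: float = 1.5        # Pareto tail of country masses
    alpha: float = 1.0                # exporter-mass elasticity
    beta: float = 1.0                 # importer-mass elasticity
    gamma: float = 1.0                # distance decay
    noise_sd: float = 0.3             # log-scale flow noise
    total_trade_usd: float = 3.0e11   # flows rescaled to this grand total
    gdp_ratio: float = 18.0           # GDP as multiple of a country's trade mass
    gdp_jitter_sd: float = 0.2        # log-normal jitter on GDP
    cri_regime: str = "pre_epidemic"  # or "epidemic"
    cri_log_mean: float = 4.1         # epidemic CRI ~ lognormal, ~[20, 150]
    cri_log_sd: float = 0.4
    threshold: float = 1.0e8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ParameterError(f"need >= 3 countries, got {self.n_countries}")
        for name in ("size_exponent", "noise_sd", "total_trade_usd",
                     "gdp_ratio", "cri_log_sd"):
            if getattr(self, name) < 0 or (
                    name in ("size_exponent", "total_trade_usd", "gdp_ratio")
                    and getattr(self, name) == 0):
                raise ParameterError(f"{name} must be positive")
        if self.cri_regime not in ("pre_epidemic", "epidemic"):
            raise ConfigurationError(f"unknown CRI regime: {self.cri_regime!r}")


@dataclass
class World:
    """A generated world plus the latent quantities that produced it."""

    flows: TradeFlowTable
    indicators: CountryIndicatorTable
    config: WorldConfig
    masses: np.ndarray = field(repr=False, default=None)
    coords: np.ndarray = field(repr=False, default=None)
    distances: np.ndarray = field(repr=False, default=None)
    raw_flows: np.ndarray = field(repr=False, default=None)


def country_codes(n: int) -> list[str]:
    """Deterministic synthetic ISO3-style codes: XAA, XAB, ... (X prefix avoids
    collisions with real assignments for small n)."""
    letters = string.ascii_uppercase
    if n > 26 * 26:
        raise ParameterError(f"at most {26 * 26} synthetic codes, asked for {n}")
    return [f"X{letters[i // 26]}{letters[i % 26]}" for i in range(n)]


def generate_world(config: WorldConfig) -> World:
    """Draw a full world (flow table + indicator table) from the config seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    codes = country_codes(n)

    masses = (1.0 + rng.pareto(config.size_exponent, size=n))
    coords = rng.uniform(0.0, 1.0, size=(n, 2))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, 1.0)  # unused, avoids divide-by-zero
    noise = rng.normal(0.0, config.noise_sd, size=(n, n))

    raw = (masses[:, None] ** config.alpha * masses[None, :] ** config.beta
           / dist ** config.gamma * np.exp(noise))
    np.fill_diagonal(raw, 0.0)
    flows_mat = raw * (config.total_trade_usd / raw.sum())

    exp_idx, imp_idx = np.nonzero(flows_mat > 0)
    frame = pd.DataFrame({
        "year": config.year,
        "exporter": [codes[i] for i in exp_idx],
        "importer": [codes[j] for j in imp_idx],
        "value": flows_mat[exp_idx, imp_idx],
    })
    flows = clean_flows(frame)

    trade_mass = flows_mat.sum(axis=0) + flows_mat.sum(axis=1)
    gdp = (config.gdp_ratio * trade_mass
           * np.exp(rng.normal(0.0, config.gdp_jitter_sd, size=n)))
    if config.cri_regime == "pre_epidemic":
        cri = np.ones(n)
    else:
        cri = np.exp(rng.normal(config.cri_log_mean, config.cri_log_sd, size=n))
    indicators = CountryIndicatorTable(pd.DataFrame({
        "iso3": codes, "year": config.year, "gdp_usd": gdp, "cri": cri}))
    return World(flows=flows, indicators=indicators, config=config,
                 masses=masses, coords=coords, distances=dist, raw_flows=flows_mat)


def calibrate_threshold(flows: TradeFlowTable, target_density: float,
                        year: int | None = None, tol: float = 0.10) -> float:
    """Threshold whose binarized density lands within ``tol`` (relative) of target.

    Searches the sorted positive flow values (density is a step function of
    the threshold); raises :class:`UnattainableDensityError` with the
    attainable range when no threshold gets close enough.
    """
    if not (0 < target_density <= 1):
        raise ParameterError(f"target density must be in (0,1], got {target_density}")
    years = flows.years()
    year = year if year is not None else years[0]
    sub = flows.for_year(year)
    n = len(set(sub["exporter"]) | set(sub["importer"]))
    possible = n * (n - 1)
    vals = np.sort(sub.loc[sub["value"] > 0, "value"].to_numpy())[::-1]
    if possible == 0 or len(vals) == 0:
        raise UnattainableDensityError("no positive flows", attainable=(0.0, 0.0))
    # keeping the m largest flows yields density m/possible at threshold vals[m-1]
    densities = np.arange(1, len(vals) + 1) / possible
    err = np.abs(densities - target_density) / target_density
    best = int(np.argmin(err))
    if err[best] > tol:
        raise UnattainableDensityError(
            f"cannot reach density {target_density} within {tol:.0%}; "
            f"attainable range is (0, {densities[-1]:.4f}]",
            attainable=(float(densities[0]), float(densities[-1])))
    return float(vals[best])
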