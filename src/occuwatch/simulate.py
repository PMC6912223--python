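"""Synthetic camera-trap monitoring data with the structure the analyses assume.

The generator emulates a two-reserve monitoring design: ``n_sites`` camera
stations split between a fox-baited area (BB) and an unbaited one (NAD),
surveyed annually for several seasons of 30-40 day deployments. Occupancy is a
latent per-(site, season) state following a first-order Markov chain with
colonization probability ``gamma`` and extinction probability ``eps``; daily
detections at occupied sites are Bernoulli with a logit-linear probability in
baiting, ground-cover score, shrub-cover score and a categorical year effect.
Camera malfunction is injected as missing-completely-at-random single days plus
whole-deployment losses (theft).

There are no false positives: an unoccupied site never yields a detection,
matching the assumption of the downstream occupancy and detection models.

Randomness is reproducible: one seed per config, with independent sub-streams
spawned per stage (sites, occupancy, detections) so each stage is individually
repeatable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data import AREAS, SCORE_COLUMNS, DetectionDataset, SiteTable

import pandas as pd


def _per_transition(value: float | Sequence[float], n_trans: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n_trans)
    if arr.size != n_trans:
        raise ValueError(f"{name} must be scalar or length {n_trans}, got {arr.size}")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} outside [0, 1]")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generating parameters for one synthetic dataset.

    Defaults mirror the monitoring design being emulated: 168 sites split
    evenly between the baited and unbaited area, four annual seasons of 40-day
    deployments, moderate initial occupancy with slow turnover, and daily
    detection probabilities in the 0.1-0.4 range typical of cryptic
    ground-dwelling marsupials.
    """

    n_sites: int = 168
    area_split: float = 0.5  # fraction of sites in the baited area (BB)
    n_years: int = 4
    days_per_deployment: int = 40
    psi1: float | Mapping[str, float] = 0.3  # initial occupancy, scalar or per area
    gamma: float | Sequence[float] = 0.1  # colonization per transition
    eps: float | Sequence[float] = 0.15  # extinction per transition
    # logit-scale detection coefficients
    beta_intercept: float = -2.2
    beta_bait: float = 0.4
    beta_ground: float = 0.35
    beta_shrub: float = 0.25
    beta_year: tuple[float, ...] = (0.1, 0.2, 0.3)  # offsets for years 2..n, year 1 baseline
    habitat_score_probs: tuple[float, float, float, float] = (0.15, 0.35, 0.35, 0.15)
    missing_day_rate: float = 0.02
    whole_deployment_loss_rate: float = 0.03
    species: str = "Potorous"
    first_year: int = 2015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_years < 1 or self.days_per_deployment < 1:
            raise ValueError("n_sites, n_years and days_per_deployment must be >= 1")
        probs = [self.area_split, self.missing_day_rate, self.whole_deployment_loss_rate]
        probs += list(self.psi1.values()) if isinstance(self.psi1, Mapping) else [self.psi1]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.habitat_score_probs) - 1.0) > 1e-9:
            raise ValueError("habitat_score_probs must sum to 1")
        if self.n_years > 1:
            _per_transition(self.gamma, self.n_years - 1, "gamma")
            _per_transition(self.eps, self.n_years - 1, "eps")
        if len(self.beta_year) < self.n_years - 1:
            raise ValueError("beta_year must cover years 2..n_years")

    @property
    def seasons(self) -> tuple[str, ...]:
        return tuple(str(self.first_year + t) for t in range(self.n_years))

    def psi1_for(self, area: str) -> float:
        if isinstance(self.psi1, Mapping):
            return float(self.psi1[area])
        return float(self.psi1)

    def _streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(3)
        return {
            name: np.random.default_rng(s)
            for name, s in zip(("sites", "occupancy", "detections"), kids)
        }


@dataclass(frozen=True)
class LatentStates:
    """Latent occupancy indicators z[site, season] in {0, 1}."""

    site_ids: tuple[str, ...]
    seasons: tuple[str, ...]
    z: np.ndarray  # (n_sites, n_years) int

    def occupied_fraction(self, year_index: int) -> float:
        return float(self.z[:, year_index].mean())


def simulate_sites(config: SimulationConfig) -> SiteTable:
    """Draw the site table: area allocation and i.i.d. habitat scores."""
    rng = config._streams()["sites"]
    n_bb = int(round(config.n_sites * config.area_split))
    site_ids = [f"S{i + 1:03d}" for i in range(config.n_sites)]
    areas = ["BB"] * n_bb + ["NAD"] * (config.n_sites - n_bb)
    scores = {
        col: rng.choice(4, size=config.n_sites, p=config.habitat_score_probs)
        for col in SCORE_COLUMNS
    }
    df = pd.DataFrame(
        {
            "site_id": site_ids,
            "area": areas,
            "baited": [a == "BB" for a in areas],
            **scores,
        }
    )
    return SiteTable.from_frame(df)


def simulate_occupancy_dynamics(sites: SiteTable, config: SimulationConfig) -> LatentStates:
    """First-season Bernoulli(psi1) states, then Markov colonization/extinction."""
    rng = config._streams()["occupancy"]
    n = len(sites)
    psi1 = np.array([config.psi1_for(a) for a in sites.frame["area"]])
    z = np.empty((n, config.n_years), dtype=int)
    z[:, 0] = rng.random(n) < psi1
    if config.n_years > 1:
        gam = _per_transition(config.gamma, config.n_years - 1, "gamma")
        eps = _per_transition(config.eps, config.n_years - 1, "eps")
        for t in range(1, config.n_years):
            stay = rng.random(n) < (1.0 - eps[t - 1])
            colonize = rng.random(n) < gam[t - 1]
            z[:, t] = np.where(z[:, t - 1] == 1, stay, colonize)
    return LatentStates(tuple(sites.site_ids), config.seasons, z)


def daily_detection_probability(
    sites: SiteTable, config: SimulationConfig
) -> np.ndarray:
    """Generating delta[site, year] = expit(beta . x), the logistic detection model."""
    df = sites.frame
    eta0 = (
        config.beta_intercept
        + config.beta_bait * df["baited"].to_numpy(dtype=float)
        + config.beta_ground * df["ground_cover"].to_numpy(dtype=float)
        + config.beta_shrub * df["shrub_cover"].to_numpy(dtype=float)
    )
    year_off = np.concatenate([[0.0], np.asarray(config.beta_year[: config.n_years - 1])])
    return expit(eta0[:, None] + year_off[None, :])


def simulate_detections(
    latent: LatentStates, sites: SiteTable, config: SimulationConfig
) -> DetectionDataset:
    """Bernoulli daily outcomes at occupied sites, with missingness injected."""
    rng = config._streams()["detections"]
    delta = daily_detection_probability(sites, config)
    d = config.days_per_deployment
    histories: dict[tuple[str, str, str], np.ndarray] = {}
    for i, site in enumerate(latent.site_ids):
        for t, season in enumerate(latent.seasons):
            lost = rng.random() < config.whole_deployment_loss_rate
            u_days = rng.random(d)
            missing = rng.random(d) < config.missing_day_rate
            if lost:
                continue
            if latent.z[i, t] == 1:
                outcomes = (u_days < delta[i, t]).astype(float)
            else:
                outcomes = np.zeros(d)
            outcomes[missing] = np.nan
            if np.isnan(outcomes).all():
                continue
            histories[(config.species, site, season)] = outcomes
    return DetectionDataset(latent.seasons, histories)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[DetectionDataset, SiteTable, LatentStates]:
    """Full pipeline: sites, latent occupancy, detection histories."""
    sites = simulate_sites(config)
    latent = simulate_occupancy_dynamics(sites, config)
    data = simulate_detections(latent, sites, config)
    return data, sites, latent
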