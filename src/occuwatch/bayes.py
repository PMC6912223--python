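"""Bayesian logistic model of daily detection probability.

Conditional on a site being used by the species in a season (operationalised
as: at least one detection of the species at that site in that season), each
surveyed day is a Bernoulli trial,

    d_ij ~ Bernoulli(delta_j),    logit(delta_j) = beta . x_j,

where x_j holds an intercept and, depending on the model variant, the site's
baiting status, its ground- and shrub-cover scores (numeric 0-3), and
categorical year indicators (first season as baseline). Coefficients carry
independent vague normal priors parameterised by mean and *precision*
(inverse variance); the default precision 1e-6 corresponds to sd 1000.

Posterior sampling is an in-house random-walk Metropolis sampler updating one
coefficient at a time, with per-coordinate proposal scales adapted during
burn-in only (targeting 20-40% acceptance) and frozen afterwards so the
post-burn-in chain satisfies detailed balance. Convergence is monitored with
the Gelman-Rubin potential scale reduction factor (flagging >= 1.05) and
per-coefficient autocorrelation tables; model comparison uses the deviance
information criterion DIC = Dbar + pD with pD = Dbar - D(posterior mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import DetectionDataset, SiteTable

logger = logging.getLogger(__name__)


class DetectionModel(str, Enum):
    """The five detection-model variants compared per species."""

    NULL = "Null"
    BAIT = "Baiting"
    HABITAT = "Habitat"
    BAIT_HABITAT = "Baiting + Habitat"
    FULL = "Baiting + Habitat + Year"

    @property
    def uses_bait(self) -> bool:
        return self in (DetectionModel.BAIT, DetectionModel.BAIT_HABITAT, DetectionModel.FULL)

    @property
    def uses_habitat(self) -> bool:
        return self in (DetectionModel.HABITAT, DetectionModel.BAIT_HABITAT, DetectionModel.FULL)

    @property
    def uses_year(self) -> bool:
        return self is DetectionModel.FULL


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal prior on each coefficient, N(mean, 1/precision)."""

    mean: float = 0.0
    precision: float = 1e-6

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("precision must be positive")

    @property
    def sd(self) -> float:
        return self.precision**-0.5


@dataclass(frozen=True)
class DesignMatrix:
    """Day-level logistic design for one species' conditioned dataset.

    ``X`` has one row per retained non-missing survey day; ``y`` is the daily
    outcome. Rows sharing a covariate profile are exchangeable, so the sampler
    works with the aggregated binomial form (``x_unique``, ``successes``,
    ``trials``), which is likelihood-equivalent.
    """

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    variant: DetectionModel
    seasons: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def aggregated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.n_rows == 0:
            k = len(self.columns)
            return np.empty((0, k)), np.empty(0), np.empty(0)
        df = pd.DataFrame(self.X)
        df["_y"] = self.y
        grouped = df.groupby(list(range(self.X.shape[1])), as_index=False).agg(
            successes=("_y", "sum"), trials=("_y", "size")
        )
        xu = grouped.iloc[:, : self.X.shape[1]].to_numpy(dtype=float)
        return xu, grouped["successes"].to_numpy(dtype=float), grouped["trials"].to_numpy(dtype=float)


def condition_on_occupancy(data: DetectionDataset, species: str | None = None) -> DetectionDataset:
    """Keep only (site, season) records with at least one detection.

    The detection model is defined conditional on use: sites where the species
    was never recorded in a season carry no information about daily detection
    probability given presence, and are removed for that season.
    """
    if species is not None:
        data = data.subset(species=species)
    hist = {k: v for k, v in data.histories.items() if np.nansum(v) > 0}
    if not hist:
        raise ValueError("no records with detections; detection model is unfittable")
    return DetectionDataset(data.seasons, hist)


def build_design(
    data: DetectionDataset, sites: SiteTable, variant: DetectionModel
) -> DesignMatrix:
    """Long-format day-level design matrix for a conditioned dataset."""
    variant = DetectionModel(variant)
    cols = ["intercept"]
    if variant.uses_bait:
        cols.append("bait")
    if variant.uses_habitat:
        cols += ["ground", "shrub"]
    year_levels = list(data.seasons[1:]) if variant.uses_year else []
    cols += [f"year_{y}" for y in year_levels]

    rows, ys = [], []
    for (sp, site, season), h in sorted(data.histories.items()):
        cov = sites.covariates(site)
        base = [1.0]
        if variant.uses_bait:
            base.append(float(cov["baited"]))
        if variant.uses_habitat:
            base += [float(cov["ground_cover"]), float(cov["shrub_cover"])]
        base += [1.0 if season == y else 0.0 for y in year_levels]
        obs = h[~np.isnan(h)]
        rows += [base] * obs.size
        ys.append(obs)
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(cols)))
    y = np.concatenate(ys) if ys else np.empty(0)
    return DesignMatrix(X, y, tuple(cols), variant, data.seasons)


@dataclass(frozen=True)
class PosteriorDraws:
    """MCMC output: all draws of every chain plus the burn-in index.

    ``chains`` has shape (n_chains, iterations, n_coefficients); draws with
    index >= ``burn_in`` form the posterior sample (no thinning).
    """

    chains: np.ndarray
    burn_in: int
    columns: tuple[str, ...]
    variant: DetectionModel
    prior: PriorSpec
    seed: int
    acceptance: np.ndarray  # (n_chains, n_coefficients), post-burn-in rates

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def iterations(self) -> int:
        return self.chains.shape[1]

    def posterior(self) -> np.ndarray:
        """Post-burn-in draws pooled across chains, shape (n, k)."""
        return self.chains[:, self.burn_in :, :].reshape(-1, self.chains.shape[2])

    def summary(self) -> pd.DataFrame:
        post = self.posterior()
        return pd.DataFrame(
            {
                "coefficient": self.columns,
                "mean": post.mean(axis=0),
                "sd": post.std(axis=0, ddof=1),
                "q2.5": np.percentile(post, 2.5, axis=0),
                "q97.5": np.percentile(post, 97.5, axis=0),
            }
        )


def _bernoulli_loglik(beta: np.ndarray, xu: np.ndarray, s: np.ndarray, n: np.ndarray) -> float:
    """Binomial-aggregated Bernoulli-logit log likelihood."""
    if xu.shape[0] == 0:
        return 0.0
    eta = xu @ beta
    return float(s @ eta - n @ np.logaddexp(0.0, eta))


def sample_posterior(
    design: DesignMatrix,
    priors: PriorSpec = PriorSpec(),
    iterations: int = 2500,
    chains: int = 2,
    seed: int = 0,
    adapt_window: int = 50,
) -> PosteriorDraws:
    """Random-walk Metropolis sampling of the detection coefficients.

    Each coefficient is updated in turn with a normal proposal whose scale is
    adapted every ``adapt_window`` iterations during the first half of the run
    (the burn-in) to keep acceptance between 0.2 and 0.4, then frozen. The
    first half of every chain is discarded as burn-in downstream.
    """
    if iterations < 2000:
        raise ValueError("use at least 2000 iterations")
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    k = len(design.columns)
    if design.n_rows > 0:
        sd = design.X.std(axis=0)
        const = sd < 1e-12
        const[0] = False  # the intercept is constant by construction
        if const.any():
            bad = [design.columns[i] for i in np.flatnonzero(const)]
            raise ValueError(f"degenerate design: constant column(s) {bad}")
        if np.linalg.matrix_rank(design.X) < k:
            raise ValueError("degenerate design: collinear columns")
    xu, s, n = design.aggregated()

    burn_in = iterations // 2
    all_chains = np.empty((chains, iterations, k))
    acceptance = np.empty((chains, k))
    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        beta = rng.normal(0.0, 1.0, size=k)
        step = np.full(k, 0.5)
        ll = _bernoulli_loglik(beta, xu, s, n)
        lp = -0.5 * priors.precision * np.sum((beta - priors.mean) ** 2)
        accepts = np.zeros(k)
        window_accepts = np.zeros(k)
        post_accepts = np.zeros(k)
        for it in range(iterations):
            for j in range(k):
                prop = beta.copy()
                prop[j] += rng.normal(0.0, step[j])
                ll_p = _bernoulli_loglik(prop, xu, s, n)
                lp_p = -0.5 * priors.precision * np.sum((prop - priors.mean) ** 2)
                if np.log(rng.random()) < (ll_p + lp_p) - (ll + lp):
                    beta, ll, lp = prop, ll_p, lp_p
                    window_accepts[j] += 1
                    if it >= burn_in:
                        post_accepts[j] += 1
            all_chains[c, it] = beta
            if it < burn_in and (it + 1) % adapt_window == 0:
                rate = window_accepts / adapt_window
                step = np.where(rate > 0.4, step * 1.5, step)
                step = np.where(rate < 0.2, step * 0.7, step)
                window_accepts[:] = 0.0
        acceptance[c] = post_accepts / max(iterations - burn_in, 1)
    logger.info("acceptance rates (post burn-in): %s", acceptance.mean(axis=0))
    return PosteriorDraws(
        chains=all_chains,
        burn_in=burn_in,
        columns=design.columns,
        variant=design.variant,
        prior=priors,
        seed=seed,
        acceptance=acceptance,
    )


def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Potential scale reduction factor per coefficient (flag if >= 1.05).

    Computed from post-burn-in segments of >= 2 chains; the finite-sample PSRF
    falls marginally below 1 when chains agree perfectly, so values are clamped
    at 1 from below (zero between-chain variance gives exactly 1).
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    seg = draws.chains[:, draws.burn_in :, :]
    m, n, k = seg.shape
    if n < 2:
        raise ValueError("post-burn-in segment too short")
    chain_means = seg.mean(axis=1)  # (m, k)
    chain_vars = seg.var(axis=1, ddof=1)  # (m, k)
    W = chain_vars.mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)  # = B / n
    var_hat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W == 0, 1.0, np.maximum(rhat, 1.0))
    out = pd.Series(rhat, index=list(draws.columns), name="rhat")
    flagged = out[out >= 1.05]
    if len(flagged):
        logger.warning("Gelman-Rubin >= 1.05 for: %s", dict(flagged))
    return out


def autocorrelation_table(draws: PosteriorDraws, lags: Sequence[int] = (1, 5, 10, 25)) -> pd.DataFrame:
    """Pooled-chain autocorrelation at selected lags, per coefficient."""
    seg = draws.chains[:, draws.burn_in :, :]
    m, n, k = seg.shape
    rows = []
    for j, name in enumerate(draws.columns):
        row = {"coefficient": name}
        for lag in lags:
            acs = []
            for c in range(m):
                x = seg[c, :, j]
                x = x - x.mean()
                denom = float(x @ x)
                acs.append(float(x[:-lag] @ x[lag:]) / denom if denom > 0 else 0.0)
            row[f"lag_{lag}"] = float(np.mean(acs))
        rows.append(row)
    return pd.DataFrame(rows)


def dic(draws: PosteriorDraws, design: DesignMatrix) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    DIC = Dbar + pD where Dbar is the posterior mean of the deviance
    D(beta) = -2 log L(beta) and pD = Dbar - D(posterior mean of beta).
    """
    xu, s, n = design.aggregated()
    post = draws.posterior()
    if xu.shape[0] == 0:
        dev = np.zeros(post.shape[0])
    else:
        eta = post @ xu.T  # (n_draws, n_groups)
        dev = -2.0 * (eta @ s - np.logaddexp(0.0, eta) @ n)
    if not np.isfinite(dev).all():
        raise ValueError("non-finite deviance over posterior draws")
    dbar = float(dev.mean())
    d_at_mean = -2.0 * _bernoulli_loglik(post.mean(axis=0), xu, s, n)
    pd_ = dbar - d_at_mean
    return dbar + pd_, pd_


@dataclass(frozen=True)
class DetectionEstimate:
    """Posterior summary of daily detection probability for one profile."""

    profile: dict
    mean: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.mean <= self.hi <= 1.0):
            raise ValueError("need 0 <= lo <= mean <= hi <= 1")


def _profile_vector(profile: Mapping, columns: Sequence[str]) -> np.ndarray:
    x = np.empty(len(columns))
    for i, col in enumerate(columns):
        if col == "intercept":
            x[i] = 1.0
        elif col.startswith("year_"):
            if "year" not in profile:
                raise ValueError(f"profile missing 'year' needed for column {col}")
            x[i] = 1.0 if str(profile["year"]) == col[len("year_") :] else 0.0
        else:
            if col not in profile:
                raise ValueError(f"profile missing covariate {col!r}")
            x[i] = float(profile[col])
    return x


def posterior_delta(draws: PosteriorDraws, profile: Mapping) -> np.ndarray:
    """Per-draw daily detection probability for one covariate profile."""
    x = _profile_vector(profile, draws.columns)
    return expit(draws.posterior() @ x)


def detection_curves(
    draws: PosteriorDraws, profiles: Sequence[Mapping]
) -> list[DetectionEstimate]:
    """Posterior mean and 95% credible interval of delta per covariate profile."""
    out = []
    for prof in profiles:
        delta = posterior_delta(draws, prof)
        out.append(
            DetectionEstimate(
                profile=dict(prof),
                mean=float(delta.mean()),
                lo=float(np.percentile(delta, 2.5)),
                hi=float(np.percentile(delta, 97.5)),
            )
        )
    return out
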