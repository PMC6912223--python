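"""Dynamic (multi-season) occupancy: colonization/extinction MLE, occupancy
projection, and parametric-bootstrap trajectory intervals.

The latent occupancy state of a site evolves as a two-state Markov chain
between seasons: an occupied site stays occupied with probability 1-eps_t and
an unoccupied one becomes occupied with probability gamma_t. Within a season,
detection on each surveyed day is Bernoulli(p) conditional on occupancy. The
site likelihood is computed by the forward recursion over the hidden chain:

    alpha_1 = (1-psi1, psi1) * e_1,    alpha_{t} = (alpha_{t-1} @ T_t) * e_t

with per-season emission e_t = ((d_t == 0), p^d_t (1-p)^(m_t - d_t)) and
transition matrix T_t = [[1-gamma_t, gamma_t], [eps_t, 1-eps_t]]. A season with
no surveyed days at a site has emission (1, 1), keeping the chain intact.

Derived occupancy in later seasons follows the recursion

    psi_{t+1} = psi_t (1 - eps_t) + (1 - psi_t) gamma_t

whose fixed point for constant rates is gamma / (gamma + eps). Uncertainty for
the derived trajectory comes from a parametric bootstrap: parameter vectors are
drawn from the multivariate normal with the MLE's working-scale covariance,
back-transformed and iterated through the recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import AREAS, DetectionDataset, SiteTable
from .single_season import _LOGIT_BOUND, _safe_vcov

logger = logging.getLogger(__name__)


class MultiSeasonModel(str, Enum):
    """The four dynamic-model variants compared for each species."""

    CONSTANT = "psi(.)g(.)e(.)p(.)"
    PSI_AREA = "psi(area)g(.)e(.)p(.)"
    PSI_AREA_YEAR = "psi(area)g(year)e(year)p(.)"
    YEAR = "psi(.)g(year)e(year)p(.)"

    @property
    def area_effect(self) -> bool:
        return self in (MultiSeasonModel.PSI_AREA, MultiSeasonModel.PSI_AREA_YEAR)

    @property
    def year_effect(self) -> bool:
        return self in (MultiSeasonModel.PSI_AREA_YEAR, MultiSeasonModel.YEAR)

    def n_params(self, n_seasons: int) -> int:
        if n_seasons == 1:
            n_trans = 0  # no transitions to estimate
        else:
            n_trans = (n_seasons - 1) if self.year_effect else 1
        return (2 if self.area_effect else 1) + 2 * n_trans + 1


@dataclass(frozen=True)
class MultiSeasonParams:
    """Natural-scale parameters of the dynamic model."""

    psi1_bb: float
    psi1_nad: float
    gamma: np.ndarray  # per transition
    eps: np.ndarray
    p: float


@dataclass(frozen=True)
class MultiSeasonFit:
    """MLE of a dynamic occupancy model.

    ``theta`` layout (all logit scale): psi1 intercept [, NAD contrast],
    gamma (1 or T-1), eps (1 or T-1), p.
    """

    model: MultiSeasonModel
    theta: np.ndarray
    loglik: float
    K: int
    vcov: np.ndarray
    converged: bool
    boundary: bool
    n_sites: int
    seasons: tuple[str, ...]

    @property
    def AIC(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.K

    def params(self, theta: np.ndarray | None = None) -> MultiSeasonParams:
        """Unpack a working-scale vector (default: the MLE) to natural scale."""
        t = self.theta if theta is None else np.asarray(theta)
        return _unpack(t, self.model, len(self.seasons))


def _unpack(theta: np.ndarray, model: MultiSeasonModel, T: int) -> MultiSeasonParams:
    if T == 1:
        n_trans = 0
    else:
        n_trans = (T - 1) if model.year_effect else 1
    i = 0
    psi_bb = expit(theta[i])
    i += 1
    if model.area_effect:
        psi_nad = expit(theta[0] + theta[i])
        i += 1
    else:
        psi_nad = psi_bb
    gamma = expit(theta[i : i + n_trans])
    i += n_trans
    eps = expit(theta[i : i + n_trans])
    i += n_trans
    p = expit(theta[i])
    if not model.year_effect and T > 1:
        gamma = np.repeat(gamma, T - 1)
        eps = np.repeat(eps, T - 1)
    return MultiSeasonParams(float(psi_bb), float(psi_nad), gamma, eps, float(p))


def multi_season_site_likelihood(
    histories,
    psi1: float,
    gamma,
    eps,
    p: float,
) -> float:
    """Forward-recursion probability of one site's multi-season history.

    ``histories`` is a sequence of per-season day vectors (entries 0/1/NaN;
    an empty or all-NaN vector is a season with no information). ``gamma`` and
    ``eps`` may be scalars or per-transition sequences of length T-1.
    """
    T = len(histories)
    if T < 1:
        raise ValueError("need at least one season")
    for val, name in ((psi1, "psi1"), (p, "p")):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    gam = np.broadcast_to(np.asarray(gamma, dtype=float), (max(T - 1, 1),)) if T > 1 else np.empty(0)
    ep = np.broadcast_to(np.asarray(eps, dtype=float), (max(T - 1, 1),)) if T > 1 else np.empty(0)

    def emission(h):
        h = np.asarray(h, dtype=float)
        obs = h[~np.isnan(h)]
        m, d = obs.size, obs.sum()
        e_occ = p**d * (1.0 - p) ** (m - d)
        e_emp = 1.0 if d == 0 else 0.0
        return np.array([e_emp, e_occ])

    alpha = np.array([1.0 - psi1, psi1]) * emission(histories[0])
    for t in range(1, T):
        trans = np.array([[1.0 - gam[t - 1], gam[t - 1]], [ep[t - 1], 1.0 - ep[t - 1]]])
        alpha = (alpha @ trans) * emission(histories[t])
    return float(alpha.sum())


def _dataset_stats(
    data: DetectionDataset, sites: SiteTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(d, m) arrays of shape (n_sites, T) and a NAD indicator per site.

    Sites are those appearing in any season; seasons with no record at a site
    get m = 0 (no information).
    """
    T = len(data.seasons)
    season_ix = {s: t for t, s in enumerate(data.seasons)}
    site_list = sorted({k[1] for k in data.histories})
    site_ix = {s: j for j, s in enumerate(site_list)}
    d = np.zeros((len(site_list), T))
    m = np.zeros((len(site_list), T))
    for (sp, site, season), h in data.histories.items():
        j, t = site_ix[site], season_ix[season]
        d[j, t] = np.nansum(h)
        m[j, t] = (~np.isnan(h)).sum()
    nad = np.array([sites.area_of(s) == "NAD" for s in site_list])
    return d, m, nad


def _negloglik_multi(
    theta: np.ndarray, d, m, nad, model: MultiSeasonModel, T: int
) -> float:
    pars = _unpack(theta, model, T)
    psi1 = np.where(nad, pars.psi1_nad, pars.psi1_bb)
    p = pars.p
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e_occ = d * np.log(p) + (m - d) * np.log1p(-p)
    log_e_occ = np.where(m > 0, log_e_occ, 0.0)
    e_occ = np.exp(np.where(np.isnan(log_e_occ), -np.inf, log_e_occ))
    e_emp = (d == 0).astype(float)

    a0 = (1.0 - psi1) * e_emp[:, 0]
    a1 = psi1 * e_occ[:, 0]
    logscale = np.zeros(d.shape[0])
    for t in range(1, T):
        g, e = pars.gamma[t - 1], pars.eps[t - 1]
        b0 = a0 * (1.0 - g) + a1 * e
        b1 = a0 * g + a1 * (1.0 - e)
        a0 = b0 * e_emp[:, t]
        a1 = b1 * e_occ[:, t]
        s = a0 + a1
        # renormalise to avoid underflow over long histories
        safe = np.where(s > 0, s, 1.0)
        a0, a1 = a0 / safe, a1 / safe
        logscale += np.where(s > 0, np.log(safe), -np.inf)
    total = a0 + a1
    with np.errstate(divide="ignore"):
        ll = np.log(total) + logscale
    if np.isneginf(ll).any():
        return 1e12  # impossible history under these parameters
    return -float(ll.sum())


def fit_multi_season(
    data: DetectionDataset,
    sites: SiteTable,
    model: MultiSeasonModel = MultiSeasonModel.CONSTANT,
    n_restarts: int = 5,
    seed: int = 0,
) -> MultiSeasonFit:
    """Maximum-likelihood fit of one of the four dynamic-model variants."""
    model = MultiSeasonModel(model)
    T = len(data.seasons)
    d, m, nad = _dataset_stats(data, sites)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    if d.sum() == 0:
        raise ValueError("no detections: model is not identifiable")
    if T < 2 and model.year_effect:
        raise ValueError("year-varying dynamics need at least 2 seasons")

    k = model.n_params(T)
    naive_psi = np.clip((d.sum(axis=1) > 0).mean(), 0.05, 0.95)
    naive_p = np.clip(d.sum() / max(m.sum(), 1.0) / naive_psi, 0.02, 0.95)
    start0 = np.zeros(k)
    start0[0] = logit(naive_psi)
    start0[1:-1] = logit(0.15)  # turnover rates are typically small
    start0[-1] = logit(naive_p)
    if model.area_effect:
        start0[1] = 0.0

    rng = np.random.default_rng(seed)
    starts = [start0] + [rng.normal(0.0, 1.5, size=k) for _ in range(n_restarts)]
    best = None
    for s in starts:
        res = minimize(
            _negloglik_multi,
            s,
            args=(d, m, nad, model, T),
            method="L-BFGS-B",
            bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * k,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = np.asarray(best.x)
    boundary = bool((np.abs(theta) >= _LOGIT_BOUND - 1e-6).any())
    vcov, hess_ok = _safe_vcov(
        lambda t: _negloglik_multi(t, d, m, nad, model, T), theta
    )
    converged = bool(best.success) and hess_ok and not boundary
    if not converged:
        logger.warning(
            "multi-season fit flagged non-converged (success=%s, boundary=%s)",
            best.success,
            boundary,
        )
    return MultiSeasonFit(
        model=model,
        theta=theta,
        loglik=-float(best.fun),
        K=k,
        vcov=vcov,
        converged=converged,
        boundary=boundary,
        n_sites=int(d.shape[0]),
        seasons=data.seasons,
    )


def project_occupancy(psi_t: float, gamma_t: float, eps_t: float) -> float:
    """One step of the occupancy recursion psi' = psi (1-eps) + (1-psi) gamma."""
    for name, v in (("psi_t", psi_t), ("gamma_t", gamma_t), ("eps_t", eps_t)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return psi_t * (1.0 - eps_t) + (1.0 - psi_t) * gamma_t


def _trajectory(pars: MultiSeasonParams, T: int) -> dict[str, np.ndarray]:
    out = {}
    for area, psi0 in (("BB", pars.psi1_bb), ("NAD", pars.psi1_nad)):
        traj = np.empty(T)
        traj[0] = psi0
        for t in range(1, T):
            traj[t] = project_occupancy(traj[t - 1], pars.gamma[t - 1], pars.eps[t - 1])
        out[area] = traj
    return out


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Derived per-season occupancy with bootstrap percentile intervals."""

    table: pd.DataFrame  # columns season, area, estimate, lo, hi
    n_boot: int

    def for_area(self, area: str) -> pd.DataFrame:
        return self.table[self.table["area"] == area].reset_index(drop=True)


def bootstrap_trajectory(
    fit: MultiSeasonFit, n_boot: int = 1000, seed: int = 0
) -> OccupancyTrajectory:
    """Parametric bootstrap of the derived occupancy trajectory.

    Draws ``n_boot`` working-scale parameter vectors from N(theta, vcov),
    back-transforms, iterates the occupancy recursion per area, and reports
    2.5/97.5 percentile bounds around the point trajectory from the MLE.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refit before bootstrapping")
    vcov = np.asarray(fit.vcov)
    w, V = np.linalg.eigh(0.5 * (vcov + vcov.T))
    if (w < -1e-8).any():
        raise ValueError("vcov is not positive semi-definite; refit the model")
    L = V * np.sqrt(np.clip(w, 0.0, None))

    T = len(fit.seasons)
    rng = np.random.default_rng(seed)
    draws = fit.theta + rng.standard_normal((n_boot, fit.theta.size)) @ L.T
    boots = {a: np.empty((n_boot, T)) for a in AREAS}
    for b in range(n_boot):
        trajs = _trajectory(fit.params(draws[b]), T)
        for a in AREAS:
            boots[a][b] = trajs[a]
    point = _trajectory(fit.params(), T)
    rows = []
    for a in AREAS:
        lo = np.percentile(boots[a], 2.5, axis=0)
        hi = np.percentile(boots[a], 97.5, axis=0)
        for t, season in enumerate(fit.seasons):
            rows.append(
                {
                    "season": season,
                    "area": a,
                    "estimate": point[a][t],
                    "lo": min(lo[t], point[a][t]),
                    "hi": max(hi[t], point[a][t]),
                }
            )
    return OccupancyTrajectory(pd.DataFrame(rows), n_boot)
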