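"""Single-season occupancy estimation under imperfect detection.

Model: each site is occupied with probability psi (optionally differing by
study area); on each surveyed day at an occupied site the species is detected
with constant probability p. For a site with detection history h (m surveyed
days, d detections) the marginal likelihood is

    L = psi * p^d * (1-p)^(m-d)              if d > 0
    L = psi * (1-p)^m + (1-psi)              if d = 0

Missing days contribute nothing. Fitting is by maximum likelihood on the logit
(working) scale with multiple random restarts; the covariance of the working
parameters comes from the inverse numerical Hessian at the optimum, and
confidence intervals for occupancy are Wald intervals on the logit scale
back-transformed to probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess

from .data import AREAS, DetectionDataset, SiteTable

logger = logging.getLogger(__name__)

_LOGIT_BOUND = 15.0  # |working parameter| beyond this is a boundary estimate


class SingleSeasonModel(str, Enum):
    PSI_DOT = "psi(.)p(.)"
    PSI_AREA = "psi(area)p(.)"


@dataclass(frozen=True)
class EstimateWithCI:
    """A probability estimate with a 95% interval."""

    estimate: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.estimate <= self.hi <= 1.0):
            raise ValueError("interval must satisfy 0 <= lo <= estimate <= hi <= 1")


@dataclass(frozen=True)
class SingleSeasonFit:
    """MLE of a single-season occupancy model on the working (logit) scale.

    ``theta`` is ``[logit psi]`` (plus an area contrast for the NAD area under
    the psi(area) model) followed by ``[logit p]``. ``vcov`` is the asymptotic
    covariance of ``theta``; ``boundary`` flags estimates pinned at the edge of
    the working-parameter box (e.g. every site detected, so psi-hat -> 1).
    """

    model: SingleSeasonModel
    theta: np.ndarray
    loglik: float
    K: int
    vcov: np.ndarray
    converged: bool
    boundary: bool
    n_sites: int

    @property
    def AIC(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.K

    @property
    def p_hat(self) -> float:
        return float(expit(self.theta[-1]))

    def psi_hat(self, area: str = "BB") -> float:
        return self.predict_occupancy(area).estimate

    def predict_occupancy(self, area: str = "BB") -> EstimateWithCI:
        """Occupancy for an area, with a Wald 95% CI on the logit scale."""
        return predict_occupancy(self, area)


def single_season_site_likelihood(history, psi: float, p: float) -> float:
    """Marginal likelihood of one site's detection history.

    ``history`` is a day-outcome vector with entries 0, 1 or NaN. An
    all-missing record carries no information and has likelihood 1.
    """
    if not (0.0 <= psi <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("psi and p must lie in [0, 1]")
    h = np.asarray(history, dtype=float)
    obs = h[~np.isnan(h)]
    m = obs.size
    if m == 0:
        logger.warning("all-missing history: likelihood defined as 1")
        return 1.0
    d = int(obs.sum())
    if d > 0:
        return float(psi * p**d * (1.0 - p) ** (m - d))
    return float(psi * (1.0 - p) ** m + (1.0 - psi))


def _site_stats(
    data: DetectionDataset, sites: SiteTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site sufficient statistics (d, m, is_nad); all-missing records dropped."""
    ds, ms, nad = [], [], []
    n_dropped = 0
    for (sp, site, season), h in sorted(data.histories.items()):
        m = int((~np.isnan(h)).sum())
        if m == 0:
            n_dropped += 1
            continue
        ds.append(np.nansum(h))
        ms.append(m)
        nad.append(sites.area_of(site) == "NAD")
    if n_dropped:
        logger.warning("dropped %d record(s) with no surveyed days", n_dropped)
    return np.array(ds), np.array(ms, dtype=float), np.array(nad, dtype=bool)


def _negloglik(theta: np.ndarray, d, m, nad, model: SingleSeasonModel) -> float:
    if model is SingleSeasonModel.PSI_AREA:
        eta_psi = theta[0] + theta[1] * nad
        lp = theta[2]
    else:
        eta_psi = np.full(d.shape, theta[0])
        lp = theta[1]
    psi = expit(eta_psi)
    p = expit(lp)
    detected = d > 0
    ll = np.empty(d.shape)
    with np.errstate(divide="ignore"):
        ll[detected] = (
            np.log(psi[detected])
            + d[detected] * np.log(p)
            + (m[detected] - d[detected]) * np.log1p(-p)
        )
        q = np.exp(m[~detected] * np.log1p(-p))  # (1-p)^m
        ll[~detected] = np.log(psi[~detected] * q + 1.0 - psi[~detected])
    return -float(ll.sum())


def fit_single_season(
    data: DetectionDataset,
    sites: SiteTable,
    model: SingleSeasonModel = SingleSeasonModel.PSI_DOT,
    n_restarts: int = 5,
    seed: int = 0,
) -> SingleSeasonFit:
    """Maximum-likelihood fit of psi(.)p(.) or psi(area)p(.).

    Starts from a naive-occupancy heuristic plus ``n_restarts`` random
    working-scale starting points and keeps the best optimum.
    """
    model = SingleSeasonModel(model)
    d, m, nad = _site_stats(data, sites)
    if d.size < 2:
        raise ValueError("need at least 2 sites with surveyed days")
    if d.sum() == 0:
        raise ValueError("no detections: occupancy and detection are not identifiable")

    naive_psi = np.clip((d > 0).mean(), 0.05, 0.95)
    naive_p = np.clip(d.sum() / m.sum() / naive_psi, 0.02, 0.95)
    k = 3 if model is SingleSeasonModel.PSI_AREA else 2
    start0 = np.zeros(k)
    start0[0] = logit(naive_psi)
    start0[-1] = logit(naive_p)

    rng = np.random.default_rng(seed)
    starts = [start0] + [rng.normal(0.0, 1.5, size=k) for _ in range(n_restarts)]
    best = None
    for s in starts:
        res = minimize(
            _negloglik,
            s,
            args=(d, m, nad, model),
            method="L-BFGS-B",
            bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * k,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = np.asarray(best.x)
    boundary = bool((np.abs(theta) >= _LOGIT_BOUND - 1e-6).any())
    if boundary:
        logger.warning("boundary estimate: working parameters %s", theta)
    vcov, hess_ok = _safe_vcov(
        lambda t: _negloglik(t, d, m, nad, model), theta
    )
    converged = bool(best.success) and hess_ok and not boundary
    if not converged:
        logger.warning("fit flagged non-converged (success=%s, boundary=%s)", best.success, boundary)
    return SingleSeasonFit(
        model=model,
        theta=theta,
        loglik=-float(best.fun),
        K=k,
        vcov=vcov,
        converged=converged,
        boundary=boundary,
        n_sites=int(d.size),
    )


def _safe_vcov(negloglik, theta: np.ndarray) -> tuple[np.ndarray, bool]:
    """Inverse numerical Hessian, symmetrised; flags failure instead of raising."""
    try:
        hess = approx_hess(theta, negloglik)
        vcov = np.linalg.inv(hess)
        vcov = 0.5 * (vcov + vcov.T)
        ok = bool(np.all(np.isfinite(vcov)) and np.all(np.diag(vcov) >= 0))
    except np.linalg.LinAlgError:
        vcov = np.full((theta.size, theta.size), np.nan)
        ok = False
    return vcov, ok


def predict_occupancy(fit: SingleSeasonFit, area: str = "BB") -> EstimateWithCI:
    """Back-transformed occupancy estimate for an area with Wald 95% CI."""
    if area not in AREAS:
        raise ValueError(f"unknown area {area!r}")
    if fit.model is SingleSeasonModel.PSI_DOT:
        if area != "BB":
            logger.info("psi(.) model has no area effect; returning common estimate")
        grad = np.zeros(fit.K)
        grad[0] = 1.0
    else:
        grad = np.zeros(fit.K)
        grad[0] = 1.0
        if area == "NAD":
            grad[1] = 1.0
    eta = float(grad @ fit.theta)
    var = float(grad @ fit.vcov @ grad)
    se = np.sqrt(max(var, 0.0))
    lo, hi = expit(eta - 1.959963984540054 * se), expit(eta + 1.959963984540054 * se)
    return EstimateWithCI(float(expit(eta)), float(lo), float(hi))
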