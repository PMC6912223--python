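"""Required survey effort: days of camera deployment needed to trust absence.

If daily detection probability at an occupied site is delta, the chance of at
least one detection over n days is 1 - (1 - delta)^n; solving for the effort
that makes this equal a confidence level alpha gives

    n = log(1 - alpha) / log(1 - delta).

``effort_scenarios`` propagates posterior uncertainty in delta through this
formula: for each posterior draw, delta is evaluated over a set of covariate
profiles and the maximum (best case — a favourable detection environment) and
minimum (worst case) are converted to required days, yielding posterior
distributions of effort per scenario.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bayes import PosteriorDraws, _profile_vector
from scipy.special import expit

logger = logging.getLogger(__name__)


def required_days(delta: float, alpha: float = 0.95) -> float:
    """Continuous survey days needed to be ``alpha``-certain of absence.

    Strictly decreasing in ``delta`` and increasing in ``alpha``. ``delta`` = 1
    means detection is certain on the first day (returns 1, logged); ``delta``
    = 0 can never be resolved and is an error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if delta <= 0.0 or delta > 1.0:
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    if delta == 1.0:
        logger.info("delta = 1: species detected on the first survey day")
        return 1.0
    return math.log(1.0 - alpha) / math.log(1.0 - delta)


@dataclass(frozen=True)
class EffortEstimate:
    """Posterior summary of required survey days for one scenario."""

    scenario: str  # "best" or "worst"
    alpha: float
    n_continuous: float  # posterior mean of continuous days
    n_days: int  # operational ceiling, >= 1
    lo: float
    hi: float
    adequate: bool  # hi within the stated deployment length
    n_infinite: int = 0  # draws with delta numerically 0 (contribute +inf)

    def __post_init__(self) -> None:
        if math.isfinite(self.n_continuous) and self.n_days != max(
            1, math.ceil(self.n_continuous)
        ):
            raise ValueError("n_days must be ceil(n_continuous), minimum 1")


def effort_scenarios(
    draws: PosteriorDraws,
    profiles: Sequence[Mapping],
    alpha: float = 0.95,
    deployment_days: float = 40.0,
) -> list[EffortEstimate]:
    """Best-/worst-case required survey days from posterior detection draws.

    For each posterior draw the detection probability is computed across all
    ``profiles``; the largest value defines the best-case scenario and the
    smallest the worst-case. Each is pushed through the days-to-detect formula
    and summarised by its mean and 2.5/97.5 percentiles. A scenario is
    ``adequate`` when its upper percentile fits within ``deployment_days``.
    """
    if not profiles:
        raise ValueError("need at least one covariate profile")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    xs = np.stack([_profile_vector(p, draws.columns) for p in profiles])
    delta = expit(draws.posterior() @ xs.T)  # (n_draws, n_profiles)
    out = []
    log_target = math.log(1.0 - alpha)
    for scenario, d in (("best", delta.max(axis=1)), ("worst", delta.min(axis=1))):
        zero = d <= 0.0
        n_inf = int(zero.sum())
        if n_inf:
            logger.warning("%d draw(s) with delta = 0 in %s case; effort infinite", n_inf, scenario)
        with np.errstate(divide="ignore"):
            n = np.where(d >= 1.0, 1.0, log_target / np.log1p(-np.where(zero, 0.5, d)))
        n[zero] = np.inf
        mean = float(n[np.isfinite(n)].mean()) if np.isfinite(n).any() else math.inf
        with np.errstate(invalid="ignore"):
            lo, hi = (float(np.percentile(n, q)) for q in (2.5, 97.5))
        # interpolation between infinite order statistics yields NaN; that is +inf
        lo = math.inf if math.isnan(lo) else lo
        hi = math.inf if math.isnan(hi) else hi
        out.append(
            EffortEstimate(
                scenario=scenario,
                alpha=alpha,
                n_continuous=mean,
                n_days=max(1, math.ceil(mean)) if math.isfinite(mean) else 10**9,
                lo=lo,
                hi=hi,
                adequate=bool(hi <= deployment_days),
                n_infinite=n_inf,
            )
        )
    return out
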