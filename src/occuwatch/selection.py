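"""Information-criterion model comparison: delta-AIC/DIC, Akaike weights,
support categories and weighted model averaging.

Akaike weights are the normalised relative likelihoods of a candidate set,

    w_i = exp(-delta_i / 2) / sum_k exp(-delta_k / 2),  delta_i = IC_i - min IC,

computed after min-subtraction for numerical stability. The degree-of-support
bins applied to delta values are 0-2 substantial, 4-7 considerably less and
>10 essentially none; deltas falling in the conventions' gaps (2, 4) and
(7, 10] are labelled intermediate rather than silently assigned to a bin.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .single_season import EstimateWithCI

_Z95 = 1.959963984540054


class Support(str, Enum):
    SUBSTANTIAL = "Substantial"
    INTERMEDIATE = "Intermediate"
    CONSIDERABLY_LESS = "Considerably Less"
    ESSENTIALLY_NONE = "Essentially None"


def akaike_weights(criterion_values: Sequence[float]) -> np.ndarray:
    """Akaike weights from raw criterion values (or, equivalently, deltas)."""
    values = np.asarray(criterion_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one criterion value")
    if not np.isfinite(values).all():
        raise ValueError("criterion values must be finite")
    delta = values - values.min()
    rel = np.exp(-0.5 * delta)
    return rel / rel.sum()


def support_category(delta: float) -> Support:
    """Degree of support implied by a model's delta-IC."""
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    if delta <= 2:
        return Support.SUBSTANTIAL
    if 4 <= delta <= 7:
        return Support.CONSIDERABLY_LESS
    if delta > 10:
        return Support.ESSENTIALLY_NONE
    return Support.INTERMEDIATE


def model_average(
    estimates: Sequence[EstimateWithCI], weights: Sequence[float]
) -> EstimateWithCI:
    """Weighted model-averaged probability estimate with an unconditional CI.

    The point estimate is the weighted mean of the per-model estimates. The
    interval combines within-model variance (recovered from each model's Wald
    CI on the logit scale) with between-model spread via the unconditional
    variance formula, then back-transforms a Wald interval around the averaged
    estimate's logit.
    """
    if len(estimates) != len(weights):
        raise ValueError("estimates and weights must have equal length")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    est = np.array([e.estimate for e in estimates])
    point = float(w @ est)

    tiny = 1e-12
    theta = logit(np.clip(est, tiny, 1 - tiny))
    se = np.array(
        [
            (logit(np.clip(e.hi, tiny, 1 - tiny)) - logit(np.clip(e.lo, tiny, 1 - tiny)))
            / (2 * _Z95)
            for e in estimates
        ]
    )
    theta_bar = float(w @ theta)
    se_uncond = float(w @ np.sqrt(se**2 + (theta - theta_bar) ** 2))
    center = logit(np.clip(point, tiny, 1 - tiny))
    lo = float(expit(center - _Z95 * se_uncond))
    hi = float(expit(center + _Z95 * se_uncond))
    return EstimateWithCI(point, min(lo, point), max(hi, point))


def comparison_table(fits: Sequence, criterion: str = "AIC") -> pd.DataFrame:
    """Publication-shaped comparison table sorted by delta.

    ``fits`` are objects exposing ``model``, ``K`` and an attribute named after
    the criterion (``AIC`` or ``DIC``); tuples ``(label, K, value)`` are also
    accepted. Akaike weights are included for AIC only (the convention for DIC
    tables is deltas without weights). Ties in the criterion are broken toward
    the model with fewer parameters.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "DIC"):
        raise ValueError("criterion must be 'AIC' or 'DIC'")
    rows = []
    for f in fits:
        if isinstance(f, tuple):
            label, K, value = f
        else:
            if not hasattr(f, criterion):
                raise ValueError(f"fit {f!r} has no {criterion} value")
            label = f.model.value if isinstance(f.model, Enum) else str(f.model)
            K, value = f.K, getattr(f, criterion)
        if not np.isfinite(value):
            raise ValueError(f"non-finite {criterion} for model {label}")
        rows.append({"model": label, "K": int(K), criterion: float(value)})
    if not rows:
        raise ValueError("need at least one fit")
    table = pd.DataFrame(rows).sort_values([criterion, "K"], kind="mergesort")
    table["delta"] = table[criterion] - table[criterion].min()
    if criterion == "AIC":
        table["weight"] = akaike_weights(table[criterion].to_numpy())
    table["support"] = [support_category(d).value for d in table["delta"]]
    return table.reset_index(drop=True)
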