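"""Reverse-social-contagion model of activity regulation.

Active workers deactivate upon meeting other active workers, while
inactive workers spontaneously reactivate after a refractory period.
Under complete mixing, each worker has ⟨k⟩ = 2E/N contacts, each active
with probability A/N, so active–active encounters occur at rate
⟨k⟩A²/N; balancing that against spontaneous activation at rate qN gives

    ⟨k⟩ A²/N = q N   ⟹   A = sqrt(q / (2 E0)) · N^((3 − βE)/2),

using the hypermetric interaction scaling E = E0·N^βE. Because βE > 1,
the active fraction falls with colony size: larger colonies keep a
proportionally smaller workforce in motion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ColonySummary
from .scaling_fits import LinearFit, PowerLawFit, fit_linear, fit_power_law

logger = logging.getLogger(__name__)


@dataclass
class ContagionParams:
    """Fitted parameters of the activity-regulation model.

    ``q`` is the ratio of the spontaneous-activation rate to the
    reverse-contagion rate; ``e0`` and ``beta_e`` are the prefactor and
    exponent of the interaction scaling E = E0·N^βE.
    """

    q: float
    e0: float
    beta_e: float

    def __post_init__(self) -> None:
        if self.q <= 0 or self.e0 <= 0:
            raise ValueError("q and e0 must be strictly positive")
        if self.beta_e <= 1:
            logger.warning(
                "beta_e=%.3f <= 1: interaction scaling is not hypermetric, the "
                "predicted active count will not scale hypometrically",
                self.beta_e,
            )


@dataclass
class EffectiveInteractionArea:
    """Mean-field per-worker interaction area with its plausibility bounds."""

    area: float  # 2·Area0·E0, mm²
    stationary_bound: float  # πd², all workers at rest
    steady_motion_bound: float | None  # 2dL, workers in constant motion


def balance_statistic(summary: ColonySummary) -> float:
    """Active–active encounter rate ⟨k⟩A²/N for one colony.

    Computed from tracked quantities: ⟨k⟩ = 2E/N, A = n_active,
    N = n_tracked. Under the balance hypothesis this equals qN.
    """
    if summary.n_tracked <= 0:
        raise ValueError(f"colony {summary.colony_id}: zero tracked count")
    k_mean = 2.0 * summary.e_mean / summary.n_tracked
    return k_mean * summary.n_active**2 / summary.n_tracked


def estimate_q(
    summaries: Sequence[ColonySummary],
    e_fit: PowerLawFit | None = None,
    *,
    zero_intercept: bool = False,
) -> tuple[LinearFit, ContagionParams]:
    """Estimate q as the slope of ⟨k⟩A²/N against N across colonies.

    The regression includes an intercept by default (its p-value is a
    check that the balance line passes near the origin);
    ``zero_intercept=True`` forces the model-faithful line through zero.
    If ``e_fit`` is omitted, the interaction scaling (E0, βE) is fitted
    from the summaries themselves.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 colonies to estimate q")
    n = np.array([s.n_tracked for s in summaries], dtype=float)
    stat = np.array([balance_statistic(s) for s in summaries])
    fit = fit_linear(n, stat, force_zero_intercept=zero_intercept)
    if e_fit is None:
        e_fit = fit_power_law(n, [s.e_mean for s in summaries])
    params = ContagionParams(q=fit.slope, e0=e_fit.prefactor, beta_e=e_fit.exponent)
    logger.info(
        "q=%.4g (95%% CI %.4g..%.4g, p=%.3g), intercept p=%.3g, dof=%d",
        fit.slope, *fit.ci95_slope, fit.p_slope, fit.p_intercept, fit.dof,
    )
    return fit, params


def predict_active(params: ContagionParams, n: float) -> float:
    """Predicted active-worker count A = sqrt(q/(2E0)) · n^((3−βE)/2)."""
    if n < 1:
        raise ValueError(f"colony size must be >= 1, got {n}")
    return math.sqrt(params.q / (2.0 * params.e0)) * n ** ((3.0 - params.beta_e) / 2.0)


def active_fraction(params: ContagionParams, n: float) -> float:
    """Predicted active fraction A/n = sqrt(q/(2E0)) · n^((1−βE)/2)."""
    return predict_active(params, n) / n


def effective_interaction_area(
    area_fit: PowerLawFit,
    e_fit: PowerLawFit,
    d: float = 6.0,
    mean_path_length: float | None = None,
) -> EffectiveInteractionArea:
    """Per-worker interaction area a = 2·Area0·E0 implied by mean-field mixing.

    If workers mixed uniformly over the spanned area, the edge count would
    be ½N²a/Area; matching E = E0·N^βE against Area = Area0·N^βArea with
    βArea ≈ 2 − βE gives a = 2·Area0·E0. For context the bounds πd²
    (complete inactivity) and 2dL (steady motion over path length L) are
    reported alongside.
    """
    if area_fit.prefactor < 0 or e_fit.prefactor < 0:
        raise ValueError("prefactors must be non-negative")
    return EffectiveInteractionArea(
        area=2.0 * area_fit.prefactor * e_fit.prefactor,
        stationary_bound=math.pi * d**2,
        steady_motion_bound=None if mean_path_length is None else 2.0 * d * mean_path_length,
    )
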