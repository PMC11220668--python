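"""Cobb–Douglas model linking activity regulation to colony metabolism.

Colony metabolic rate is treated as the output of a two-input production
function with active workers as labour and inactive workers as capital:

    B = B0 · (A*)^αB · (I*)^(1−αB),

where A* = A·N*/N rescales the tracked active count to the whole colony
and I* = N* − A*. The function is homogeneous of degree one, so the
marginal products αB·B/A* and (1−αB)·B/I* exhaust B exactly (Euler's
identity). Combining it with the contagion prediction for A yields a
closed-form metabolic rate as a function of colony size whose large-N
log-log slope, (1−βE)·αB/2 + 1, is a Kleiber-like hypometric exponent
when the interaction network scales hypermetrically (βE > 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contagion_model import ContagionParams, active_fraction
from .records import ColonyRecord, ColonySummary
from .scaling_fits import LinearFit, fit_linear

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """Model evaluated outside its validity region (predicted active fraction ≥ 1)."""


@dataclass
class CobbDouglasParams:
    """Baseline scale B0 (mW) and active-worker elasticity αB."""

    b0: float
    alpha_b: float

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be strictly positive")
        if not 0 < self.alpha_b < 1:
            logger.warning(
                "alpha_b=%.3f outside (0, 1): marginal products of one worker "
                "class are non-positive", self.alpha_b,
            )


@dataclass
class ScaledCounts:
    """Whole-colony active/inactive counts A* = A·N*/N and I* = N* − A*."""

    a_star: float
    i_star: float

    def __post_init__(self) -> None:
        if self.a_star < 0 or self.i_star < 0:
            raise ValueError("scaled counts must be non-negative")


def scale_counts(summary: ColonySummary, record: ColonyRecord) -> ScaledCounts:
    """Rescale the tracked active count to the whole colony.

    Untracked workers are assumed active in the same proportion as tracked
    ones, so they contribute to the colony's metabolic inputs.
    """
    if record.n_tracked <= 0:
        raise ValueError(f"colony {record.colony_id}: zero tracked count")
    a_star = summary.n_active * record.n_total / record.n_tracked
    if a_star > record.n_total + 1e-9:
        raise ValueError(
            f"colony {record.colony_id}: scaled active count {a_star:g} exceeds n_total"
        )
    return ScaledCounts(a_star=a_star, i_star=record.n_total - a_star)


def cobb_douglas_rate(params: CobbDouglasParams, counts: ScaledCounts) -> float:
    """Metabolic rate B0·(A*)^αB·(I*)^(1−αB) in mW."""
    return params.b0 * counts.a_star**params.alpha_b * counts.i_star ** (1.0 - params.alpha_b)


def fit_cobb_douglas(
    counts: Sequence[ScaledCounts],
    rates: Sequence[float],
) -> tuple[CobbDouglasParams, LinearFit]:
    """Fit (B0, αB) by the univariate log regression ln(B/I*) = ln B0 + αB·ln(A*/I*).

    Regressing the ratio rather than both inputs controls for the
    multicollinearity of A* and I* (they sum to N*). Colonies with a zero
    count are excluded with a warning; at least three must remain.
    """
    if len(counts) != len(rates):
        raise ValueError("counts and rates must have equal length")
    a = np.array([c.a_star for c in counts], dtype=float)
    i = np.array([c.i_star for c in counts], dtype=float)
    b = np.asarray(rates, dtype=float)
    keep = (a > 0) & (i > 0) & (b > 0)
    if keep.sum() < len(counts):
        warnings.warn(
            f"excluding {int(len(counts) - keep.sum())} colony(ies) with zero "
            "counts from the Cobb-Douglas fit",
            stacklevel=2,
        )
    a, i, b = a[keep], i[keep], b[keep]
    if a.size < 3:
        raise ValueError(f"need >= 3 usable colonies, got {a.size}")
    x = np.log(a / i)
    if np.ptp(x) == 0:
        raise ValueError("A*/I* is constant across colonies; alpha_b is unidentifiable")
    fit = fit_linear(x, np.log(b / i))
    params = CobbDouglasParams(b0=float(np.exp(fit.intercept)), alpha_b=fit.slope)
    logger.info(
        "alpha_b=%.4g (95%% CI %.4g..%.4g), B0=%.4g mW, R2=%.3f, dof=%d",
        fit.slope, *fit.ci95_slope, params.b0, fit.r2_raw, fit.dof,
    )
    return params, fit


def marginal_products(
    params: CobbDouglasParams, counts: ScaledCounts
) -> tuple[float, float]:
    """Marginal metabolic products (mW per additional worker).

    Returns (∂B/∂A*, ∂B/∂I*) = (αB·B/A*, (1−αB)·B/I*) with B the
    Cobb–Douglas rate at ``counts``.
    """
    if counts.a_star <= 0 or counts.i_star <= 0:
        raise ValueError("marginal products require strictly positive counts")
    b = cobb_douglas_rate(params, counts)
    return params.alpha_b * b / counts.a_star, (1.0 - params.alpha_b) * b / counts.i_star


def predict_metabolic_rate(
    cd: CobbDouglasParams,
    cg: ContagionParams,
    n: float,
    n_total: float,
) -> float:
    """End-to-end metabolic prediction from colony size alone:

        B = B0·N*·(q/(2E0))^(αB/2) · N^((1−βE)·αB/2)
              · (1 − sqrt(q/(2E0))·N^((1−βE)/2))^(1−αB).

    Equivalent to evaluating the Cobb–Douglas function at the scaled
    counts implied by the contagion prediction for A. Invalid (raises
    :class:`DomainError`) when the predicted active fraction reaches 1,
    which happens for colonies smaller than (2E0/q)^(1/(1−βE)).
    """
    if n < 1 or n_total < 1:
        raise ValueError("colony sizes must be >= 1")
    f = active_fraction(cg, n)
    if f >= 1.0:
        raise DomainError(
            f"predicted active fraction {f:.3f} >= 1 at n={n:g}; the balance "
            "model does not apply to colonies this small"
        )
    root = np.sqrt(cg.q / (2.0 * cg.e0))
    return float(
        cd.b0
        * n_total
        * root**cd.alpha_b
        * n ** ((1.0 - cg.beta_e) * cd.alpha_b / 2.0)
        * (1.0 - root * n ** ((1.0 - cg.beta_e) / 2.0)) ** (1.0 - cd.alpha_b)
    )


def derived_exponent(cg: ContagionParams, cd: CobbDouglasParams) -> float:
    """Predicted large-N scaling exponent of B versus colony mass.

    With M ∝ N and N*/N constant, B ∝ M^((1−βE)·αB/2 + 1); βE = 1
    (isometric interactions) recovers B ∝ M.
    """
    return (1.0 - cg.beta_e) * cd.alpha_b / 2.0 + 1.0
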