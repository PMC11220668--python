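"""Power-law and linear regression with the study's reporting conventions.

Scaling laws Y = Y0·Xᵝ are estimated by ordinary least squares on
natural-log-transformed variables, with the coefficient of determination
computed on the log residuals; plain linear relations are fitted on raw
variables with R² computed accordingly. Confidence intervals and p-values
come from the t distribution with n − 2 residual degrees of freedom
(14 for a 16-colony design).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class PowerLawFit:
    """OLS fit of ln y on ln x: y = prefactor · x^exponent."""

    exponent: float
    prefactor: float
    ci95_exponent: tuple[float, float]
    r2_log: float
    p_slope: float
    p_intercept: float
    dof: int
    n_used: int


@dataclass
class LinearFit:
    """OLS fit on raw variables: y = slope·x + intercept."""

    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    r2_raw: float
    p_slope: float
    p_intercept: float
    dof: int
    n_used: int


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y = Y0·xᵝ by OLS on (ln x, ln y).

    Non-positive (x, y) pairs are excluded with a warning; at least three
    positive pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = (x > 0) & (y > 0)
    if keep.sum() < x.size:
        warnings.warn(
            f"excluding {int(x.size - keep.sum())} non-positive point(s) from log-space fit",
            stacklevel=2,
        )
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 positive points for a power-law fit, got {x.size}")
    res = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
    ci = res.conf_int(alpha=0.05)
    return PowerLawFit(
        exponent=float(res.params[1]),
        prefactor=float(np.exp(res.params[0])),
        ci95_exponent=(float(ci[1, 0]), float(ci[1, 1])),
        r2_log=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        p_intercept=float(res.pvalues[0]),
        dof=int(res.df_resid),
        n_used=int(x.size),
    )


def fit_linear(x, y, force_zero_intercept: bool = False) -> LinearFit:
    """Fit y = a·x + b (or y = a·x) by OLS on raw variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points for a linear fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is unidentifiable")
    if force_zero_intercept:
        res = sm.OLS(y, x[:, None]).fit()
        ci = res.conf_int(alpha=0.05)
        return LinearFit(
            slope=float(res.params[0]),
            intercept=0.0,
            ci95_slope=(float(ci[0, 0]), float(ci[0, 1])),
            r2_raw=float(res.rsquared),
            p_slope=float(res.pvalues[0]),
            p_intercept=float("nan"),
            dof=int(res.df_resid),
            n_used=int(x.size),
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        r2_raw=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        p_intercept=float(res.pvalues[0]),
        dof=int(res.df_resid),
        n_used=int(x.size),
    )


def prediction_r2(observed, predicted, log_scale: bool = False) -> float:
    """R² of a model prediction against observations: 1 − SS_res/SS_tot.

    Computed on raw values, or on natural logs when ``log_scale`` is set
    (all values must then be positive). Can be negative when the
    prediction is worse than the observed mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need >= 2 points")
    if log_scale:
        if np.any(obs <= 0) or np.any(pred <= 0):
            raise ValueError("log-scale R² requires strictly positive values")
        obs, pred = np.log(obs), np.log(pred)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def fit_to_dict(fit: PowerLawFit | LinearFit) -> dict:
    """JSON-serialisable view of a fit result."""
    d = asdict(fit)
    d["kind"] = type(fit).__name__
    return d


def save_fits(fits: dict[str, PowerLawFit | LinearFit], path: str | Path) -> None:
    """Serialise a named collection of fits to JSON."""
    payload = {name: fit_to_dict(f) for name, f in fits.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_fits(path: str | Path) -> dict[str, PowerLawFit | LinearFit]:
    """Load fits written by :func:`save_fits`."""
    payload = json.loads(Path(path).read_text())
    out: dict[str, PowerLawFit | LinearFit] = {}
    for name, d in payload.items():
        kind = d.pop("kind")
        if kind == "PowerLawFit":
            d["ci95_exponent"] = tuple(d["ci95_exponent"])
            out[name] = PowerLawFit(**d)
        else:
            d["ci95_slope"] = tuple(d["ci95_slope"])
            out[name] = LinearFit(**d)
    return out
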