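"""Marginal trajectories, decline contrasts and minimum detectable effects.

Predictions are marginal in the Stata ``margins`` sense: the fitted
fixed-effect design is evaluated at a requested time and group for every
analysis row's observed covariate vector (and aget0), and averaged.
Window changes (default four years before to eight years after the
origin, the median follow-up spans) are linear functionals L'beta of the
fixed effects, so standard errors follow from the delta method,
``sqrt(L' V L)``, using the mixed-model fixed-effect covariance V.
The minimum detectable effect size (MDES) converts the standard error of
the between-group post-window contrast into the smallest true difference
detectable at a given two-sided alpha and power:
``MDES = (z_{1-alpha/2} + z_{power}) * SE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CetrajError, SpecificationError
from .model import PiecewiseLinearMixedModel

Z95 = 1.959964  # two-sided 95% normal quantile


def _check_fitted(model: PiecewiseLinearMixedModel) -> None:
    if not hasattr(model, "fit_"):
        raise CetrajError("model is not fitted")


def marginal_trajectory(model: PiecewiseLinearMixedModel, group: int, times) -> np.ndarray:
    """Marginal predicted score at each time, averaged over observed covariates."""
    _check_fitted(model)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise CetrajError("time grid is empty")
    beta = model.fit_.params.to_numpy()
    return np.array([model.marginal_design(t, group).mean(axis=0) @ beta for t in times])


def contrast_vector(
    model: PiecewiseLinearMixedModel, t1: float, t2: float, group: int, at_aget0: float | None = None
) -> np.ndarray:
    """L such that L'beta is the marginal change from t1 to t2 for a group.

    By default every row keeps its observed aget0 (so the contrast is at
    the sample-average age at exposure); ``at_aget0`` evaluates the
    change at a chosen age at exposure instead.
    """
    _check_fitted(model)
    return (
        model.marginal_design(t2, group, at_aget0).mean(axis=0)
        - model.marginal_design(t1, group, at_aget0).mean(axis=0)
    )


def _estimate(L: np.ndarray, beta: np.ndarray, V: np.ndarray) -> dict:
    est = float(L @ beta)
    se = float(np.sqrt(L @ V @ L))
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - Z95 * se,
        "ci_high": est + Z95 * se,
        "p": float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else float(est == 0.0),
    }


@dataclass
class MarginalContrast:
    """Pre/post window changes per group, their differences and the MDES."""

    outcome: str
    pre_window: float
    post_window: float
    exposed: dict = field(default_factory=dict)  # {"pre": {...}, "post": {...}}
    control: dict = field(default_factory=dict)
    difference: dict = field(default_factory=dict)  # exposed change - control change
    mdes: float = float("nan")
    mdes_se: float = float("nan")
    mdes_multiplier: float = float("nan")
    mdes_alpha: float = 0.05
    mdes_power: float = 0.80
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "pre_window": self.pre_window,
            "post_window": self.post_window,
            "exposed": self.exposed,
            "control": self.control,
            "difference": self.difference,
            "mdes": self.mdes,
            "mdes_se": self.mdes_se,
            "mdes_multiplier": self.mdes_multiplier,
            "mdes_alpha": self.mdes_alpha,
            "mdes_power": self.mdes_power,
            "extrapolated": self.extrapolated,
        }


def mdes_multiplier(alpha: float = 0.05, power: float = 0.80) -> float:
    """z_{1-alpha/2} + z_{power} (two-sided, normal approximation)."""
    return float(stats.norm.isf(alpha / 2) + stats.norm.ppf(power))


def decline_contrast(
    model: PiecewiseLinearMixedModel,
    pre_window: float = 4.0,
    post_window: float = 8.0,
    alpha: float = 0.05,
    power: float = 0.80,
    at_aget0: float | None = None,
) -> MarginalContrast:
    """Marginal pre- and post-origin changes, group differences and MDES.

    Pre change is the marginal prediction difference from ``-pre_window``
    to 0; post change from 0 to ``post_window``.  The between-group
    difference is exposed change minus control change.  If a window
    extends beyond the observed time support the result is still
    computed (the model extrapolates its polynomial) and flagged.
    """
    _check_fitted(model)
    beta = model.fit_.params.to_numpy()
    V = model.fit_.cov_params.to_numpy()
    tmin = float(model.X_["pre_time"].min())
    tmax = float(model.X_["post_time"].max())
    extrapolated = (-pre_window < tmin) or (post_window > tmax)

    out = MarginalContrast(
        outcome=model.fit_.outcome, pre_window=pre_window, post_window=post_window, extrapolated=extrapolated
    )
    L = {}
    for grp, name in ((1, "exposed"), (0, "control")):
        L[name, "pre"] = contrast_vector(model, -pre_window, 0.0, grp, at_aget0)
        L[name, "post"] = contrast_vector(model, 0.0, post_window, grp, at_aget0)
        getattr(out, name)["pre"] = _estimate(L[name, "pre"], beta, V)
        getattr(out, name)["post"] = _estimate(L[name, "post"], beta, V)
    for win in ("pre", "post"):
        Ld = L["exposed", win] - L["control", win]
        out.difference[win] = _estimate(Ld, beta, V)

    mult = mdes_multiplier(alpha, power)
    se_post_diff = out.difference["post"]["se"]
    out.mdes = mult * se_post_diff
    out.mdes_se = se_post_diff
    out.mdes_multiplier = mult
    out.mdes_alpha = alpha
    out.mdes_power = power
    return out


def step_contrast(model: PiecewiseLinearMixedModel, horizon: float = 8.0) -> dict:
    """Between-group marginal score difference at t=0 (the step) and at a horizon.

    Requires a discontinuity fit (t >= 0 indicator and group interaction);
    the t=0 difference is the step itself, the horizon difference is the
    step plus the accumulated slope difference.
    """
    _check_fitted(model)
    if "disc" not in model.fit_.params.index or "group_disc" not in model.fit_.params.index:
        raise SpecificationError("step contrast requires a discontinuity fit (disc, group_disc terms)")
    beta = model.fit_.params.to_numpy()
    V = model.fit_.cov_params.to_numpy()
    out = {"horizon": float(horizon)}
    for label, t in (("at_t0", 0.0), ("at_horizon", float(horizon))):
        L = model.marginal_design(t, 1).mean(axis=0) - model.marginal_design(t, 0).mean(axis=0)
        out[label] = _estimate(L, beta, V)
    return out


def mdes(
    model: PiecewiseLinearMixedModel, post_window: float = 8.0, alpha: float = 0.05, power: float = 0.80
) -> dict:
    """MDES for the post-origin between-group change over ``post_window`` years."""
    _check_fitted(model)
    if "group_post" not in model.fit_.params.index:
        raise SpecificationError("MDES requires the group x post-time term in the model")
    beta = model.fit_.params.to_numpy()
    V = model.fit_.cov_params.to_numpy()
    L = contrast_vector(model, 0.0, post_window, 1) - contrast_vector(model, 0.0, post_window, 0)
    se = float(np.sqrt(L @ V @ L))
    mult = mdes_multiplier(alpha, power)
    return {
        "mdes": mult * se,
        "se": se,
        "multiplier": mult,
        "alpha": alpha,
        "power": power,
        "post_window": post_window,
    }
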