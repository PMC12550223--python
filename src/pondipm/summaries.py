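"""Scenario-effect summaries of simulation output.

Simulation responses (lambda, K, 100-year size, percent of K, persistence)
are regressed on the two scenario treatments — hydroperiod (days) and
initial hybrid proportion — with the parameter-draw index as a grouping
term, because all scenarios sharing one draw share its coefficients.
Log-scale responses are shifted by the smallest positive observed value
before the natural log so collapsed runs (zeros) remain in the model.

Headline comparisons use two derived statistics:

* percent change per c units of a predictor, (e^{c beta} - 1) x 100%;
* the ratio of standardized slopes beta1/beta2, comparing the relative
  influence of two predictors after scaling each to unit SD over the design
  values actually simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FittingError

__all__ = [
    "EffectEstimate",
    "log_shift_transform",
    "fit_effect_model",
    "percent_change_per_unit",
    "scaled_effect_ratio",
    "effects_to_frame",
]

PREDICTORS = ("hydroperiod_days", "prop_hybrid")


@dataclass
class EffectEstimate:
    """One predictor's slope in a scenario-effect model."""

    response: str
    predictor: str
    beta_raw: float
    beta_scaled: float
    ci_low: float
    ci_high: float
    p_value: float
    link: str
    grouped: bool = True  # False when the iteration grouping had to be dropped

    def __post_init__(self):
        if not (self.ci_low <= self.beta_raw <= self.ci_high):
            raise FittingError(
                f"inconsistent interval for {self.response}~{self.predictor}: "
                f"[{self.ci_low}, {self.ci_high}] does not bracket {self.beta_raw}"
            )


def log_shift_transform(values) -> np.ndarray:
    """ln(y + min positive y): defined at zero, monotone, order-preserving."""
    y = np.asarray(values, dtype=float)
    if np.any(y < 0):
        raise ValueError("log_shift_transform requires values >= 0")
    positive = y[y > 0]
    if positive.size == 0:
        raise ValueError("log_shift_transform requires at least one positive value")
    return np.log(y + positive.min())


def fit_effect_model(
    rows: pd.DataFrame,
    response_kind: str,
    link: str = "log",
) -> list[EffectEstimate]:
    """Fit the scenario-effect model and return one estimate per predictor.

    ``rows`` needs columns ``value``, ``hydroperiod_days``, ``prop_hybrid``,
    ``iteration_id``.  With ``link='log'`` the response is log-shift
    transformed and fit by a linear mixed model with a random intercept per
    iteration (falling back to fixed iteration effects if the mixed fit
    fails).  With ``link='logit'`` the 0/1 response is fit by logistic
    regression with iteration fixed effects, dropping the grouping (flagged)
    under complete separation.

    Standardized slopes multiply the raw slope by the SD of the design
    values present in ``rows`` (scaling reflects the simulated design, not
    field variation).
    """
    import statsmodels.api as sm

    needed = {"value", "hydroperiod_days", "prop_hybrid", "iteration_id"}
    missing = needed - set(rows.columns)
    if missing:
        raise ConfigurationError(f"effect-model rows missing columns: {sorted(missing)}")
    if rows["iteration_id"].nunique() < 2:
        raise FittingError("need >= 2 iterations for the grouping term")
    for pred in PREDICTORS:
        if rows[pred].nunique() < 2:
            raise FittingError(f"predictor {pred} has a single design level")

    X = sm.add_constant(rows[list(PREDICTORS)].astype(float))
    grouped = True

    if link == "log":
        y = log_shift_transform(rows["value"].to_numpy())
        params = ci = pvals = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = sm.MixedLM(y, X, groups=rows["iteration_id"]).fit(reml=True)
            if np.all(np.isfinite(mixed.bse[list(PREDICTORS)])):
                params = mixed.params
                ci = mixed.conf_int()
                pvals = mixed.pvalues
        except (np.linalg.LinAlgError, ValueError):
            params = None
        if params is None:  # fixed-effects fallback with iteration dummies
            grouped = False
            dummies = pd.get_dummies(rows["iteration_id"], prefix="it", drop_first=True, dtype=float)
            Xd = pd.concat([X, dummies.set_index(X.index)], axis=1)
            ols = sm.OLS(y, Xd).fit()
            params, ci, pvals = ols.params, ols.conf_int(), ols.pvalues
    elif link == "logit":
        y = rows["value"].astype(float).to_numpy()
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ConfigurationError("logit link requires a 0/1 response")
        dummies = pd.get_dummies(rows["iteration_id"], prefix="it", drop_first=True, dtype=float)
        Xd = pd.concat([X, dummies.set_index(X.index)], axis=1)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse[list(PREDICTORS)])):
                raise FittingError("non-finite standard errors")
            params, ci, pvals = fit.params, fit.conf_int(), fit.pvalues
        except Exception:
            # complete separation within iteration cells: drop the grouping
            grouped = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, ci, pvals = fit.params, fit.conf_int(), fit.pvalues
    else:
        raise ConfigurationError(f"unknown link {link!r} (use 'log' or 'logit')")

    ci = pd.DataFrame(np.asarray(ci), index=params.index, columns=["low", "high"])
    estimates = []
    for pred in PREDICTORS:
        sd = float(rows[pred].astype(float).std(ddof=1))
        beta = float(params[pred])
        estimates.append(
            EffectEstimate(
                response=response_kind,
                predictor=pred,
                beta_raw=beta,
                beta_scaled=beta * sd,
                ci_low=float(ci.loc[pred, "low"]),
                ci_high=float(ci.loc[pred, "high"]),
                p_value=float(pvals[pred]),
                link=link,
                grouped=grouped,
            )
        )
    return estimates


def percent_change_per_unit(beta_raw: float, c: float) -> float:
    """Percent change in y per c-unit change of the predictor: (e^{c beta}-1)*100."""
    return float((np.exp(c * beta_raw) - 1.0) * 100.0)


def scaled_effect_ratio(beta_scaled_1: float, beta_scaled_2: float) -> float:
    """Relative influence of two predictors as the ratio of standardized slopes."""
    if beta_scaled_2 == 0:
        raise ConfigurationError("scaled_effect_ratio undefined for a zero denominator")
    return float(beta_scaled_1 / beta_scaled_2)


def effects_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "response": e.response,
                "predictor": e.predictor,
                "beta_raw": e.beta_raw,
                "beta_scaled": e.beta_scaled,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "link": e.link,
                "grouped": e.grouped,
            }
            for e in estimates
        ]
    )
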