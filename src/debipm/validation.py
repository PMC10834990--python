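"""Observed-versus-predicted validation statistics.

Model predictions (generation time, longevity = L_alpha + L_omega, age
at maturity, all in years) are compared to caller-supplied observed
values with a linear regression through the origin, y ~ x with y the
prediction and x the observation.  A regression coefficient whose 95%
confidence interval (coefficient +/- 2 standard errors) overlaps 1 means
predictions do not significantly differ from observations.  The root
mean square error summarises the spread; dividing the RMSE by the
largest observed value gives a dimensionless error rate, and +/- 2*RMSE
is the band expected to contain 95% of observations under Gaussian
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ipm import DEFAULT_N_BINS, build_kernels, core_demography
from .kernels import Environment
from .life_history import derived_traits
from .perturb import feasibility
from .traits import TraitTable

__all__ = [
    "PairedSeries",
    "RegressionResult",
    "regression_no_intercept",
    "error_rate",
    "coverage_band",
    "preprocess_observation",
    "predict_validation_traits",
    "validate_against_observations",
]

#: Names of the traits the validation workflow compares.
VALIDATION_TRAITS = ("generation_time", "longevity", "age_at_maturity")


@dataclass
class PairedSeries:
    """Observed/predicted value pairs (years) with species labels."""

    observed: np.ndarray
    predicted: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.observed) != len(self.predicted):
            raise ValueError("observed and predicted must have equal length")


@dataclass
class RegressionResult:
    slope: float
    se: float
    ci_low: float
    ci_high: float
    rmse: float
    r2: float
    r2_origin: float
    n: int


def regression_no_intercept(p: PairedSeries) -> RegressionResult:
    """Fit predicted ~ observed through the origin.

    slope = sum(xy)/sum(x^2); its standard error uses the residual
    variance with n-1 degrees of freedom (one fitted parameter); the
    95% CI is slope +/- 2*se.  Two R^2 conventions are reported: ``r2``
    takes total sum of squares about the mean of y (the convention whose
    small values at near-unit slopes match reported validation tables),
    ``r2_origin`` about zero.
    """
    x, y = p.observed, p.predicted
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(x, 0.0):
        raise ValueError("degenerate regressor: all observed values zero")
    fit = sm.OLS(y, x[:, np.newaxis]).fit()
    slope = float(fit.params[0])
    se = float(fit.bse[0])
    resid = y - slope * x
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_res = float((resid ** 2).sum())
    ss_tot_mean = float(((y - y.mean()) ** 2).sum())
    ss_tot_zero = float((y ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot_mean if ss_tot_mean > 0 else np.nan
    r2_origin = 1.0 - ss_res / ss_tot_zero if ss_tot_zero > 0 else np.nan
    return RegressionResult(slope=slope, se=se, ci_low=slope - 2.0 * se,
                            ci_high=slope + 2.0 * se, rmse=rmse, r2=r2,
                            r2_origin=r2_origin, n=len(x))


def error_rate(rmse: float, max_observed: float) -> float:
    """RMSE as a fraction of the largest observed value."""
    if max_observed <= 0:
        raise ValueError("max_observed must be > 0")
    return rmse / max_observed


def coverage_band(rmse: float) -> float:
    """Half-width (2*RMSE) of the nominal 95% observation band."""
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    return 2.0 * rmse


def preprocess_observation(values, kind: str = "series") -> float:
    """Collapse a raw observation to one number.

    ``kind="range"`` takes the median of a reported value range;
    ``kind="series"`` the mean of a series of observations.
    """
    values = np.asarray(values, dtype=float)
    if kind == "range":
        return float(np.median(values))
    if kind == "series":
        return float(np.mean(values))
    raise ValueError(f"unknown kind {kind!r}")


def predict_validation_traits(table: TraitTable, env: Environment,
                              n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Predicted generation time, longevity and age at maturity per species.

    Infeasible species at this feeding level appear with ``feasible``
    False and NaN predictions (they are excluded from, and counted by,
    the regression step).
    """
    rows = []
    for t in table.valid_records:
        ok, reason = feasibility(t, env)
        row = {"record_id": t.record_id, "E_Y": env.E_Y, "feasible": ok,
               "generation_time": np.nan, "longevity": np.nan,
               "age_at_maturity": np.nan}
        if ok:
            k = build_kernels(t, env, n_bins)
            res = derived_traits(k)
            row.update(generation_time=res.T,
                       longevity=res.L_alpha + res.L_omega,
                       age_at_maturity=res.L_alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def validate_against_observations(table: TraitTable, observations: pd.DataFrame,
                                  E_Y: float, sigma_Y: float = 0.1,
                                  n_bins: int = DEFAULT_N_BINS):
    """Per-trait no-intercept regressions of predictions on observations.

    ``observations`` has columns record_id, trait_name, observed_value
    with trait_name in {generation_time, longevity, age_at_maturity};
    observed values are always caller-supplied, never fetched.  Returns
    (dict trait -> RegressionResult, number of infeasible species).
    Raises if fewer than 3 feasible pairs exist for every trait.
    """
    env = Environment(E_Y=E_Y, sigma_Y=sigma_Y)
    pred = predict_validation_traits(table, env, n_bins=n_bins)
    n_excluded = int((~pred["feasible"]).sum())
    merged = pred.merge(observations, on="record_id")
    results: dict[str, RegressionResult] = {}
    for trait in VALIDATION_TRAITS:
        sub = merged[(merged["trait_name"] == trait) & merged["feasible"]]
        sub = sub[np.isfinite(sub[trait]) & np.isfinite(sub["observed_value"])]
        if len(sub) < 3:
            continue
        results[trait] = regression_no_intercept(PairedSeries(
            observed=sub["observed_value"].to_numpy(),
            predicted=sub[trait].to_numpy(),
            labels=list(sub["record_id"])))
    if not results:
        raise ValueError("fewer than 3 feasible observation pairs for every trait")
    return results, n_excluded
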