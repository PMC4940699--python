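"""Multiple imputation by chained equations for the predictor table.

Variable-by-variable conditional imputation: each incomplete variable is
regressed on all others, the fit is perturbed with a draw from its
approximate posterior, and missing cells are filled — by predictive mean
matching (5 donors by default) for continuous variables, or a Bernoulli
draw from a logistic fit for binary variables. Cycling through all
incomplete variables a configurable number of times yields one completed
dataset; the whole process is repeated independently for each imputation.

Downstream validation metrics are computed per completed dataset and
averaged (:func:`pool_metric`); bootstrap confidence intervals come from
the first completed dataset. Rubin's-rules variance pooling is out of
scope, since interval estimates here come from the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = ["ImputationConfig", "impute", "pool_metric"]


@dataclass
class ImputationConfig:
    n_imputations: int = 10
    n_cycles: int = 10
    families: dict = field(default_factory=dict)  # column -> linear|logistic|pmm
    pmm: bool = True
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_imputations < 1 or self.n_cycles < 1:
            raise ValueError("n_imputations and n_cycles must be >= 1")


def _infer_family(observed: pd.Series) -> str:
    values = set(np.unique(observed.to_numpy(dtype=float)))
    if values <= {0.0, 1.0}:
        return "logistic"
    return "linear"


def _posterior_beta(fit, rng):
    cov = np.asarray(fit.cov_params())
    beta = np.asarray(fit.params, dtype=float)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        return beta
    return beta + chol @ rng.standard_normal(len(beta))


def _impute_linear(X_obs, y_obs, X_mis, rng, config):
    Xo = sm.add_constant(X_obs, has_constant="add")
    Xm = sm.add_constant(X_mis, has_constant="add")
    fit = sm.OLS(y_obs, Xo).fit()
    n, p = Xo.shape
    dof = max(n - p, 1)
    sigma2_hat = max(fit.ssr / dof, 1e-12)
    sigma2 = fit.ssr / rng.chisquare(dof)  # scaled inverse-chi-square draw
    beta_hat = np.asarray(fit.params)
    beta_star = beta_hat + np.sqrt(sigma2 / sigma2_hat) * (
        _posterior_beta(fit, rng) - beta_hat
    )
    pred_mis = Xm @ beta_star
    if not config.pmm:
        return pred_mis + rng.normal(0.0, np.sqrt(sigma2), len(pred_mis))
    # predictive mean matching: donors are observed rows nearest in
    # predicted mean (observed means from the unperturbed fit)
    pred_obs = Xo @ np.asarray(fit.params)
    k = min(config.pmm_donors, len(y_obs))
    out = np.empty(len(pred_mis))
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    for i, value in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, value)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        window = order[lo:hi]
        nearest = window[np.argsort(np.abs(pred_obs[window] - value), kind="stable")[:k]]
        out[i] = y_obs[rng.choice(nearest)]
    return out


def _impute_logistic(X_obs, y_obs, X_mis, rng):
    Xo = sm.add_constant(X_obs, has_constant="add")
    Xm = sm.add_constant(X_mis, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y_obs, Xo, family=sm.families.Binomial()).fit(maxiter=50)
    if not np.isfinite(np.asarray(fit.params)).all():
        raise np.linalg.LinAlgError("logistic fit diverged")
    beta_star = _posterior_beta(fit, rng)
    p_mis = expit(Xm @ beta_star)
    return (rng.random(len(p_mis)) < p_mis).astype(float)


def impute(table: pd.DataFrame, config: ImputationConfig | None = None,
           columns: list[str] | None = None) -> list[pd.DataFrame]:
    """Return ``n_imputations`` completed copies of ``table``.

    Only numeric columns participate; ``columns`` restricts which variables
    are imputed and used as predictors (default: all numeric columns).
    Observed cells are never altered. A column that is entirely missing is
    an error; a conditional fit that fails falls back to an unconditional
    draw from the observed values, with a warning.
    """
    config = config or ImputationConfig()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    work = table[columns].astype(float)
    missing_mask = work.isna()
    incomplete = [c for c in columns if missing_mask[c].any()]
    for column in incomplete:
        if missing_mask[column].all():
            raise ValueError(f"column {column!r} is entirely missing; cannot impute")
    if not any((~missing_mask[c]).all() for c in columns):
        raise ValueError("at least one fully observed column is required")

    completed: list[pd.DataFrame] = []
    for m in range(config.n_imputations):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(int(config.seed), 70, m))
        )
        filled = work.copy()
        for column in incomplete:  # initialize from the observed margins
            observed = work[column].dropna().to_numpy()
            filled.loc[missing_mask[column], column] = rng.choice(
                observed, size=int(missing_mask[column].sum())
            )
        for _ in range(config.n_cycles if incomplete else 0):
            for column in incomplete:
                others = [c for c in columns if c != column]
                obs = ~missing_mask[column]
                X_obs = filled.loc[obs, others].to_numpy()
                y_obs = work.loc[obs, column].to_numpy()
                X_mis = filled.loc[~obs, others].to_numpy()
                family = config.families.get(
                    column, _infer_family(work[column].dropna())
                )
                try:
                    if family == "logistic":
                        values = _impute_logistic(X_obs, y_obs, X_mis, rng)
                    else:
                        values = _impute_linear(X_obs, y_obs, X_mis, rng, config)
                except (np.linalg.LinAlgError, ValueError):
                    warnings.warn(
                        f"conditional fit for {column!r} failed; "
                        "falling back to unconditional draws"
                    )
                    values = rng.choice(y_obs, size=int((~obs).sum()))
                filled.loc[~obs, column] = values
        out = table.copy()
        out[columns] = filled
        completed.append(out)
    return completed


def pool_metric(values) -> float:
    """Arithmetic mean of a metric across completed datasets."""
    values = list(values)
    if not values:
        raise ValueError("pool_metric needs at least one value")
    return float(np.mean(values))
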