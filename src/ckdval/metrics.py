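"""Validation surface for one set of predictions against one cohort.

Discrimination (AUC, Harrell's c), calibration (MAPE, calibration slope,
grouped calibration bins), classification thresholds (Youden's J, PPV /
sensitivity / specificity), case-mix diagnostics (mean linear predictor,
development vs validation), decision-curve analysis (net benefit over a
threshold-probability grid) and top-decile case capture — with percentile
bootstrap confidence intervals.

Throughout, classification at a threshold t labels ``value >= t`` positive,
for probabilities and integer scores alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

__all__ = [
    "SingleClassError",
    "auc_roc",
    "harrell_c",
    "bootstrap_ci",
    "bootstrap_sd",
    "mape",
    "calibration_slope",
    "calibration_bins",
    "youden_threshold",
    "threshold_metrics",
    "net_benefit",
    "decision_curve",
    "top_decile_capture",
    "case_mix_compare",
    "ValidationReport",
]


class SingleClassError(ValueError):
    """A metric needing both outcome classes saw only one."""


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be coded 0/1")
    if y.min() == y.max():
        raise SingleClassError("both outcome classes are required")
    return y


def auc_roc(p, y) -> float:
    """Area under the ROC curve — the probability a random case outranks a
    random control, ties counted 1/2 (Mann-Whitney form)."""
    y = _check_binary(y)
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def harrell_c(lp, time, event) -> float:
    """Harrell's concordance index for a risk score against censored
    follow-up: concordant / comparable over usable pairs, where a pair is
    comparable iff the earlier time is an event; score ties count 1/2.

    Higher ``lp`` must mean higher risk (shorter time to event).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    lp = np.asarray(lp, dtype=float)
    if event.sum() == 0:
        raise SingleClassError("no events: no comparable pairs for the c-index")
    # concordance_index is oriented for predictions that increase with
    # survival time, so negate the risk score.
    return float(concordance_index(time, -lp, event_observed=event))


def mape(p, y) -> tuple[float, float]:
    """Mean absolute prediction error |p - y| and its SD across patients."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    err = np.abs(p - y)
    return float(err.mean()), float(err.std(ddof=1)) if err.size > 1 else 0.0


def bootstrap_ci(
    metric: Callable[..., float],
    data: Sequence[np.ndarray],
    B: int = 500,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    ``data`` is a tuple of equal-length arrays resampled jointly; ``metric``
    is called on the resampled arrays. Resamples on which the metric is
    undefined (single outcome class) are redrawn.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    stats = _bootstrap_distribution(metric, data, B, seed, max_redraws)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(stats, alpha)),
        float(np.quantile(stats, 1.0 - alpha)),
    )


def bootstrap_sd(
    metric: Callable[..., float],
    data: Sequence[np.ndarray],
    B: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap standard error of a metric (SD of its resampling
    distribution), used where tables report "(SD)" for a derived quantity."""
    stats = _bootstrap_distribution(metric, data, B, seed, 1000)
    return float(np.std(stats, ddof=1))


def _bootstrap_distribution(metric, data, B, seed, max_redraws):
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("bootstrap arrays must share a length")
    stats = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                stats[b] = metric(*(a[idx] for a in arrays))
                break
            except SingleClassError:
                redraws += 1
                if redraws > max_redraws:
                    raise
    return stats


def calibration_slope(lp, y, return_se: bool = False):
    """Slope from the logistic recalibration fit logit P(y=1) = a + b*lp.

    ``lp`` must include the model intercept (it is the model's full linear
    predictor evaluated on the validation data; for Cox models, the log
    cumulative-hazard scale predictor). Returns (slope, lo, hi) with a Wald
    95% CI from the fit's standard error. A slope of 1 is ideal; below 1
    indicates overfitting / risk spread too wide.
    """
    y = _check_binary(y)
    lp = np.asarray(lp, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictors must be finite")
    X = sm.add_constant(lp)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes perfect separation
        raise ValueError(
            "calibration fit failed (possibly perfect separation); "
            "check for degenerate predictions"
        ) from exc
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise ValueError(
            "calibration fit did not converge to a finite slope standard error; "
            "the validation data may be perfectly separated"
        )
    if return_se:
        return slope, se
    return slope, slope - 1.96 * se, slope + 1.96 * se


def calibration_bins(p, y, groups: int = 10) -> pd.DataFrame:
    """Quantile-grouped calibration table: per risk group, mean predicted
    risk, observed event proportion and count. Heavy ties that collapse
    quantile edges merge groups with a warning."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) < groups:
        raise ValueError(f"need at least {groups} observations for {groups} groups")
    try:
        cats = pd.qcut(p, groups, duplicates="raise")
    except ValueError:
        warnings.warn("tied predicted risks collapsed some calibration groups; merging")
        cats = pd.qcut(p, groups, duplicates="drop")
    frame = pd.DataFrame({"p": p, "y": y, "bin": cats})
    out = (
        frame.groupby("bin", observed=True)
        .agg(mean_predicted=("p", "mean"), observed_rate=("y", "mean"), n=("y", "size"))
        .reset_index(drop=True)
    )
    if out.empty:  # fully tied predictions: one effective group
        out = pd.DataFrame(
            {"mean_predicted": [p.mean()], "observed_rate": [y.mean()], "n": [len(y)]}
        )
    out.insert(0, "group", np.arange(1, len(out) + 1))
    return out


def youden_threshold(values, y) -> float:
    """Threshold (among observed prediction values) maximizing Youden's
    J = sensitivity + specificity - 1, classifying >= threshold positive.
    Ties in J are broken toward the lowest threshold."""
    y = _check_binary(y)
    values = np.asarray(values, dtype=float)
    candidates = np.unique(values)
    pos = y == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    # vectorized: for each candidate t, sens = P(v >= t | y=1)
    sens = (values[pos][:, None] >= candidates[None, :]).mean(axis=0)
    fpr = (values[~pos][:, None] >= candidates[None, :]).sum(axis=0) / n_neg
    j = sens - fpr
    # tie tolerance absorbs float noise in sens/spec fractions
    best = np.flatnonzero(j >= j.max() - 1e-9)[0]  # unique() is sorted: first = lowest
    return float(candidates[best])


def threshold_metrics(values, y, threshold: float) -> dict[str, float]:
    """PPV, sensitivity and specificity of the rule ``value >= threshold``.

    PPV is NaN when nothing is predicted positive.
    """
    y = np.asarray(y, dtype=float)
    values = np.asarray(values, dtype=float)
    pred = values >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    return {
        "ppv": tp / (tp + fp) if (tp + fp) > 0 else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) > 0 else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) > 0 else float("nan"),
    }


def net_benefit(p, y, p_t: float) -> float:
    """Net benefit of treating at threshold probability p_t:
    TP/n - (FP/n) * p_t / (1 - p_t), positives being p >= p_t."""
    if not 0.0 < p_t < 1.0:
        raise ValueError(f"threshold probability must be in (0,1), got {p_t}")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    pred = p >= p_t
    tp = np.sum(pred & (y == 1)) / n
    fp = np.sum(pred & (y == 0)) / n
    return float(tp - fp * p_t / (1.0 - p_t))


def treat_all_net_benefit(prevalence: float, p_t: float) -> float:
    if not 0.0 < p_t < 1.0:
        raise ValueError(f"threshold probability must be in (0,1), got {p_t}")
    return prevalence - (1.0 - prevalence) * p_t / (1.0 - p_t)


def decision_curve(
    p, y, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Net-benefit curve over a threshold-probability grid, with the
    treat-all and treat-none reference strategies."""
    if grid is None:
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    y = np.asarray(y, dtype=float)
    prevalence = float(y.mean())
    rows = [
        {
            "p_t": float(pt),
            "net_benefit": net_benefit(p, y, pt),
            "treat_all": treat_all_net_benefit(prevalence, pt),
            "treat_none": 0.0,
        }
        for pt in grid
    ]
    return pd.DataFrame(rows)


def top_decile_capture(p, y) -> tuple[float, float]:
    """(threshold at the 90th percentile of predicted risk, proportion of
    all observed cases at or above it) — the yield of a high-risk screening
    strategy targeting the riskiest tenth of the population."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) < 10:
        raise ValueError("need at least 10 patients for a top-decile analysis")
    cases = y.sum()
    threshold = float(np.quantile(p, 0.9))
    if cases == 0:
        return threshold, float("nan")
    capture = float(np.sum((p >= threshold) & (y == 1)) / cases)
    return threshold, capture


def case_mix_compare(
    model,
    validation_covariates: pd.DataFrame,
    validation_summary=None,
    include_intercept: bool = True,
) -> dict[str, float]:
    """Transportability diagnostic: mean linear predictor in the development
    population (from its summary statistics) vs the validation population
    (from summary statistics and from individual patient data).

    A lower validation mean LP indicates a healthier case-mix than the
    development population's.
    """
    from . import models as _m

    dev_mean = _m.mean_lp_from_summary(model, include_intercept=include_intercept)
    ind_mean, ind_sd = _m.mean_lp_from_individuals(
        model, validation_covariates, include_intercept=include_intercept
    )
    out = {
        "dev_mean_lp": dev_mean,
        "val_mean_lp_individual": ind_mean,
        "val_sd_lp_individual": ind_sd,
        "difference_individual": ind_mean - dev_mean,
    }
    if validation_summary is not None:
        val_sum = _m.mean_lp_from_summary(
            model, dev=validation_summary, include_intercept=include_intercept
        )
        out["val_mean_lp_summary"] = val_sum
        out["difference_summary"] = val_sum - dev_mean
    return out


@dataclass
class ValidationReport:
    """All validation results for one model on one cohort."""

    model: str
    cohort: str
    n: int
    n_events: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    c_index: float | None = None
    c_index_ci: tuple[float, float] | None = None
    mape_mean: float | None = None
    mape_sd: float | None = None
    calibration_slope: float | None = None
    calibration_slope_ci: tuple[float, float] | None = None
    calibration_table: pd.DataFrame | None = None
    threshold_block: dict | None = None
    mean_lp_block: dict | None = None
    top_decile_threshold: float | None = None
    top_decile_capture: float | None = None
    decision_curve: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_rows(self) -> pd.DataFrame:
        """Long-format (model, cohort, metric, estimate, lo, hi) table."""
        rows = []

        def add(metric, estimate, ci=None):
            if estimate is None:
                return
            lo, hi = (ci if ci is not None else (np.nan, np.nan))
            rows.append(
                {
                    "model": self.model,
                    "cohort": self.cohort,
                    "metric": metric,
                    "estimate": estimate,
                    "lo": lo,
                    "hi": hi,
                }
            )

        add("n", self.n)
        add("n_events", self.n_events)
        add("auc", self.auc, self.auc_ci)
        add("c_index", self.c_index, self.c_index_ci)
        add("mape", self.mape_mean)
        add("mape_sd", self.mape_sd)
        add("calibration_slope", self.calibration_slope, self.calibration_slope_ci)
        if self.threshold_block:
            for key, value in self.threshold_block.items():
                add(f"threshold_{key}", value)
        if self.mean_lp_block:
            for key, value in self.mean_lp_block.items():
                add(f"case_mix_{key}", value)
        add("top_decile_threshold", self.top_decile_threshold)
        add("top_decile_capture", self.top_decile_capture)
        for key, value in self.extras.items():
            add(key, value)
        return pd.DataFrame(rows)
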