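"""Declarative representation and evaluation of published CKD risk models.

A published prediction model is captured as a :class:`ModelSpec`: a family
(logistic, Cox at a fixed horizon, or integer score), a list of terms
(predictor, transform, coefficient or points), an intercept or baseline
survival, and optionally the development population's summary statistics
(outcome prevalence, predictor means/prevalences). Everything needed to
re-apply the model to a new cohort is data, not code, so model definitions
live in YAML documents.

Conventions
-----------
* The linear predictor LP excludes the intercept; the intercept enters at
  the risk step (``predict_logistic``) or not at all (Cox, where the
  baseline survival absorbs it).
* Cox 5-year risk is ``1 - S0(h)**exp(LP - LP_bar)`` where ``LP_bar`` is the
  development-population centering constant (0 when the published baseline
  survival is uncentered).
* Development summaries are given on the *transformed* scale: the mean of
  the transformed covariate for continuous terms, the prevalence of the
  condition for binary/indicator terms. The summary-based mean linear
  predictor is then simply ``b0 + sum(beta * xbar)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Term",
    "DevelopmentSummary",
    "ModelSpec",
    "ModelConfigError",
    "load_model_spec",
    "linear_predictor",
    "predict_logistic",
    "predict_cox",
    "estimate_intercept",
    "apply_score",
    "mean_lp_from_summary",
    "mean_lp_from_individuals",
]


class ModelConfigError(ValueError):
    """Raised when a model document violates the schema."""


_TRANSFORMS = {"identity", "centered", "log", "fp", "indicator", "ge", "le", "lt", "band"}


@dataclass
class Term:
    """One additive term of a model: ``beta * transform(x)`` or score points.

    ``transform`` vocabulary:

    identity   x
    centered   x - center
    log        log(x / scale)
    fp         (x / scale) ** power - center   (power 0 means log; covers
               fractional-polynomial terms with printed powers)
    indicator  1 if x == level else 0
    ge / le / lt   1 if x >= / <= / < threshold else 0
    band       1 if lower <= x < upper else 0
    """

    predictor: str
    transform: str = "identity"
    beta: float | None = None
    points: int | None = None
    center: float = 0.0
    scale: float = 1.0
    power: float = 1.0
    level: Any = None
    threshold: float | None = None
    lower: float | None = None
    upper: float | None = None
    dropped: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ModelConfigError(
                f"unknown transform {self.transform!r} in term for {self.predictor!r}"
            )
        if self.name is None:
            self.name = self.predictor

    def design_value(self, x):
        """Evaluate transform(x); x may be scalar or array-like."""
        x = np.asarray(x, dtype=float) if self.transform != "indicator" else np.asarray(x)
        t = self.transform
        if t == "identity":
            return np.asarray(x, dtype=float)
        if t == "centered":
            return x - self.center
        if t == "log":
            return np.log(x / self.scale)
        if t == "fp":
            if self.power == 0:
                return np.log(x / self.scale) - self.center
            return (x / self.scale) ** self.power - self.center
        if t == "indicator":
            return (x == self.level).astype(float)
        if t == "ge":
            return (np.asarray(x, dtype=float) >= self.threshold).astype(float)
        if t == "le":
            return (np.asarray(x, dtype=float) <= self.threshold).astype(float)
        if t == "lt":
            return (np.asarray(x, dtype=float) < self.threshold).astype(float)
        # band
        xf = np.asarray(x, dtype=float)
        return ((xf >= self.lower) & (xf < self.upper)).astype(float)


@dataclass
class DevelopmentSummary:
    """Summary statistics of the population a model was developed on."""

    prevalence: float
    n: int | None = None
    summaries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ModelConfigError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass
class ModelSpec:
    name: str
    family: str  # logistic | cox | score
    horizon_years: float
    terms: list[Term]
    intercept: float | None = None
    baseline_survival: float | None = None
    lp_bar: float = 0.0
    development_summary: DevelopmentSummary | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "cox", "score"):
            raise ModelConfigError(f"unknown model family {self.family!r}")
        if self.family == "cox":
            if self.baseline_survival is None:
                raise ModelConfigError(
                    f"cox model {self.name!r} requires baseline_survival at horizon"
                )
            if not 0.0 < self.baseline_survival <= 1.0:
                raise ModelConfigError(
                    f"baseline_survival must be in (0,1], got {self.baseline_survival}"
                )
        if self.family == "score":
            for t in self.terms:
                if t.points is None or int(t.points) != t.points:
                    raise ModelConfigError(
                        f"score model {self.name!r}: term {t.name!r} needs integer points"
                    )
        else:
            for t in self.terms:
                if t.beta is None and not t.dropped:
                    raise ModelConfigError(
                        f"{self.family} model {self.name!r}: term {t.name!r} lacks a coefficient"
                    )

    @property
    def active_terms(self) -> list[Term]:
        return [t for t in self.terms if not t.dropped]

    @property
    def dropped_terms(self) -> list[Term]:
        return [t for t in self.terms if t.dropped]

    @property
    def predictors(self) -> list[str]:
        return sorted({t.predictor for t in self.active_terms})

    @property
    def intercept_available(self) -> bool:
        return self.intercept is not None


def _term_from_doc(doc: Mapping[str, Any]) -> Term:
    allowed = {
        "predictor", "transform", "beta", "points", "center", "scale",
        "power", "level", "threshold", "lower", "upper", "dropped", "name",
    }
    unknown = set(doc) - allowed
    if unknown:
        raise ModelConfigError(f"unknown term fields {sorted(unknown)} at terms/{doc.get('predictor')}")
    if "predictor" not in doc:
        raise ModelConfigError("term missing required field 'predictor'")
    return Term(**doc)


def load_model_spec(source: str | Path | Mapping[str, Any]) -> ModelSpec:
    """Build a validated :class:`ModelSpec` from a YAML file or mapping.

    A logistic model may omit the intercept if a development summary is
    present (the intercept is then marked "to estimate" and can be filled
    with :func:`estimate_intercept`). A Cox model must declare its baseline
    survival at the horizon.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ModelConfigError("model document must be a mapping")
    for req in ("name", "family", "horizon_years", "terms"):
        if req not in doc:
            raise ModelConfigError(f"missing required field {req!r}")
    dev = None
    if doc.get("development_summary") is not None:
        d = doc["development_summary"]
        try:
            dev = DevelopmentSummary(
                prevalence=float(d["prevalence"]),
                n=d.get("n"),
                summaries=dict(d.get("summaries", {})),
            )
        except KeyError as exc:
            raise ModelConfigError(f"development_summary missing field {exc}") from exc
    terms = [_term_from_doc(t) for t in doc["terms"]]
    spec = ModelSpec(
        name=str(doc["name"]),
        family=str(doc["family"]),
        horizon_years=float(doc["horizon_years"]),
        terms=terms,
        intercept=None if doc.get("intercept") is None else float(doc["intercept"]),
        baseline_survival=(
            None if doc.get("baseline_survival") is None else float(doc["baseline_survival"])
        ),
        lp_bar=float(doc.get("lp_bar", 0.0)),
        development_summary=dev,
        threshold=None if doc.get("threshold") is None else float(doc["threshold"]),
    )
    if spec.family == "logistic" and spec.intercept is None and spec.development_summary is None:
        raise ModelConfigError(
            f"logistic model {spec.name!r}: provide intercept or development_summary"
        )
    return spec


def _covariate(covariates, name: str):
    if isinstance(covariates, pd.DataFrame):
        if name not in covariates.columns:
            raise KeyError(name)
        col = covariates[name]
        if col.isna().any():
            bad = covariates.index[col.isna()][0]
            raise ValueError(
                f"covariate {name!r} is missing for patient {bad!r}; impute first"
            )
        return col.to_numpy()
    if name not in covariates:
        raise KeyError(name)
    value = covariates[name]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"covariate {name!r} is missing; impute first")
    return value


def linear_predictor(model: ModelSpec, covariates) -> np.ndarray | float:
    """LP = sum of beta * transform(x) over non-dropped terms (no intercept).

    ``covariates`` is a mapping (one patient) or DataFrame (one row per
    patient). Dropped terms contribute nothing. A missing covariate raises
    with the predictor (and patient, for tabular input) named.
    """
    if model.family == "score":
        raise ModelConfigError(f"model {model.name!r} is a score; use apply_score")
    is_frame = isinstance(covariates, pd.DataFrame)
    lp = np.zeros(len(covariates)) if is_frame else 0.0
    for term in model.active_terms:
        try:
            x = _covariate(covariates, term.predictor)
        except KeyError:
            raise ValueError(
                f"model {model.name!r}: covariate {term.predictor!r} not supplied"
            ) from None
        lp = lp + term.beta * term.design_value(x)
    return lp


def predict_logistic(model: ModelSpec, covariates) -> np.ndarray | float:
    """Predicted probability expit(intercept + LP)."""
    if model.family != "logistic":
        raise ModelConfigError(f"model {model.name!r} is not logistic")
    if model.intercept is None:
        raise ModelConfigError(
            f"model {model.name!r} has no intercept; estimate it with estimate_intercept"
        )
    lp = linear_predictor(model, covariates)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(model.intercept + lp)))


def predict_cox(model: ModelSpec, covariates) -> np.ndarray | float:
    """Risk at the model horizon: 1 - S0(h) ** exp(LP - LP_bar)."""
    if model.family != "cox":
        raise ModelConfigError(f"model {model.name!r} is not a Cox model")
    lp = linear_predictor(model, covariates)
    with np.errstate(over="ignore"):
        return 1.0 - model.baseline_survival ** np.exp(lp - model.lp_bar)


def predict_risk(model: ModelSpec, covariates) -> np.ndarray | float:
    """Family dispatch: logistic or Cox predicted risk."""
    if model.family == "logistic":
        return predict_logistic(model, covariates)
    return predict_cox(model, covariates)


def apply_score(model: ModelSpec, covariates) -> np.ndarray | int:
    """Sum of integer points over satisfied (non-dropped) conditions."""
    if model.family != "score":
        raise ModelConfigError(f"model {model.name!r} is not a score")
    is_frame = isinstance(covariates, pd.DataFrame)
    total = np.zeros(len(covariates)) if is_frame else 0.0
    for term in model.active_terms:
        try:
            x = _covariate(covariates, term.predictor)
        except KeyError:
            raise ValueError(
                f"score {model.name!r}: covariate {term.predictor!r} not supplied"
            ) from None
        total = total + term.points * term.design_value(x)
    if is_frame:
        return np.rint(total).astype(int)
    return int(round(total))


def _summary_value(term: Term, dev: DevelopmentSummary, model_name: str) -> float:
    key = term.name if term.name in dev.summaries else term.predictor
    if key not in dev.summaries:
        raise ModelConfigError(
            f"model {model_name!r}: development summary lacks {term.name!r}"
        )
    return float(dev.summaries[key])


def estimate_intercept(model: ModelSpec, dev: DevelopmentSummary | None = None) -> float:
    """Reconstruct a logistic intercept from development summary statistics.

    b0 = logit(pi) - sum(beta * xbar), the mean-covariate approximation used
    when a publication reports coefficients, outcome prevalence and
    predictor summaries but not the intercept itself.
    """
    if dev is None:
        dev = model.development_summary
    if dev is None:
        raise ModelConfigError(f"model {model.name!r} has no development summary")
    offset = sum(t.beta * _summary_value(t, dev, model.name) for t in model.active_terms)
    return math.log(dev.prevalence / (1.0 - dev.prevalence)) - offset


def with_estimated_intercept(model: ModelSpec) -> ModelSpec:
    """Copy of a logistic model with its intercept filled from the summary."""
    from dataclasses import replace

    return replace(model, intercept=estimate_intercept(model))


def mean_lp_from_summary(
    model: ModelSpec,
    dev: DevelopmentSummary | None = None,
    include_intercept: bool = True,
) -> float:
    """Population mean linear predictor from summary statistics alone."""
    if dev is None:
        dev = model.development_summary
    if dev is None:
        raise ModelConfigError(f"model {model.name!r} has no development summary")
    total = sum(t.beta * _summary_value(t, dev, model.name) for t in model.active_terms)
    if include_intercept:
        if model.intercept is None:
            raise ModelConfigError(
                f"model {model.name!r}: intercept unavailable for mean LP"
            )
        total += model.intercept
    return float(total)


def mean_lp_from_individuals(
    model: ModelSpec, covariates: pd.DataFrame, include_intercept: bool = True
) -> tuple[float, float]:
    """Mean and SD of the per-patient linear predictor (intercept included
    by default, mirroring how case-mix tables report it)."""
    if len(covariates) < 2:
        raise ValueError("need at least two patients for a mean and SD")
    lp = np.asarray(linear_predictor(model, covariates), dtype=float)
    if include_intercept:
        if model.family == "logistic":
            if model.intercept is None:
                raise ModelConfigError(f"model {model.name!r}: intercept unavailable")
            lp = lp + model.intercept
        # Cox models have no free intercept; LP is reported as-is.
    return float(lp.mean()), float(lp.std(ddof=1))
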