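"""Synthetic EHR cohort generator with known ground truth.

Emits raw, EHR-like event tables (demographics, dated labs, diagnostic
codes, prescriptions, vital status) for a configurable population, plus a
truth table holding each patient's generating covariates, linear predictor
and latent 5-year CKD risk. Default parameters emulate the covariate
prevalences, missingness fractions and baseline eGFR distribution of a
deprived urban UK primary-care population (~52% female, mean adult age in
the low 40s, hypertension ~14.5%, type-2 diabetes ~3.7%, baseline eGFR
83.7 +/- 9.4 mL/min/1.73 m^2, systolic blood pressure missing for ~49% of
patients, haemoglobin for ~71%, proteinuria for ~95%).

Outcomes arise mechanistically, not by fiat: a latent logistic model on the
generated covariates selects "progressors", whose linear eGFR trajectories
drift below 60 within the horizon; measurement noise, diagnostic-code lag
and code-only cases exercise both arms of the phenotyping definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import models as _models
from .phenotyping import DAYS_PER_YEAR, egfr_mdrd, egfr_ckdepi

__all__ = [
    "ConfigurationError",
    "CohortParams",
    "RawEhrBundle",
    "generate_cohort",
    "generate_from_model",
    "inject_missingness",
    "ground_truth_model",
    "write_bundle",
    "read_bundle",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


DEFAULT_COMORBIDITY_PREVALENCES = {
    "hypertension": 0.145,
    "diabetes_t1": 0.004,
    "diabetes_t2": 0.037,
    "cardiovascular": 0.078,
    "heart_failure": 0.006,
    "stroke": 0.015,
    "pvd": 0.015,
    "kidney_stones": 0.005,
    "rheumatoid_arthritis": 0.009,
    "sle": 0.001,
    "fh_kidney": 0.0002,
    "aki": 0.015,
    "prostatic_hypertrophy": 0.007,
    "haematuria": 0.021,
}

DEFAULT_MEDICATION_PREVALENCES = {
    "antihypertensive": 0.144,
    "nsaid": 0.031,
    "lithium": 0.001,
    "tacrolimus": 0.0001,
    "cyclosporin": 0.0002,
}

DEFAULT_MISSINGNESS = {
    "creatinine": 0.759,
    "haemoglobin": 0.71,
    "bmi": 0.224,
    "sbp": 0.493,
    "dbp": 0.494,
    "hdl": 0.782,
    "smoking": 0.135,
    "deprivation": 0.019,
    "ethnicity": 0.356,
}

SMOKING_LEVELS = (0, 1, 2, 3, 4)  # non, ex, light, moderate, heavy
SMOKING_PROBS = (0.484, 0.222, 0.081, 0.124, 0.089)

LAB_MOMENTS = {  # analyte -> (mean, sd, floor)
    "haemoglobin": (13.9, 1.6, 5.0),
    "bmi": (28.0, 6.1, 13.0),
    "sbp": (130.5, 16.7, 70.0),
    "dbp": (78.9, 10.2, 40.0),
    "hdl": (26.0, 7.9, 5.0),
}


@dataclass
class EgfrTrajectoryParams:
    baseline_mean: float = 83.7
    baseline_sd: float = 9.4
    slope_mean: float = -0.3        # mL/min/1.73m^2 per year, non-progressors
    slope_sd: float = 0.3
    noise_sd: float = 3.0           # measurement noise
    measurements_per_year: float = 1.2
    progressor_crossing_min: float = 0.3   # years to cross below 60
    progressor_crossing_max: float = 5.0
    code_after_crossing_rate: float = 0.6  # P(diagnostic code | sustained crossing)
    code_lag_min_days: float = 30.0
    code_lag_max_days: float = 365.0
    code_only_rate: float = 0.002          # code without lab support


@dataclass
class DeathHazardParams:
    annual_rate: float = 0.02      # at the reference age
    age_coef: float = 0.08         # log-hazard per year of age
    reference_age: float = 70.0


@dataclass
class CohortParams:
    """Full configuration of one synthetic cohort."""

    n_patients: int = 5000
    entry_start: str = "2009-04-01"
    entry_end: str = "2010-03-31"
    study_end: str = "2014-12-31"
    age_mean: float = 42.7
    age_sd: float = 17.3
    age_min: float = 18.0
    sex_fraction_female: float = 0.519
    comorbidity_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    medication_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_MEDICATION_PREVALENCES)
    )
    missingness_fractions: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    egfr_trajectory: EgfrTrajectoryParams = field(default_factory=EgfrTrajectoryParams)
    death_hazard: DeathHazardParams = field(default_factory=DeathHazardParams)
    moveout_annual_rate: float = 0.012
    diabetes_unspecified_fraction: float = 0.1
    risk_intercept: float = -3.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not pd.Timestamp(self.entry_start) <= pd.Timestamp(self.entry_end):
            raise ConfigurationError("entry window start must precede its end")
        if not pd.Timestamp(self.entry_end) < pd.Timestamp(self.study_end):
            raise ConfigurationError("entry window must precede study end")
        for name, mapping in (
            ("comorbidity_prevalences", self.comorbidity_prevalences),
            ("medication_prevalences", self.medication_prevalences),
            ("missingness_fractions", self.missingness_fractions),
        ):
            for key, value in mapping.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigurationError(f"{name}[{key!r}] = {value} not in [0,1]")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigurationError("sex_fraction_female must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "egfr_trajectory" in doc:
            doc["egfr_trajectory"] = EgfrTrajectoryParams(**doc["egfr_trajectory"])
        if "death_hazard" in doc:
            doc["death_hazard"] = DeathHazardParams(**doc["death_hazard"])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RawEhrBundle:
    """Raw event tables plus the generator's truth block.

    patients: id, birth_date, sex, ethnicity, deprivation, death_date,
    moveout_date. labs: id, date, analyte, value. codes: id, date,
    code_class. prescriptions: id, date, drug_class. truth: id, generating
    covariates, linear predictor, latent risk, progressor flag.
    """

    patients: pd.DataFrame
    labs: pd.DataFrame
    codes: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame
    entry_start: pd.Timestamp = pd.Timestamp("2009-04-01")
    entry_end: pd.Timestamp = pd.Timestamp("2010-03-31")
    study_end: pd.Timestamp = pd.Timestamp("2014-12-31")


#: generating-model coefficients: a plausible comorbidity-driven CKD risk
#: gradient (age in years, centered at 45; binary flags otherwise)
TRUTH_TERMS = (
    ("age", "centered", 45.0, 0.045),
    ("female", "identity", None, 0.10),
    ("hypertension", "identity", None, 0.65),
    ("diabetes_t1", "identity", None, 0.70),
    ("diabetes_t2", "identity", None, 0.85),
    ("cardiovascular", "identity", None, 0.45),
    ("heart_failure", "identity", None, 0.55),
    ("pvd", "identity", None, 0.35),
    ("stroke", "identity", None, 0.30),
)


def ground_truth_model(params: CohortParams | None = None) -> _models.ModelSpec:
    """The data-generating 5-year risk model as a ModelSpec, so downstream
    code can re-evaluate the truth linear predictor from covariates."""
    params = params or CohortParams()
    terms = []
    summaries = {}
    prev = params.comorbidity_prevalences
    for name, transform, center, beta in TRUTH_TERMS:
        kwargs = {"predictor": name, "transform": transform, "beta": beta}
        if transform == "centered":
            kwargs["center"] = center
        terms.append(kwargs)
        if name == "age":
            summaries[name] = params.age_mean - center
        elif name == "female":
            summaries[name] = params.sex_fraction_female
        else:
            summaries[name] = prev.get(name, 0.0)
    return _models.load_model_spec(
        {
            "name": "synthetic-truth",
            "family": "logistic",
            "horizon_years": 5.0,
            "intercept": params.risk_intercept,
            "terms": terms,
            "development_summary": {
                "prevalence": 0.037,
                "n": params.n_patients,
                "summaries": summaries,
            },
        }
    )


def _substream(seed: int, channel: int) -> np.random.Generator:
    # fixed channel numbers give per-table streams: adding a table later
    # does not perturb existing ones
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), channel)))


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < low
    return out


def _invert_egfr(egfr, age, female, formula="mdrd"):
    """Serum creatinine consistent with an eGFR value (bisection on the
    forward equation, so MDRD and CKD-EPI stay mutually consistent)."""
    func = egfr_mdrd if formula == "mdrd" else egfr_ckdepi
    if formula == "mdrd":
        # closed form: egfr = 175 * scr^-1.154 * age^-0.203 * 0.742[f]
        factor = 175.0 * np.asarray(age, dtype=float) ** -0.203
        factor = factor * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
        return (np.asarray(egfr, dtype=float) / factor) ** (-1.0 / 1.154)
    egfr = np.atleast_1d(np.asarray(egfr, dtype=float))
    age = np.broadcast_to(np.asarray(age, dtype=float), egfr.shape)
    female = np.broadcast_to(np.asarray(female, dtype=bool), egfr.shape)
    out = np.empty_like(egfr)
    for i in range(egfr.size):
        out[i] = brentq(
            lambda s: func(s, age[i], female[i]) - egfr[i], 0.05, 40.0
        )
    return out


def generate_cohort(params: CohortParams) -> RawEhrBundle:
    """Generate a raw EHR bundle: deterministic given ``params.seed``.

    Every patient receives a creatinine measurement dated at the entry
    anchor (guaranteeing an in-window record) and a longitudinal post-entry
    eGFR series; pre-entry labs, codes and prescriptions realize the
    configured prevalences and missingness fractions.
    """
    n = params.n_patients
    entry_start = pd.Timestamp(params.entry_start)
    entry_end = pd.Timestamp(params.entry_end)
    study_end = pd.Timestamp(params.study_end)
    traj = params.egfr_trajectory

    rng_demo = _substream(params.seed, 1)
    rng_codes = _substream(params.seed, 2)
    rng_rx = _substream(params.seed, 3)
    rng_labs = _substream(params.seed, 4)
    rng_outcome = _substream(params.seed, 5)
    rng_vital = _substream(params.seed, 6)

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    # entry anchors skew toward the start of the window (most patients have
    # an early in-year contact); every pre-entry event is dated before the
    # window start so the anchor is each patient's first in-window record
    window_days = (entry_end - entry_start).days
    anchor_offset = np.minimum(
        np.floor(rng_demo.exponential(60.0, n)), window_days
    ).astype(int)
    anchors = entry_start + pd.to_timedelta(anchor_offset, unit="D")

    ages = _truncated_normal(rng_demo, params.age_mean, params.age_sd, params.age_min, n)
    birth_dates = anchors - pd.to_timedelta(np.round(ages * DAYS_PER_YEAR), unit="D")
    female = rng_demo.random(n) < params.sex_fraction_female

    eth_missing = rng_demo.random(n) < params.missingness_fractions.get("ethnicity", 0.0)
    eth_draw = rng_demo.choice(["white", "other", "black"], size=n, p=[0.90, 0.09, 0.01])
    ethnicity = np.where(eth_missing, None, eth_draw)

    depr_missing = rng_demo.random(n) < params.missingness_fractions.get("deprivation", 0.0)
    deprivation = rng_demo.normal(1.6, 3.4, n)
    deprivation = np.where(depr_missing, np.nan, deprivation)

    # ---- diagnostic codes before entry -------------------------------
    flags: dict[str, np.ndarray] = {}
    code_rows: list[dict] = []
    for code_class, prevalence in params.comorbidity_prevalences.items():
        present = rng_codes.random(n) < prevalence
        flags[code_class] = present.astype(float)
        for i in np.flatnonzero(present):
            if code_class == "aki":
                # keep within ~2 years of the entry anchor (the NICE window)
                back = rng_codes.uniform(1, 350)
            else:
                adult_span = max(
                    (entry_start - (birth_dates[i] + pd.Timedelta(days=18 * 365))).days, 2
                )
                back = rng_codes.uniform(1, min(adult_span, 25 * DAYS_PER_YEAR))
            date = entry_start - pd.Timedelta(days=float(np.floor(back)))
            klass = code_class
            if code_class in ("diabetes_t1", "diabetes_t2"):
                if rng_codes.random() < params.diabetes_unspecified_fraction:
                    klass = "diabetes_unspecified"
                    # keep the date consistent with the age-35 typing rule
                    age_at = (date - birth_dates[i]).days / DAYS_PER_YEAR
                    if code_class == "diabetes_t1" and age_at >= 35:
                        date = birth_dates[i] + pd.Timedelta(
                            days=float(np.floor(rng_codes.uniform(20, 34) * DAYS_PER_YEAR))
                        )
                        date = min(date, entry_start - pd.Timedelta(days=1))
                    elif code_class == "diabetes_t2" and age_at < 35:
                        latest = (entry_start - pd.Timedelta(days=1) - birth_dates[i]).days / DAYS_PER_YEAR
                        if latest > 35:
                            date = birth_dates[i] + pd.Timedelta(
                                days=float(np.floor(rng_codes.uniform(35, latest) * DAYS_PER_YEAR))
                            )
                        else:
                            klass = code_class  # too young: keep the typed code
            code_rows.append({"id": ids[i], "date": date, "code_class": klass})

    # ---- prescriptions: two scripts in the 6 months pre-entry ---------
    # scripts must fall in the 6 months before the anchor AND before the
    # window start; patients anchored > ~6 months into the window cannot
    # carry an observable repeat prescription (as in real data)
    rx_rows: list[dict] = []
    med_flags: dict[str, np.ndarray] = {}
    for drug, prevalence in params.medication_prevalences.items():
        present = rng_rx.random(n) < prevalence
        med_flags[drug] = present.astype(float)
        for i in np.flatnonzero(present):
            room = 181 - anchor_offset[i]  # days available before entry_start
            if room < 4:
                med_flags[drug][i] = 0.0
                continue
            half = room / 2.0
            d1 = rng_rx.uniform(1, half)
            d2 = rng_rx.uniform(half + 1, room)
            for back in (d1, d2):
                rx_rows.append(
                    {
                        "id": ids[i],
                        "date": entry_start - pd.Timedelta(days=float(np.floor(back)) + 1),
                        "drug_class": drug,
                    }
                )

    # ---- latent risk and outcome mechanism ----------------------------
    truth_model = ground_truth_model(params)
    covariates = pd.DataFrame(
        {
            "id": ids,
            "age": ages,
            "female": female.astype(float),
            "hypertension": flags["hypertension"],
            "diabetes_t1": flags["diabetes_t1"],
            "diabetes_t2": flags["diabetes_t2"],
            "cardiovascular": flags["cardiovascular"],
            "heart_failure": flags["heart_failure"],
            "pvd": flags["pvd"],
            "stroke": flags["stroke"],
        }
    )
    lp = np.asarray(_models.linear_predictor(truth_model, covariates.drop(columns="id")))
    risk = expit(truth_model.intercept + lp)
    progressor = rng_outcome.random(n) < risk

    baseline = rng_outcome.normal(traj.baseline_mean, traj.baseline_sd, n)
    slope = rng_outcome.normal(traj.slope_mean, traj.slope_sd, n)
    crossing_years = rng_outcome.uniform(
        traj.progressor_crossing_min, traj.progressor_crossing_max, n
    )
    slope = np.where(progressor, (57.0 - baseline) / crossing_years, slope)

    # ---- vital status --------------------------------------------------
    hazard = params.death_hazard.annual_rate * np.exp(
        params.death_hazard.age_coef * (ages - params.death_hazard.reference_age)
    )
    t_death = rng_vital.exponential(1.0 / np.maximum(hazard, 1e-12))
    t_move = rng_vital.exponential(1.0 / max(params.moveout_annual_rate, 1e-12), n)
    max_followup = (study_end - anchors).days / DAYS_PER_YEAR
    death_dates = pd.Series([pd.NaT] * n)
    moveout_dates = pd.Series([pd.NaT] * n)
    for i in range(n):
        if t_death[i] <= max_followup[i] and t_death[i] <= t_move[i]:
            death_dates.iloc[i] = anchors[i] + pd.Timedelta(
                days=float(np.floor(t_death[i] * DAYS_PER_YEAR))
            )
        elif t_move[i] <= max_followup[i]:
            moveout_dates.iloc[i] = anchors[i] + pd.Timedelta(
                days=float(np.floor(t_move[i] * DAYS_PER_YEAR))
            )

    # ---- laboratory series ---------------------------------------------
    lab_rows: list[dict] = []
    miss = params.missingness_fractions
    gap_years = 1.0 / traj.measurements_per_year

    for i in range(n):
        anchor = anchors[i]
        end_i = min(
            [d for d in (study_end, death_dates.iloc[i], moveout_dates.iloc[i]) if not pd.isna(d)]
        )
        followup_i = max((end_i - anchor).days / DAYS_PER_YEAR, 0.0)
        age_i, female_i = ages[i], bool(female[i])

        def egfr_at(t):
            value = baseline[i] + slope[i] * t + rng_labs.normal(0.0, traj.noise_sd)
            return max(value, 8.0)

        def add_creatinine(t):
            egfr = egfr_at(t)
            scr = float(
                _invert_egfr(egfr, age_i + t, female_i, "mdrd")
            )
            lab_rows.append(
                {
                    "id": ids[i],
                    "date": anchor + pd.Timedelta(days=float(np.floor(t * DAYS_PER_YEAR))),
                    "analyte": "creatinine",
                    "value": round(scr, 3),
                }
            )

        # pre-entry labs: dated before the window start yet inside the
        # 12-month lookback from the anchor
        lab_room = 364 - anchor_offset[i]

        def pre_entry_date():
            back = np.floor(rng_labs.uniform(1, lab_room))
            return anchor - pd.Timedelta(days=float(anchor_offset[i] + back))

        if lab_room >= 3:
            if rng_labs.random() >= miss.get("creatinine", 0.0):
                back = np.floor(rng_labs.uniform(1, lab_room))
                add_creatinine(-(anchor_offset[i] + back) / DAYS_PER_YEAR)
            for analyte, (mean, sd, floor) in LAB_MOMENTS.items():
                if rng_labs.random() < miss.get(analyte, 0.0):
                    continue
                value = max(rng_labs.normal(mean, sd), floor)
                lab_rows.append(
                    {
                        "id": ids[i],
                        "date": pre_entry_date(),
                        "analyte": analyte,
                        "value": round(float(value), 2),
                    }
                )
            if rng_labs.random() >= miss.get("smoking", 0.0):
                lab_rows.append(
                    {
                        "id": ids[i],
                        "date": pre_entry_date(),
                        "analyte": "smoking",
                        "value": float(rng_labs.choice(SMOKING_LEVELS, p=SMOKING_PROBS)),
                    }
                )

        # post-entry creatinine schedule; t = 0 is the guaranteed in-window record
        t = 0.0
        while t <= followup_i:
            add_creatinine(t)
            t += gap_years * rng_labs.uniform(0.75, 1.25)

        # diagnostic-code arm of the outcome
        if progressor[i] and rng_outcome.random() < traj.code_after_crossing_rate:
            lag = rng_outcome.uniform(traj.code_lag_min_days, traj.code_lag_max_days)
            code_t = crossing_years[i] + lag / DAYS_PER_YEAR
            if code_t <= followup_i:
                code_rows.append(
                    {
                        "id": ids[i],
                        "date": anchor + pd.Timedelta(days=float(np.floor(code_t * DAYS_PER_YEAR))),
                        "code_class": "ckd_stage_3_5",
                    }
                )
        elif not progressor[i] and rng_outcome.random() < traj.code_only_rate:
            code_t = rng_outcome.uniform(0.5, 4.5)
            if code_t <= followup_i:
                code_rows.append(
                    {
                        "id": ids[i],
                        "date": anchor + pd.Timedelta(days=float(np.floor(code_t * DAYS_PER_YEAR))),
                        "code_class": "ckd_stage_3_5",
                    }
                )

    patients = pd.DataFrame(
        {
            "id": ids,
            "birth_date": birth_dates,
            "sex": np.where(female, "F", "M"),
            "ethnicity": ethnicity,
            "deprivation": np.round(deprivation, 3),
            "death_date": death_dates.to_numpy(),
            "moveout_date": moveout_dates.to_numpy(),
        }
    )
    labs = pd.DataFrame(lab_rows, columns=["id", "date", "analyte", "value"])
    codes = pd.DataFrame(code_rows, columns=["id", "date", "code_class"])
    prescriptions = pd.DataFrame(rx_rows, columns=["id", "date", "drug_class"])

    truth = covariates.copy()
    for name, values in med_flags.items():
        truth[name] = values
    truth["lp"] = lp
    truth["risk"] = risk
    truth["progressor"] = progressor.astype(int)
    truth["baseline_egfr"] = np.round(baseline, 3)
    truth["slope"] = np.round(slope, 4)
    truth["entry_anchor"] = anchors

    for frame in (labs, codes, prescriptions):
        if len(frame):
            frame.sort_values(["id", "date"], inplace=True, kind="stable")
            frame.reset_index(drop=True, inplace=True)

    return RawEhrBundle(
        patients=patients,
        labs=labs,
        codes=codes,
        prescriptions=prescriptions,
        truth=truth,
        entry_start=entry_start,
        entry_end=entry_end,
        study_end=study_end,
    )


_DIST_BUILDERS = {
    "normal": lambda rng, n, mu, sd: rng.normal(mu, sd, n),
    "lognormal": lambda rng, n, mu, sd: rng.lognormal(mu, sd, n),
    "uniform": lambda rng, n, lo, hi: rng.uniform(lo, hi, n),
    "bernoulli": lambda rng, n, p: (rng.random(n) < p).astype(float),
    "constant": lambda rng, n, v: np.full(n, float(v)),
    "choice": lambda rng, n, values, probs=None: rng.choice(values, size=n, p=probs),
}


def generate_from_model(
    model: _models.ModelSpec,
    covariate_sampler: dict,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw covariates, evaluate a logistic/Cox model on them and sample
    Bernoulli outcomes with probability exactly the model's predicted risk.

    ``covariate_sampler`` maps each model predictor to a distribution spec,
    e.g. ``{"age": ("normal", 50, 10), "diabetes": ("bernoulli", 0.1)}``.
    Returns covariates plus truth columns ``lp`` (no intercept), ``risk``
    and outcome ``y``. The workhorse for parameter-recovery simulations.
    """
    if model.family not in ("logistic", "cox"):
        raise ConfigurationError("generate_from_model needs a logistic or cox model")
    missing = [p for p in model.predictors if p not in covariate_sampler]
    if missing:
        raise ConfigurationError(f"sampler does not cover predictors: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 90)))
    data = {}
    for name, spec in covariate_sampler.items():
        kind, *args = spec
        if kind not in _DIST_BUILDERS:
            raise ConfigurationError(f"unknown distribution kind {kind!r} for {name!r}")
        data[name] = _DIST_BUILDERS[kind](rng, n, *args)
    frame = pd.DataFrame(data, index=pd.RangeIndex(n))
    lp = np.asarray(_models.linear_predictor(model, frame), dtype=float)
    risk = np.asarray(_models.predict_risk(model, frame), dtype=float)
    frame["lp"] = lp
    frame["risk"] = risk
    frame["y"] = (rng.random(n) < risk).astype(int)
    return frame


def inject_missingness(
    table: pd.DataFrame,
    fractions: dict,
    mechanism: str = "mcar",
    seed: int = 0,
    age_column: str = "age",
) -> pd.DataFrame:
    """Blank cells of the named columns at the requested marginal rates.

    ``mcar`` blanks uniformly at random; ``mar_age`` makes the blanking
    probability logistic in standardized age while preserving the marginal
    fraction (the intercept is solved numerically). Retained cells are
    untouched.
    """
    if mechanism not in ("mcar", "mar_age"):
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    for column, fraction in fractions.items():
        if column not in table.columns:
            raise ConfigurationError(f"unknown field {column!r}")
        if not 0.0 <= fraction <= 1.0:
            raise ConfigurationError(f"fraction for {column!r} not in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 91)))
    out = table.copy()
    n = len(out)
    if mechanism == "mar_age":
        if age_column not in table.columns:
            raise ConfigurationError(f"mar_age needs the {age_column!r} column")
        age = out[age_column].to_numpy(dtype=float)
        z = (age - age.mean()) / (age.std() or 1.0)
    for column, fraction in fractions.items():
        if fraction == 0.0 or n == 0:
            continue
        if mechanism == "mcar" or fraction == 1.0:
            mask = rng.random(n) < fraction
        else:
            a = brentq(lambda a_: expit(a_ + z).mean() - fraction, -40.0, 40.0)
            mask = rng.random(n) < expit(a + z)
        out.loc[mask, column] = np.nan
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O: header row, ISO-8601 dates, empty string = missing

_DATE_COLUMNS = {
    "patients": ["birth_date", "death_date", "moveout_date"],
    "labs": ["date"],
    "codes": ["date"],
    "prescriptions": ["date"],
    "truth": ["entry_anchor"],
}


def write_bundle(bundle: RawEhrBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("patients", "labs", "codes", "prescriptions", "truth"):
        frame = getattr(bundle, name).copy()
        for column in _DATE_COLUMNS.get(name, []):
            if column in frame.columns:
                frame[column] = pd.to_datetime(frame[column]).dt.strftime("%Y-%m-%d")
        frame.to_csv(directory / f"{name}.csv", index=False)
    meta = {
        "entry_start": str(bundle.entry_start.date()),
        "entry_end": str(bundle.entry_end.date()),
        "study_end": str(bundle.study_end.date()),
    }
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_bundle(directory) -> RawEhrBundle:
    directory = Path(directory)
    frames = {}
    for name in ("patients", "labs", "codes", "prescriptions", "truth"):
        path = directory / f"{name}.csv"
        frame = pd.read_csv(path) if path.exists() else pd.DataFrame()
        for column in _DATE_COLUMNS.get(name, []):
            if column in frame.columns:
                frame[column] = pd.to_datetime(frame[column])
        frames[name] = frame
    meta_path = directory / "meta.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return RawEhrBundle(
        patients=frames["patients"],
        labs=frames["labs"],
        codes=frames["codes"],
        prescriptions=frames["prescriptions"],
        truth=frames["truth"],
        entry_start=pd.Timestamp(meta.get("entry_start", "2009-04-01")),
        entry_end=pd.Timestamp(meta.get("entry_end", "2010-03-31")),
        study_end=pd.Timestamp(meta.get("study_end", "2014-12-31")),
    )
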