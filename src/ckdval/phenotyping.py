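"""EHR phenotyping: from raw event tables to an analysis-ready cohort.

Implements eGFR estimation from serum creatinine (MDRD and CKD-EPI 2009),
detection of incident CKD stage 3-5 from longitudinal eGFR series and
diagnostic codes, cohort entry/exclusion/censoring rules, and extraction of
model predictors at the entry date.

CKD onset (main definition): at least two consecutive eGFR values below
60 mL/min/1.73 m^2 spanning 90 days or more — "consecutive" meaning
adjacent in time order with no intervening value >= 60 — OR a CKD stage 3-5
diagnostic code. The onset date is the date at which the criterion is first
satisfied (the confirming low measurement, or the first code). A relaxed
sensitivity definition accepts a single eGFR below 60.

Internals work on numeric day offsets for speed; the public API accepts and
returns calendar dates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeDefinition",
    "egfr_mdrd",
    "egfr_ckdepi",
    "detect_ckd_onset",
    "build_cohort",
    "extract_predictors",
    "flag_nice_risk_group",
]

CKD_CODE = "ckd_stage_3_5"
DAYS_PER_YEAR = 365.25
SPAN_DAYS = 90          # "3 months or longer"
MED_WINDOW_DAYS = 182   # "6 months prior to entry"
LAB_WINDOW_DAYS = 365   # "most recent result within 12 months"
AKI_WINDOW_DAYS = 730   # "acute kidney injury in the previous 2 years"

#: predictors the chained-equations imputation is expected to handle
IMPUTED_PREDICTORS = ("smoking", "bmi", "sbp", "dbp", "haemoglobin", "deprivation")

COMORBIDITY_CODES = (
    "hypertension",
    "cardiovascular",
    "heart_failure",
    "stroke",
    "pvd",
    "kidney_stones",
    "rheumatoid_arthritis",
    "sle",
    "fh_kidney",
    "prostatic_hypertrophy",
    "haematuria",
)
DRUG_CLASSES = ("nsaid", "antihypertensive", "lithium", "tacrolimus", "cyclosporin")
LAB_ANALYTES = ("creatinine", "haemoglobin", "bmi", "sbp", "dbp", "hdl", "smoking")


@dataclass(frozen=True)
class OutcomeDefinition:
    """Which CKD-onset rule, eGFR equation and horizon to phenotype with.

    rule: 'main' (two consecutive low eGFR spanning >= 3 months, or code)
    or 'single' (any one low eGFR, or code). ``death_as_event`` recodes
    death before CKD as an event at the death date (competing-risk
    sensitivity analysis).
    """

    rule: str = "main"
    egfr_formula: str = "mdrd"
    horizon_years: float = 5.0
    death_as_event: bool = False

    def __post_init__(self) -> None:
        if self.rule not in ("main", "single"):
            raise ValueError(f"unknown outcome rule {self.rule!r}")
        if self.egfr_formula not in ("mdrd", "ckdepi"):
            raise ValueError(f"unknown eGFR formula {self.egfr_formula!r}")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")

    def label(self) -> str:
        parts = [self.rule, self.egfr_formula, f"h{self.horizon_years:g}"]
        if self.death_as_event:
            parts.append("death-event")
        return "-".join(parts)


def egfr_mdrd(creatinine, age, female, black=False):
    """4-variable IDMS-traceable MDRD eGFR in mL/min/1.73 m^2.

    175 * Scr^-1.154 * age^-0.203 * 0.742[female] * 1.212[black],
    creatinine in mg/dL, age in years (adults).
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be positive")
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    out = 175.0 * creatinine ** -1.154 * age ** -0.203
    out = out * np.where(female, 0.742, 1.0) * np.where(black, 1.212, 1.0)
    return float(out) if out.ndim == 0 else out


def egfr_ckdepi(creatinine, age, female, black=False):
    """CKD-EPI 2009 creatinine eGFR in mL/min/1.73 m^2.

    141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209 * 0.993^age
    * 1.018[female] * 1.159[black]; k = 0.7 (F) / 0.9 (M),
    alpha = -0.329 (F) / -0.411 (M).
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be positive")
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = creatinine / kappa
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
    )
    out = out * np.where(female, 1.018, 1.0) * np.where(black, 1.159, 1.0)
    return float(out) if out.ndim == 0 else out


def _egfr_func(formula: str):
    return egfr_mdrd if formula == "mdrd" else egfr_ckdepi


# ---------------------------------------------------------------------------
# onset detection

def _dedupe_daily_min(days: np.ndarray, values: np.ndarray):
    """Sort by day; same-day duplicates keep the day's lowest value."""
    order = np.lexsort((values, days))
    days, values = days[order], values[order]
    keep = np.ones(len(days), dtype=bool)
    keep[1:] = days[1:] != days[:-1]
    return days[keep], values[keep], order[keep]


def _detect_onset_days(days, values, code_days, rule: str):
    """Core detector on numeric days; returns the onset day or None."""
    onset = None
    if len(days):
        days, values, _ = _dedupe_daily_min(np.asarray(days, float), np.asarray(values, float))
        if rule == "single":
            low = np.flatnonzero(values < 60.0)
            if low.size:
                onset = float(days[low[0]])
        else:
            run_start = None
            for j in range(len(days)):
                if values[j] >= 60.0:
                    run_start = None
                elif run_start is None:
                    run_start = days[j]
                elif days[j] - run_start >= SPAN_DAYS:
                    onset = float(days[j])
                    break
    if len(code_days):
        first_code = float(np.min(code_days))
        onset = first_code if onset is None else min(onset, first_code)
    return onset


def _dates_to_days(dates) -> np.ndarray:
    s = pd.Series(dates)
    if len(s) == 0:
        return np.array([])
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)
    parsed = pd.to_datetime(s)
    days = parsed.to_numpy().astype("datetime64[D]").astype(float)
    days[parsed.isna().to_numpy()] = np.nan
    return days


def _day_to_timestamp(day: float) -> pd.Timestamp:
    return pd.Timestamp("1970-01-01") + pd.Timedelta(days=int(day))


def detect_ckd_onset(egfr_series, code_dates=(), definition: OutcomeDefinition | None = None):
    """Earliest date at which the CKD-onset criterion is satisfied, or None.

    ``egfr_series``: DataFrame with (date, value) columns or a sequence of
    (date, value) pairs; dates may be datetimes or plain day numbers.
    ``code_dates``: dates of CKD stage 3-5 diagnostic codes.

    Main rule: within a run of consecutive sub-60 values (no intervening
    >= 60 value), the onset is the first measurement whose distance from the
    run's start reaches 90 days. Code arm: date of the first code. The
    overall onset is the earlier of the two arms. Same-day duplicate
    measurements are resolved to the day's lowest value.
    """
    definition = definition or OutcomeDefinition()
    if isinstance(egfr_series, pd.DataFrame):
        dates = egfr_series.iloc[:, 0]
        values = egfr_series.iloc[:, 1].to_numpy(dtype=float)
    else:
        pairs = list(egfr_series)
        dates = pd.Series([p[0] for p in pairs])
        values = np.asarray([p[1] for p in pairs], dtype=float)
    days = _dates_to_days(dates)
    numeric_in = pd.api.types.is_numeric_dtype(pd.Series(dates)) if len(dates) else True
    code_list = list(code_dates) if code_dates is not None else []
    code_days = _dates_to_days(pd.Series(code_list)) if code_list else np.array([])
    numeric_codes = (
        pd.api.types.is_numeric_dtype(pd.Series(code_list)) if code_list else True
    )
    onset = _detect_onset_days(days, values, code_days, definition.rule)
    if onset is None:
        return None
    if numeric_in and numeric_codes:
        return onset
    return _day_to_timestamp(onset)


# ---------------------------------------------------------------------------
# per-patient index over the bundle's event tables

class _BundleIndex:
    """Numeric per-patient views of a bundle, built once per build/extract."""

    def __init__(self, bundle, formula: str):
        self.formula = formula
        patients = bundle.patients
        self.birth = dict(zip(patients["id"], _dates_to_days(patients["birth_date"])))
        self.female = dict(zip(patients["id"], (patients["sex"] == "F").to_numpy()))
        eth = patients["ethnicity"] if "ethnicity" in patients else pd.Series(index=patients.index)
        self.ethnicity = dict(zip(patients["id"], eth))
        depr = patients["deprivation"] if "deprivation" in patients else pd.Series(index=patients.index)
        self.deprivation = dict(zip(patients["id"], pd.to_numeric(depr, errors="coerce")))
        self.death = dict(zip(patients["id"], _dates_to_days(patients.get("death_date"))))
        self.moveout = dict(zip(patients["id"], _dates_to_days(patients.get("moveout_date"))))

        labs = bundle.labs
        if len(labs):
            lab_days = _dates_to_days(labs["date"])
            ids = labs["id"].to_numpy()
            analyte = labs["analyte"].to_numpy()
            value = labs["value"].to_numpy(dtype=float)
            cr_mask = analyte == "creatinine"
            # eGFR for every creatinine row, vectorized (age at measurement)
            birth_arr = np.array([self.birth[i] for i in ids[cr_mask]])
            female_arr = np.array([self.female[i] for i in ids[cr_mask]])
            black_arr = np.array(
                [(not pd.isna(self.ethnicity[i])) and self.ethnicity[i] == "black"
                 for i in ids[cr_mask]]
            )
            age_at = (lab_days[cr_mask] - birth_arr) / DAYS_PER_YEAR
            egfr = _egfr_func(formula)(value[cr_mask], age_at, female_arr, black_arr)
            self.cr = self._group(ids[cr_mask], lab_days[cr_mask], value[cr_mask], egfr)
            other = ~cr_mask
            self.labs = self._group(ids[other], lab_days[other], analyte[other], value[other])
        else:
            self.cr, self.labs = {}, {}

        codes = bundle.codes
        self.codes = (
            self._group(codes["id"].to_numpy(), _dates_to_days(codes["date"]),
                        codes["code_class"].to_numpy())
            if len(codes)
            else {}
        )
        rx = bundle.prescriptions
        self.rx = (
            self._group(rx["id"].to_numpy(), _dates_to_days(rx["date"]),
                        rx["drug_class"].to_numpy())
            if len(rx)
            else {}
        )

    @staticmethod
    def _group(ids, *arrays):
        if len(ids) == 0:
            return {}
        order = np.argsort(ids, kind="stable")
        ids = ids[order]
        arrays = [a[order] for a in arrays]
        out = {}
        bounds = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1], True])
        for s, e in zip(bounds[:-1], bounds[1:]):
            out[ids[s]] = tuple(a[s:e] for a in arrays)
        return out

    def egfr_series(self, pid):
        days, _, egfr = self.cr.get(pid, (np.array([]), np.array([]), np.array([])))
        return days, egfr

    def ckd_code_days(self, pid):
        days, classes = self.codes.get(pid, (np.array([]), np.array([])))
        return days[classes == CKD_CODE]


def _extract_from_index(index: _BundleIndex, pid, entry_day: float) -> dict:
    birth = index.birth[pid]
    female = bool(index.female[pid])
    ethnicity = index.ethnicity[pid]
    if pd.isna(ethnicity):
        ethnicity = "white"  # >90% of the source population is White British
    out: dict = {
        "age": (entry_day - birth) / DAYS_PER_YEAR,
        "female": float(female),
        "ethnicity": ethnicity,
        "white": float(ethnicity == "white"),
        "black": float(ethnicity == "black"),
        "deprivation": index.deprivation.get(pid, np.nan),
    }

    code_days, code_classes = index.codes.get(pid, (np.array([]), np.array([])))
    pre = code_days < entry_day
    pre_classes = code_classes[pre]
    pre_days = code_days[pre]
    present = set(pre_classes)
    for name in COMORBIDITY_CODES:
        out[name] = float(name in present)

    aki_mask = (pre_classes == "aki") & (entry_day - pre_days <= AKI_WINDOW_DAYS)
    out["aki_2yr"] = float(aki_mask.any())

    # diabetes typing by the age-35-at-first-code rule
    diab_mask = np.isin(pre_classes, ("diabetes_t1", "diabetes_t2", "diabetes_unspecified"))
    t1 = t2 = 0.0
    if diab_mask.any():
        typed = set(pre_classes[diab_mask])
        if typed == {"diabetes_t1"}:
            t1 = 1.0
        elif typed == {"diabetes_t2"}:
            t2 = 1.0
        else:  # unspecified or conflicting codes
            age_first = (pre_days[diab_mask].min() - birth) / DAYS_PER_YEAR
            if age_first < 35:
                t1 = 1.0
            else:
                t2 = 1.0
    out["diabetes_t1"] = t1
    out["diabetes_t2"] = t2
    out["diabetes_any"] = float(t1 or t2)

    rx_days, rx_classes = index.rx.get(pid, (np.array([]), np.array([])))
    in_window = (rx_days >= entry_day - MED_WINDOW_DAYS) & (rx_days < entry_day)
    counts = Counter(rx_classes[in_window])
    for name in DRUG_CLASSES:
        out[name] = float(counts.get(name, 0) >= 2)

    lab_days, lab_analyte, lab_value = index.labs.get(
        pid, (np.array([]), np.array([]), np.array([]))
    )
    window = (lab_days >= entry_day - LAB_WINDOW_DAYS) & (lab_days < entry_day)
    for analyte in LAB_ANALYTES:
        if analyte == "creatinine":
            continue
        mask = window & (lab_analyte == analyte)
        out[analyte] = float(lab_value[mask][np.argmax(lab_days[mask])]) if mask.any() else np.nan

    cr_days, cr_values, _ = index.cr.get(pid, (np.array([]), np.array([]), np.array([])))
    cr_window = (cr_days >= entry_day - LAB_WINDOW_DAYS) & (cr_days < entry_day)
    if cr_window.any():
        out["creatinine"] = float(cr_values[cr_window][np.argmax(cr_days[cr_window])])
        out["egfr"] = float(
            _egfr_func(index.formula)(
                out["creatinine"], out["age"], female, out["black"] == 1.0
            )
        )
    else:
        out["creatinine"] = np.nan
        out["egfr"] = np.nan

    hb = out["haemoglobin"]
    out["anaemia"] = np.nan if np.isnan(hb) else float(hb < (12.0 if female else 13.0))
    return out


def extract_predictors(bundle, patient_id, entry_date, formula: str = "mdrd") -> dict:
    """Extract one patient's model predictors as known at the entry date.

    Comorbidity flags: any diagnostic code strictly before entry.
    Medication flags: >= 2 prescriptions of the class in the 6 months before
    entry. Labs: most recent value in the 12 months before entry (strictly
    pre-entry), else missing (NaN). Diabetes without a typed code is
    assigned type 1 if the first diabetes code predates age 35, else type 2.
    Anaemia is haemoglobin < 13 g/dL (men) / < 12 g/dL (women). Missing
    ethnicity defaults to White British.
    """
    if patient_id not in set(bundle.patients["id"]):
        raise KeyError(f"unknown patient id {patient_id!r}")
    index = _BundleIndex(bundle, formula)
    entry_day = float(_dates_to_days(pd.Series([pd.Timestamp(entry_date)]))[0])
    return _extract_from_index(index, patient_id, entry_day)


NICE_RISK_FACTORS = (
    "nsaid", "lithium", "tacrolimus", "cyclosporin",
    "diabetes_any", "hypertension", "aki_2yr",
    "cardiovascular", "kidney_stones", "prostatic_hypertrophy",
    "sle", "haematuria", "fh_kidney",
)


def flag_nice_risk_group(predictors: dict) -> bool:
    """True iff the patient carries any established CKD risk factor from the
    national early-detection guidance: calcineurin inhibitors, lithium or
    NSAID use; diabetes; hypertension; AKI in the 2 years before entry;
    cardiovascular disease, renal calculi, prostatic hypertrophy, SLE or
    haematuria; family history of kidney disease."""
    return any(float(predictors.get(f, 0) or 0) == 1.0 for f in NICE_RISK_FACTORS)


def build_cohort(
    bundle,
    definition: OutcomeDefinition | None = None,
    entry_window: tuple | None = None,
    study_end=None,
) -> pd.DataFrame:
    """Apply the study's selection, outcome and censoring rules to a bundle.

    Includes adults (>= 18 years at entry) with at least one record in the
    entry window; entry is the date of the first in-window record. Patients
    whose pre-entry data already satisfy the CKD definition are excluded as
    prevalent. Follow-up runs to the earliest of study end, death, move-out
    or CKD onset. ``complete_followup`` marks patients who either developed
    CKD or were observed for the full horizon.

    Returns one row per included patient with predictors, follow-up time,
    event type and analysis flags.
    """
    definition = definition or OutcomeDefinition()
    start, end = entry_window or (bundle.entry_start, bundle.entry_end)
    study_end_day = float(
        _dates_to_days(pd.Series([pd.Timestamp(study_end or bundle.study_end)]))[0]
    )
    start_day = float(_dates_to_days(pd.Series([pd.Timestamp(start)]))[0])
    end_day = float(_dates_to_days(pd.Series([pd.Timestamp(end)]))[0])

    if bundle.patients.empty:
        warnings.warn("empty bundle: returning empty cohort")
        return pd.DataFrame()

    index = _BundleIndex(bundle, definition.egfr_formula)

    # entry = first in-window record across all event tables
    pieces = []
    for frame in (bundle.labs, bundle.codes, bundle.prescriptions):
        if len(frame):
            pieces.append(
                pd.DataFrame({"id": frame["id"].to_numpy(), "day": _dates_to_days(frame["date"])})
            )
    if not pieces:
        warnings.warn("bundle has no events: returning empty cohort")
        return pd.DataFrame()
    events = pd.concat(pieces, ignore_index=True)
    events = events[(events["day"] >= start_day) & (events["day"] <= end_day)]
    entries = events.groupby("id")["day"].min()

    rows = []
    for pid, entry_day in entries.items():
        if pid not in index.birth:
            continue
        age = (entry_day - index.birth[pid]) / DAYS_PER_YEAR
        if age < 18:
            continue

        cr_days, cr_egfr = index.egfr_series(pid)
        ckd_days = index.ckd_code_days(pid)

        # prevalence assessed on strictly pre-entry data only
        pre = cr_days < entry_day
        if (
            _detect_onset_days(
                cr_days[pre], cr_egfr[pre], ckd_days[ckd_days < entry_day], definition.rule
            )
            is not None
        ):
            continue

        death = index.death.get(pid, np.nan)
        moveout = index.moveout.get(pid, np.nan)
        admin_end = np.nanmin([study_end_day, death, moveout])

        post = (cr_days >= entry_day) & (cr_days <= admin_end)
        post_codes = ckd_days[(ckd_days >= entry_day) & (ckd_days <= admin_end)]
        onset = _detect_onset_days(cr_days[post], cr_egfr[post], post_codes, definition.rule)

        if onset is not None:
            followup_end, event = onset, "ckd"
        elif not np.isnan(death) and death <= admin_end:
            followup_end, event = death, "death"
        else:
            followup_end, event = admin_end, "censored"

        if definition.death_as_event and event == "death":
            event = "ckd"

        followup_years = max(followup_end - entry_day, 0.0) / DAYS_PER_YEAR
        event_within_horizon = int(
            event == "ckd" and followup_years <= definition.horizon_years
        )
        complete_followup = bool(
            event == "ckd" or followup_years >= definition.horizon_years
        )

        pred = _extract_from_index(index, pid, entry_day)
        row = {
            "id": pid,
            "entry_date": _day_to_timestamp(entry_day),
            "onset_date": None if onset is None else _day_to_timestamp(onset),
            "followup_years": followup_years,
            "event": event,
            "event_within_horizon": event_within_horizon,
            "complete_followup": complete_followup,
            "nice_risk_group": flag_nice_risk_group(pred),
        }
        row.update(pred)
        row["complete_case"] = not any(
            pd.isna(row.get(v)) for v in IMPUTED_PREDICTORS
        )
        rows.append(row)

    cohort = pd.DataFrame(rows)
    if cohort.empty:
        warnings.warn("no patients satisfied the selection rules")
    return cohort
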