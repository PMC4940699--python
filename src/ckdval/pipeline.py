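"""End-to-end orchestration: data -> cohort -> imputation -> predictions ->
validation reports, including the sensitivity-analysis variants.

The run is declarative (:class:`RunConfig`, loadable from YAML): choose a
data source (synthetic parameters or saved tables), an outcome definition,
a cohort variant, model configuration files, and imputation/bootstrap
settings. ``run_validation`` writes a long-format metrics table per model
plus combined discrimination/calibration, threshold and case-mix tables,
decision-curve and calibration-bin CSVs, a cohort-flow summary and a
manifest (config hash + seed) sufficient to reproduce every number.

Validation conventions: logistic models and simplified scores are
evaluated on the complete-follow-up cohort (fixed-horizon outcomes need
complete follow-up); Cox models are additionally given a Harrell c-index
on the full cohort, using observed follow-up and events.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from . import models as _models
from .imputation import ImputationConfig, impute, pool_metric
from .phenotyping import IMPUTED_PREDICTORS, OutcomeDefinition, build_cohort, detect_ckd_onset, CKD_CODE
from .synthetic import CohortParams, RawEhrBundle, generate_cohort, read_bundle

__all__ = [
    "RunConfig",
    "run_validation",
    "validate_model_on_cohort",
    "summarize_selection",
    "dev_prevalence",
    "round_half_up",
    "packaged_model_paths",
]

COHORT_VARIANTS = ("all", "complete_followup", "nice_risk_group", "complete_case")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention used for reported percentages;
    banker's rounding would turn 91.25 into 91.2 instead of 91.3)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def dev_prevalence(cases: int, n: int) -> float:
    """Outcome prevalence of a development cohort as a percentage rounded
    half-up to one decimal, as printed in model-summary tables."""
    if not 0 < cases <= n:
        raise ValueError(f"need 0 < cases <= n, got cases={cases}, n={n}")
    return round_half_up(100.0 * cases / n, 1)


def summarize_selection(bundle: RawEhrBundle, definition: OutcomeDefinition | None = None,
                        cohort: pd.DataFrame | None = None) -> dict:
    """Cohort-flow counts (screened, excluded prevalent, included, complete
    follow-up, deaths before CKD, incident events) with one-decimal
    percentages of the included population."""
    definition = definition or OutcomeDefinition()
    if cohort is None:
        cohort = build_cohort(bundle, definition)

    all_dates = pd.concat(
        [bundle.labs[["id", "date"]], bundle.codes[["id", "date"]],
         bundle.prescriptions[["id", "date"]]],
        ignore_index=True,
    )
    in_window = all_dates[
        (all_dates["date"] >= bundle.entry_start) & (all_dates["date"] <= bundle.entry_end)
    ]
    entries = in_window.groupby("id")["date"].min()
    patients = bundle.patients.set_index("id")
    screened_ids = entries.index.intersection(patients.index)
    ages = (
        entries.loc[screened_ids] - patients.loc[screened_ids, "birth_date"]
    ).dt.days / 365.25
    screened = int((ages >= 18).sum())

    included = len(cohort)
    excluded_prevalent = screened - included
    complete = int(cohort["complete_followup"].sum()) if included else 0
    died = int((cohort["event"] == "death").sum()) if included else 0
    events = int((cohort["event"] == "ckd").sum()) if included else 0

    def pct(x):
        return round_half_up(100.0 * x / included, 1) if included else float("nan")

    return {
        "screened_adults": screened,
        "excluded_prevalent": excluded_prevalent,
        "included": included,
        "complete_followup": complete,
        "complete_followup_pct": pct(complete),
        "died_before_ckd": died,
        "died_before_ckd_pct": pct(died),
        "events": events,
        "events_pct": pct(events),
    }


def packaged_model_paths() -> list[Path]:
    """The model configuration files shipped with the package (placeholder
    coefficients; substitute published values to reproduce a real study)."""
    directory = Path(__file__).parent / "model_configs"
    return sorted(directory.glob("*.yaml"))


@dataclass
class RunConfig:
    synthetic: dict | None = field(default_factory=dict)  # CohortParams kwargs
    data_dir: str | None = None
    outcome: str = "main"              # main | single
    egfr: str = "mdrd"                 # mdrd | ckdepi
    horizon_years: float = 5.0
    death_as_event: bool = False
    cohort_variant: str = "all"
    model_paths: list = field(default_factory=list)
    imputation: dict = field(default_factory=dict)
    bootstrap_B: int = 500
    threshold_sd_B: int = 200
    calibration_groups: int = 10
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_variant not in COHORT_VARIANTS:
            raise ValueError(f"unknown cohort variant {self.cohort_variant!r}")
        if self.synthetic is None and self.data_dir is None:
            raise ValueError("provide synthetic parameters or a data directory")
        if self.death_as_event and self.outcome not in ("main", "single"):
            raise ValueError("death_as_event combines only with an eGFR/code rule")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def definition(self) -> OutcomeDefinition:
        return OutcomeDefinition(
            rule=self.outcome,
            egfr_formula=self.egfr,
            horizon_years=self.horizon_years,
            death_as_event=self.death_as_event,
        )

    def config_hash(self) -> str:
        doc = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _prepare_model(spec: _models.ModelSpec) -> _models.ModelSpec:
    if spec.family == "logistic" and spec.intercept is None:
        return _models.with_estimated_intercept(spec)
    return spec


def _refresh_derived(frame: pd.DataFrame) -> pd.DataFrame:
    """Re-derive anaemia from (possibly imputed) haemoglobin."""
    out = frame.copy()
    if "haemoglobin" in out.columns and "female" in out.columns:
        hb = out["haemoglobin"]
        cut = np.where(out["female"] == 1.0, 12.0, 13.0)
        derived = (hb < cut).astype(float)
        out["anaemia"] = np.where(hb.isna(), out.get("anaemia", np.nan), derived)
    return out


def _validation_summary(model: _models.ModelSpec, covariates: pd.DataFrame,
                        prevalence: float) -> _models.DevelopmentSummary:
    summaries = {}
    for term in model.active_terms:
        x = covariates[term.predictor]
        summaries[term.name] = float(np.mean(term.design_value(x.to_numpy())))
    return _models.DevelopmentSummary(
        prevalence=min(max(prevalence, 1e-9), 1 - 1e-9), n=len(covariates),
        summaries=summaries,
    )


def validate_model_on_cohort(
    model: _models.ModelSpec,
    completed: list[pd.DataFrame],
    y: np.ndarray,
    full_cohort: pd.DataFrame | None = None,
    B: int = 500,
    threshold_sd_B: int = 200,
    calibration_groups: int = 10,
    seed: int = 0,
    cohort_label: str = "complete_followup",
) -> M.ValidationReport:
    """Full validation surface for one model.

    ``completed`` are the multiply-imputed covariate tables of the
    complete-follow-up cohort; ``y`` the fixed-horizon binary outcome.
    Point estimates are averaged over completed datasets; bootstrap CIs and
    plot data come from the first. For Cox models, ``full_cohort`` (with
    ``followup_years`` and ``event``) adds a c-index on everyone.
    """
    model = _prepare_model(model)
    y = np.asarray(y, dtype=float)
    report = M.ValidationReport(
        model=model.name, cohort=cohort_label, n=len(y), n_events=int(y.sum())
    )

    if model.family == "score":
        scores = [np.asarray(_models.apply_score(model, d), dtype=float) for d in completed]
        report.auc = pool_metric(M.auc_roc(s, y) for s in scores)
        report.auc_ci = M.bootstrap_ci(M.auc_roc, (scores[0], y), B=B, seed=seed)
        report.threshold_block = _threshold_block(
            model, scores[0], y, threshold_sd_B, seed
        )
        return report

    lp_list, risk_list = [], []
    for data in completed:
        lp = np.asarray(_models.linear_predictor(model, data), dtype=float)
        if model.family == "logistic":
            lp = lp + model.intercept
        risk = np.asarray(_models.predict_risk(model, data), dtype=float)
        lp_list.append(lp)
        risk_list.append(risk)
    risk0, lp0 = risk_list[0], lp_list[0]

    report.auc = pool_metric(M.auc_roc(r, y) for r in risk_list)
    report.auc_ci = M.bootstrap_ci(M.auc_roc, (risk0, y), B=B, seed=seed)

    mape_pairs = [M.mape(r, y) for r in risk_list]
    report.mape_mean = pool_metric(m for m, _ in mape_pairs)
    report.mape_sd = pool_metric(s for _, s in mape_pairs)

    slopes = [M.calibration_slope(lp, y) for lp in lp_list]
    report.calibration_slope = pool_metric(s for s, _, _ in slopes)
    report.calibration_slope_ci = (slopes[0][1], slopes[0][2])

    report.calibration_table = M.calibration_bins(risk0, y, groups=calibration_groups)
    report.threshold_block = _threshold_block(model, risk0, y, threshold_sd_B, seed)

    thr, capture = M.top_decile_capture(risk0, y)
    report.top_decile_threshold = thr
    report.top_decile_capture = capture
    report.decision_curve = M.decision_curve(risk0, y)

    if model.development_summary is not None:
        val_summary = _validation_summary(model, completed[0], float(y.mean()))
        include_b0 = model.family == "logistic"
        report.mean_lp_block = M.case_mix_compare(
            model, completed[0], validation_summary=val_summary,
            include_intercept=include_b0,
        )

    if model.family == "cox" and full_cohort is not None and len(full_cohort):
        lp_full = np.asarray(_models.linear_predictor(model, full_cohort), dtype=float)
        time = full_cohort["followup_years"].to_numpy(dtype=float)
        event = (full_cohort["event"] == "ckd").to_numpy(dtype=float)
        report.c_index = M.harrell_c(lp_full, time, event)
        report.c_index_ci = M.bootstrap_ci(
            M.harrell_c, (lp_full, time, event), B=B, seed=seed
        )
    return report


def _threshold_block(model, values, y, sd_B, seed):
    block: dict[str, float] = {}
    best = M.youden_threshold(values, y)
    block["best"] = best
    block["best_sd"] = M.bootstrap_sd(
        M.youden_threshold, (values, y), B=sd_B, seed=seed
    )
    for label, threshold in (("proposed", model.threshold), ("best", best)):
        if threshold is None:
            continue
        tm = M.threshold_metrics(values, y, threshold)
        for key, val in tm.items():
            block[f"{label}_{key}"] = val
            block[f"{label}_{key}_sd"] = M.bootstrap_sd(
                lambda v, yy, t=threshold, k=key: M.threshold_metrics(v, yy, t)[k],
                (values, y), B=sd_B, seed=seed,
            )
    if model.threshold is not None:
        block["proposed"] = model.threshold
    return block


def run_validation(config: RunConfig) -> dict:
    """Run the whole study under one configuration; returns the report
    frames and writes them under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    definition = config.definition()

    if config.data_dir is not None:
        bundle = read_bundle(config.data_dir)
    else:
        params = CohortParams(**{"seed": config.seed, **(config.synthetic or {})})
        bundle = generate_cohort(params)

    cohort = build_cohort(bundle, definition)
    if cohort.empty:
        raise RuntimeError("cohort stage produced no patients; check the configuration")
    flow = summarize_selection(bundle, definition, cohort=cohort)

    if config.cohort_variant == "nice_risk_group":
        cohort = cohort[cohort["nice_risk_group"]].reset_index(drop=True)
    elif config.cohort_variant == "complete_case":
        cohort = cohort[cohort["complete_case"]].reset_index(drop=True)
    if config.cohort_variant == "complete_followup":
        cohort = cohort[cohort["complete_followup"]].reset_index(drop=True)
    if not cohort["complete_followup"].any():
        raise RuntimeError("no complete-follow-up patients under this configuration")

    # imputation runs on the whole (variant) cohort so Cox models can score
    # everyone; fixed-horizon metrics then use the complete-follow-up subset
    impute_cols = [c for c in IMPUTED_PREDICTORS if c in cohort.columns]
    helper_cols = [c for c in ("age", "female", "event_within_horizon") if c in cohort.columns]
    if config.cohort_variant == "complete_case" or not cohort[impute_cols].isna().any().any():
        completed_full = [cohort]
    else:
        imp_config = ImputationConfig(**{"seed": config.seed, **(config.imputation or {})})
        completed_full = impute(cohort, imp_config, columns=impute_cols + helper_cols)
    completed_full = [_refresh_derived(d) for d in completed_full]
    cf_mask = cohort["complete_followup"].to_numpy(dtype=bool)
    completed = [d[cf_mask].reset_index(drop=True) for d in completed_full]
    y = completed[0]["event_within_horizon"].to_numpy(dtype=float)

    model_paths = [Path(p) for p in (config.model_paths or packaged_model_paths())]
    reports: list[M.ValidationReport] = []
    for path in model_paths:
        spec = _models.load_model_spec(path)
        reports.append(
            validate_model_on_cohort(
                spec,
                completed,
                y,
                full_cohort=completed_full[0] if spec.family == "cox" else None,
                B=config.bootstrap_B,
                threshold_sd_B=config.threshold_sd_B,
                calibration_groups=config.calibration_groups,
                seed=config.seed,
                cohort_label=config.cohort_variant,
            )
        )

    frames = _write_outputs(out, config, flow, reports)
    return {"flow": flow, "reports": reports, **frames}


def _write_outputs(out: Path, config: RunConfig, flow: dict, reports) -> dict:
    variant_dir = out / "reports" / config.cohort_variant
    variant_dir.mkdir(parents=True, exist_ok=True)

    long_rows, calib_rows, dc_rows = [], [], []
    for report in reports:
        rows = report.to_rows()
        rows.to_csv(variant_dir / f"{report.model}.csv", index=False)
        long_rows.append(rows)
        if report.calibration_table is not None:
            table = report.calibration_table.copy()
            table.insert(0, "model", report.model)
            calib_rows.append(table)
        if report.decision_curve is not None:
            curve = report.decision_curve.copy()
            curve.insert(0, "model", report.model)
            dc_rows.append(curve)

    combined = pd.concat(long_rows, ignore_index=True)
    table4 = combined[
        combined["metric"].isin(
            ["n", "n_events", "auc", "c_index", "mape", "mape_sd", "calibration_slope"]
        )
    ]
    table5 = combined[combined["metric"].str.startswith("threshold_")]
    table6 = combined[combined["metric"].str.startswith("case_mix_")]
    table4.to_csv(out / "table4.csv", index=False)
    table5.to_csv(out / "table5.csv", index=False)
    table6.to_csv(out / "table6.csv", index=False)
    combined.to_csv(out / "metrics_long.csv", index=False)

    calibration = pd.concat(calib_rows, ignore_index=True) if calib_rows else pd.DataFrame()
    curves = pd.concat(dc_rows, ignore_index=True) if dc_rows else pd.DataFrame()
    calibration.to_csv(out / "calibration_bins.csv", index=False)
    curves.to_csv(out / "decision_curves.csv", index=False)
    pd.DataFrame([flow]).to_csv(out / "cohort_flow.csv", index=False)

    import importlib.metadata as _ilm

    try:
        version = _ilm.version("ckdval")
    except _ilm.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "ckdval": version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "table4": table4,
        "table5": table5,
        "table6": table6,
        "calibration_bins": calibration,
        "decision_curves": curves,
        "metrics_long": combined,
    }
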