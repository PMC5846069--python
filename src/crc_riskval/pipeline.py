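"""Validation-study orchestration in a statsmodels-style Model/Results shape.

:class:`ExternalValidation` is constructed from a harmonized cohort and one
or more model specifications (directly, or via :meth:`from_files`). Its
:meth:`fit` runs the full study for every model × sex stratum:

    complete-case mask → scoring → horizon conversion (per hazard
    assumption) → discrimination (binary AUC at five years in the closed
    cohort, Harrell's C in the open cohort) → threshold metrics →
    calibration

and returns a :class:`ValidationResults` carrying every per-stratum metric,
a summary table, a provenance block (config hash, seed, exclusion counts)
and writers for the report artefacts. :func:`sensitivity_battery` reruns the
study under the standard perturbations — extreme-case imputation in both
directions, dropped covariate terms, surveillance exclusion, the open-cohort
design — and reports each alongside its AUC delta against the base run.

Every computation is carried out at full precision; rounding (half-even, one
decimal for percentage metrics, two for AUC and likelihood ratios) happens
only at the report boundary.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import harmonization as hz
from . import model_spec as ms
from .evaluation import (
    CalibrationResult,
    DiscriminationResult,
    ThresholdMetrics,
    auc,
    calibration_table,
    harrell_c,
    threshold_metrics,
)
from .horizon import HazardAssumption
from .presets import crc_code_set, surveillance_code_set

__all__ = [
    "RunConfig",
    "StratumResult",
    "ValidationResults",
    "ExternalValidation",
    "run_validation",
    "sensitivity_battery",
    "write_report",
]

DEFAULT_Q = (0.10, 0.20, 0.80, 0.90)
DEFAULT_ASSUMPTIONS = (
    HazardAssumption(shape="constant"),
    HazardAssumption(shape="doubling"),
)


class RunConfig(BaseModel):
    """Declarative configuration of one validation run."""

    model_config = ConfigDict(frozen=True)

    model_specs: list[str]
    cohort: str
    cohort_mode: str = "closed"  # closed | open
    assumptions: list[HazardAssumption] = Field(
        default_factory=lambda: list(DEFAULT_ASSUMPTIONS)
    )
    q_list: list[float] = Field(default_factory=lambda: list(DEFAULT_Q))
    outcome_scope: str = "CRC"  # CRC | colon
    sensitivity: dict[str, Any] = Field(default_factory=dict)
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.model_specs:
            raise ValueError("at least one model spec is required")
        if any(not 0.0 < q < 1.0 for q in self.q_list):
            raise ValueError("q values must lie in (0, 1)")
        if self.cohort_mode not in ("closed", "open"):
            raise ValueError("cohort_mode must be 'closed' or 'open'")
        if self.outcome_scope not in ("CRC", "colon"):
            raise ValueError("outcome_scope must be 'CRC' or 'colon'")
        known = {"extreme_impute_high", "extreme_impute_low", "drop_term_sets",
                 "exclude_surveillance", "open_cohort"}
        unknown = set(self.sensitivity) - known
        if unknown:
            raise ValueError(f"unknown sensitivity toggle(s): {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(pathlib.Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StratumResult:
    """All metrics for one model in one sex stratum."""

    model_id: str
    sex: str
    n: int
    n_events: int
    applicable_fraction: float
    discrimination: Optional[DiscriminationResult]
    harrell_c: Optional[float]
    thresholds: dict[float, ThresholdMetrics]
    calibration: dict[str, CalibrationResult]
    note: str = ""


@dataclass
class ValidationResults:
    """Fitted results of an external-validation run."""

    strata: dict[tuple[str, str], StratumResult]
    provenance: dict[str, Any]
    mode: str
    assumptions: list[HazardAssumption]

    def summary(self) -> pd.DataFrame:
        """One row per model × sex with the headline metrics (full precision)."""
        rows = []
        for (model_id, sex), res in sorted(self.strata.items()):
            row: dict[str, Any] = {
                "model_id": model_id,
                "sex": sex,
                "n": res.n,
                "n_events": res.n_events,
                "applicable_fraction": res.applicable_fraction,
            }
            if res.discrimination is not None:
                row["auc"] = res.discrimination.auc
                row["auc_ci_low"] = res.discrimination.ci_low
                row["auc_ci_high"] = res.discrimination.ci_high
            if res.harrell_c is not None:
                row["harrell_c"] = res.harrell_c
            for label, cal in res.calibration.items():
                row[f"hl_chi2_{label}"] = cal.hl_chi2
                row[f"hl_p_{label}"] = cal.hl_p
            if res.note:
                row["note"] = res.note
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir, formats: Sequence[str] = ("csv", "json")) -> list[pathlib.Path]:
        return write_report(self, outdir, formats)


def _assumption_label(a: HazardAssumption) -> str:
    if a.shape == "constant":
        return "constant"
    return f"doubling{a.doubling_period_years:g}y"


class ExternalValidation:
    """External validation of risk models against a harmonized cohort.

    Parameters
    ----------
    cohort : DataFrame
        Harmonized, post-exclusion cohort (see :mod:`crc_riskval.harmonization`).
    models : sequence of ModelSpec
    cohort_mode : {"closed", "open"}
        Closed: outcome binary at five years, AUC discrimination. Open:
        censored design, Harrell's C.
    outcome_scope : {"CRC", "colon"}
        ``colon`` restricts events to the colon subtype.
    assumptions : hazard assumptions for horizon conversion (calibration is
        reported once per assumption).
    q_list : population fractions for threshold metrics.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        models: Sequence[ms.ModelSpec],
        *,
        cohort_mode: str = "closed",
        outcome_scope: str = "CRC",
        assumptions: Sequence[HazardAssumption] = DEFAULT_ASSUMPTIONS,
        q_list: Sequence[float] = DEFAULT_Q,
        seed: int = 0,
        provenance: Optional[dict[str, Any]] = None,
    ) -> None:
        if not models:
            raise ValueError("at least one model spec is required")
        self.cohort = cohort
        self.models = sorted(models, key=lambda m: m.model_id)
        self.cohort_mode = cohort_mode
        self.outcome_scope = outcome_scope
        self.assumptions = list(assumptions)
        self.q_list = list(q_list)
        self.seed = seed
        self.provenance = dict(provenance or {})
        if "exclusion_flow" in cohort.attrs:
            self.provenance.setdefault("exclusion_flow", cohort.attrs["exclusion_flow"])

    @classmethod
    def from_files(
        cls,
        cohort_csv,
        spec_paths: Iterable,
        *,
        apply_exclusions: bool = True,
        **kwargs,
    ) -> "ExternalValidation":
        cohort = hz.load_cohort_csv(cohort_csv)
        mode = kwargs.get("cohort_mode", "closed")
        if apply_exclusions:
            cohort = hz.apply_exclusions(
                cohort, crc_code_set(), require_5y=(mode == "closed")
            )
        models = [ms.load_model_spec(p) for p in spec_paths]
        return cls(cohort, models, **kwargs)

    # -- outcome definition -------------------------------------------------

    def _outcome(self, sub: pd.DataFrame) -> np.ndarray:
        event = sub["event"].fillna(0).astype(int).to_numpy()
        if self.outcome_scope == "colon" and "event_subtype" in sub.columns:
            event = event * (sub["event_subtype"].fillna("") == "colon").to_numpy()
        if self.cohort_mode == "closed" and "event_time_years" in sub.columns:
            t = pd.to_numeric(sub["event_time_years"], errors="coerce").to_numpy(float)
            within = np.where(np.isnan(t), True, t <= 5.0)
            event = event * within
        return event.astype(int)

    def _time(self, sub: pd.DataFrame, event: np.ndarray) -> np.ndarray:
        fup = pd.to_numeric(sub["followup_years"], errors="coerce").to_numpy(float)
        t = fup.copy()
        if "event_time_years" in sub.columns:
            et = pd.to_numeric(sub["event_time_years"], errors="coerce").to_numpy(float)
            use = (event == 1) & ~np.isnan(et)
            t[use] = et[use]
        return t

    # -- fitting -------------------------------------------------------------

    def fit(self) -> ValidationResults:
        strata: dict[tuple[str, str], StratumResult] = {}
        for spec in self.models:
            complete = hz.complete_case_mask(self.cohort, spec)
            if not complete.any():
                raise ValueError(f"model {spec.model_id!r} has zero complete cases")
            preds = ms.score_cohort(spec, self.cohort)
            for sex in ("male", "female"):
                sel = complete & (self.cohort["sex"] == sex).to_numpy()
                if not sel.any():
                    continue
                sub = self.cohort.loc[sel]
                p = preds.loc[sel]
                strata[(spec.model_id, sex)] = self._fit_stratum(spec, sub, p, sex)
        provenance = dict(self.provenance)
        provenance.update(
            {
                "seed": self.seed,
                "cohort_mode": self.cohort_mode,
                "outcome_scope": self.outcome_scope,
                "n_cohort": int(len(self.cohort)),
                "models": [m.model_id for m in self.models],
            }
        )
        provenance["config_hash"] = hashlib.sha256(
            json.dumps(provenance, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return ValidationResults(
            strata=strata,
            provenance=provenance,
            mode=self.cohort_mode,
            assumptions=self.assumptions,
        )

    def _fit_stratum(
        self, spec: ms.ModelSpec, sub: pd.DataFrame, preds: pd.DataFrame, sex: str
    ) -> StratumResult:
        outcome = self._outcome(sub)
        scores = preds["linear_predictor_or_points"].to_numpy(float)
        n, n_events = len(sub), int(outcome.sum())
        applicable_fraction = float(preds["applicable"].mean())

        discrimination = None
        c_index = None
        thresholds: dict[float, ThresholdMetrics] = {}
        calibration: dict[str, CalibrationResult] = {}
        note = ""

        if self.cohort_mode == "open":
            time = self._time(sub, outcome)
            c_index = harrell_c(scores, time, outcome)
        else:
            discrimination = auc(scores, outcome)
            for q in self.q_list:
                thresholds[q] = threshold_metrics(scores, outcome, q)
            native = preds["native_risk"].to_numpy(float)
            for assumption in self.assumptions:
                label = _assumption_label(assumption)
                from .horizon import convert_risk

                risk5 = convert_risk(
                    np.clip(native, 0.0, np.nextafter(1.0, 0.0)),
                    spec.native_horizon_years,
                    5.0,
                    assumption,
                )
                try:
                    calibration[label] = calibration_table(risk5, outcome)
                except ValueError as exc:
                    note = f"calibration ({label}) unavailable: {exc}"
        return StratumResult(
            model_id=spec.model_id,
            sex=sex,
            n=n,
            n_events=n_events,
            applicable_fraction=applicable_fraction,
            discrimination=discrimination,
            harrell_c=c_index,
            thresholds=thresholds,
            calibration=calibration,
            note=note,
        )


# ---------------------------------------------------------------------------
# config-driven entry points
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    cohort = hz.load_cohort_csv(config.cohort)
    models = [ms.load_model_spec(p) for p in config.model_specs]
    return cohort, models


def _build(config: RunConfig, cohort: pd.DataFrame, models, *, mode=None,
           extra_provenance=None) -> ExternalValidation:
    mode = mode or config.cohort_mode
    excluded = hz.apply_exclusions(cohort, crc_code_set(), require_5y=(mode == "closed"))
    prov = {"config_hash": config.hash()}
    if extra_provenance:
        prov.update(extra_provenance)
    return ExternalValidation(
        excluded,
        models,
        cohort_mode=mode,
        outcome_scope=config.outcome_scope,
        assumptions=config.assumptions,
        q_list=config.q_list,
        seed=config.seed,
        provenance=prov,
    )


def run_validation(config: RunConfig) -> ValidationResults:
    """Run the base validation study described by ``config``."""
    cohort, models = _load_inputs(config)
    results = _build(config, cohort, models).fit()
    if config.output_dir:
        write_report(results, config.output_dir)
    return results


def _auc_delta(results: ValidationResults, base: ValidationResults) -> dict[str, float]:
    deltas = {}
    for key, res in results.strata.items():
        ref = base.strata.get(key)
        if ref is None or res.discrimination is None or ref.discrimination is None:
            continue
        deltas["|".join(key)] = res.discrimination.auc - ref.discrimination.auc
    return deltas


def sensitivity_battery(config: RunConfig) -> dict[str, ValidationResults]:
    """Base run plus one rerun per enabled sensitivity toggle.

    Supported toggles (keys of ``config.sensitivity``): ``extreme_impute_high``
    and ``extreme_impute_low`` (booleans), ``drop_term_sets`` (mapping of
    analysis name to covariate list), ``exclude_surveillance`` (boolean) and
    ``open_cohort`` (boolean). Each rerun's provenance carries the AUC delta
    against the base run; dropping terms a model does not contain flags the
    model as not applicable rather than failing.
    """
    cohort, models = _load_inputs(config)
    base = _build(config, cohort, models).fit()
    reports: dict[str, ValidationResults] = {"base": base}
    toggles = config.sensitivity

    all_covs = {c.name: c for m in models for c in m.covariates}
    for direction in ("high", "low"):
        if toggles.get(f"extreme_impute_{direction}"):
            imputed = hz.extreme_value_impute(
                cohort, [all_covs[k] for k in sorted(all_covs)], direction=direction)
            rep = _build(config, imputed, models,
                         extra_provenance={"analysis": f"extreme_impute_{direction}"}).fit()
            rep.provenance["auc_delta_vs_base"] = _auc_delta(rep, base)
            reports[f"extreme_impute_{direction}"] = rep

    for name, cov_names in (toggles.get("drop_term_sets") or {}).items():
        reduced = []
        skipped = []
        for m in models:
            present = [c for c in cov_names if c in m.term_covariates]
            if present:
                reduced.append(ms.drop_terms(m, present))
            else:
                skipped.append(m.model_id)
                reduced.append(m)
        rep = _build(config, cohort, reduced,
                     extra_provenance={"analysis": f"drop_terms:{name}"}).fit()
        rep.provenance["auc_delta_vs_base"] = _auc_delta(rep, base)
        if skipped:
            rep.provenance["not_applicable"] = sorted(skipped)
            for (model_id, sex), res in rep.strata.items():
                if model_id in skipped:
                    res.note = (res.note + " " if res.note else "") + "drop-terms not applicable"
        reports[f"drop_terms:{name}"] = rep

    if toggles.get("exclude_surveillance"):
        trimmed = hz.exclude_surveillance(cohort, surveillance_code_set())
        rep = _build(config, trimmed, models,
                     extra_provenance={"analysis": "exclude_surveillance",
                                       "surveillance_removed": trimmed.attrs.get(
                                           "surveillance_removed")}).fit()
        rep.provenance["auc_delta_vs_base"] = _auc_delta(rep, base)
        reports["exclude_surveillance"] = rep

    if toggles.get("open_cohort"):
        rep = _build(config, cohort, models, mode="open",
                     extra_provenance={"analysis": "open_cohort"}).fit()
        reports["open_cohort"] = rep

    return reports


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _round_half_even(x: float, nd: int) -> str:
    return f"{round(float(x), nd):.{nd}f}"


def write_report(
    results: ValidationResults, outdir, formats: Sequence[str] = ("csv", "json")
) -> list[pathlib.Path]:
    """Write report artefacts with the publication rounding conventions.

    CSV tables round percentage metrics to one decimal and AUC / likelihood
    ratios to two (half-even); the JSON summary preserves full precision.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []

    if "csv" in formats:
        rows = []
        for (model_id, sex), res in sorted(results.strata.items()):
            for q, tm in sorted(res.thresholds.items()):
                rows.append(
                    {
                        "model_id": model_id,
                        "sex": sex,
                        "top_fraction": f"{q:g}",
                        "Sensitivity": _round_half_even(tm.sensitivity, 1),
                        "Specificity": _round_half_even(tm.specificity, 1),
                        "LR+": _round_half_even(tm.lr_plus, 2),
                        "LR-": _round_half_even(tm.lr_minus, 2),
                        "PPV (%)": _round_half_even(tm.ppv, 1),
                        "NPV (%)": _round_half_even(tm.npv, 1),
                    }
                )
        path = outdir / "threshold_metrics.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)

        cal_rows = []
        for (model_id, sex), res in sorted(results.strata.items()):
            for label, cal in sorted(res.calibration.items()):
                for rec in cal.groups.to_dict("records"):
                    cal_rows.append(
                        {
                            "model_id": model_id,
                            "sex": sex,
                            "assumption": label,
                            "decile": int(rec["group"]),
                            "n": int(rec["n"]),
                            "mean_predicted": repr(float(rec["mean_predicted"])),
                            "observed_pct": _round_half_even(
                                100.0 * rec["observed_prop"], 2
                            ),
                        }
                    )
        path = outdir / "calibration.csv"
        pd.DataFrame(cal_rows).to_csv(path, index=False)
        written.append(path)

        summary = results.summary().copy()
        for col in summary.columns:
            if col.startswith("auc") or col == "harrell_c":
                summary[col] = summary[col].map(
                    lambda v: _round_half_even(v, 2) if pd.notna(v) else ""
                )
        path = outdir / "summary.csv"
        summary.to_csv(path, index=False)
        written.append(path)

    if "json" in formats:
        payload: dict[str, Any] = {"provenance": results.provenance, "strata": {}}
        for (model_id, sex), res in sorted(results.strata.items()):
            entry: dict[str, Any] = {
                "n": res.n,
                "n_events": res.n_events,
                "applicable_fraction": res.applicable_fraction,
                "note": res.note,
            }
            if res.discrimination is not None:
                d = res.discrimination
                entry["auc"] = {
                    "auc": d.auc, "ci_low": d.ci_low, "ci_high": d.ci_high,
                    "se": d.se, "n": d.n, "n_events": d.n_events,
                }
            if res.harrell_c is not None:
                entry["harrell_c"] = res.harrell_c
            entry["thresholds"] = {
                f"{q:g}": {
                    "cutoff": tm.cutoff, "tp": tm.tp, "fp": tm.fp,
                    "tn": tm.tn, "fn": tm.fn,
                    "sensitivity": tm.sensitivity, "specificity": tm.specificity,
                    "lr_plus": tm.lr_plus, "lr_minus": tm.lr_minus,
                    "ppv": tm.ppv, "npv": tm.npv,
                }
                for q, tm in sorted(res.thresholds.items())
            }
            entry["calibration"] = {
                label: {
                    "hl_chi2": cal.hl_chi2,
                    "hl_df": cal.hl_df,
                    "hl_p": cal.hl_p,
                    "groups": cal.groups.to_dict("records"),
                }
                for label, cal in sorted(res.calibration.items())
            }
            payload["strata"][f"{model_id}|{sex}"] = entry
        path = outdir / "summary.json"
        path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=float))
        written.append(path)

    return written
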