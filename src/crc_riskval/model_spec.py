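"""Declarative risk-model specifications and scoring engines.

A published colorectal-cancer risk model is represented as a :class:`ModelSpec`:
a list of covariate definitions, a list of weighted terms, and the baseline
quantities its functional form needs to turn a linear predictor into an
absolute risk over the model's native horizon. Four functional families are
supported, covering the published models this machinery validates:

``logistic``
    risk = expit(intercept + lp), lp the weighted covariate sum.
``cox``
    risk = 1 − S0(t)^exp(lp − mean_lp), with S0(t) the baseline survival at
    the native horizon and mean_lp the development-cohort mean linear
    predictor used for centering.
``points``
    integer points summed over matched categories, mapped to risk through a
    non-decreasing step function.
``rr_product``
    risk = min(1, baseline_risk × Π relative risks); coefficients are
    log-relative-risks so the product is exp(lp). The baseline absolute risk
    is configurable because population-average baselines are often not
    published alongside such consensus scores.

Scoring is provided both per-record (reference semantics) and vectorised over
a cohort ``DataFrame`` (used by the pipeline); the two agree exactly and this
is asserted in the test suite.
"""

from __future__ import annotations

import json
import math
import pathlib
from typing import Any, Iterable, Literal, Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "CovariateDefinition",
    "Transform",
    "TermSpec",
    "ModelSpec",
    "MissingCovariateError",
    "InapplicableRecordError",
    "validate_model_spec",
    "linear_predictor",
    "linear_predictor_frame",
    "absolute_risk",
    "absolute_risk_frame",
    "applicability",
    "applicability_frame",
    "drop_terms",
    "score_cohort",
    "load_model_spec",
    "save_model_spec",
]

SCHEMA_VERSION = 1

Sex = Literal["male", "female"]


class MissingCovariateError(KeyError):
    """A record lacks a value required by a model term."""


class InapplicableRecordError(ValueError):
    """Risk requested for a record outside the model's applicable range."""


class CovariateDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    kind: Literal["continuous", "binary", "categorical"]
    levels: Optional[list[str]] = None
    unit: Optional[str] = None
    reference_level: Optional[str] = None

    @model_validator(mode="after")
    def _check_levels(self) -> "CovariateDefinition":
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical covariate {self.name!r} needs levels")
            if self.reference_level is not None and self.reference_level not in self.levels:
                raise ValueError(
                    f"reference_level {self.reference_level!r} not among levels of {self.name!r}"
                )
        elif self.levels:
            raise ValueError(f"{self.kind} covariate {self.name!r} must not declare levels")
        return self


class Transform(BaseModel):
    """One step of a transform chain applied to a continuous covariate value."""

    model_config = ConfigDict(frozen=True)

    op: Literal["identity", "log", "center", "scale", "indicator"]
    param: Optional[float | str] = None

    @model_validator(mode="after")
    def _check_param(self) -> "Transform":
        if self.op in ("center", "scale", "indicator") and self.param is None:
            raise ValueError(f"transform {self.op!r} requires a parameter")
        if self.op == "scale" and float(self.param) == 0.0:
            raise ValueError("scale divisor must be nonzero")
        return self

    def apply(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.op == "identity":
            return x
        if self.op == "log":
            return np.log(x)
        if self.op == "center":
            return x - float(self.param)
        if self.op == "scale":
            return x / float(self.param)
        # indicator
        return (np.asarray(x) == self.param).astype(float) if isinstance(x, np.ndarray) else float(x == self.param)


class TermSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    covariate: str
    level: Optional[str] = None
    coefficient: float
    transforms: list[Transform] = []


class ModelSpec(BaseModel):
    """Declarative description of one published risk model."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = SCHEMA_VERSION
    model_id: str
    outcome: Literal["CRC", "colon"] = "CRC"
    form: Literal["logistic", "cox", "points", "rr_product"]
    native_horizon_years: float
    intercept: Optional[float] = None
    baseline_survival: Optional[float] = None
    mean_linear_predictor: Optional[float] = None
    baseline_risk: Optional[float] = None
    points_to_risk: Optional[list[tuple[int, float]]] = None
    covariates: list[CovariateDefinition]
    terms: list[TermSpec]
    applicable_sexes: list[Sex] = ["male", "female"]
    applicable_age_range: Optional[tuple[float, float]] = None

    # -- invariants ---------------------------------------------------------

    @field_validator("native_horizon_years")
    @classmethod
    def _horizon_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("native_horizon_years must be positive")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        required = {
            "logistic": ("intercept",),
            "cox": ("baseline_survival",),
            "points": ("points_to_risk",),
            "rr_product": ("baseline_risk",),
        }[self.form]
        allowed = set(required) | ({"mean_linear_predictor"} if self.form == "cox" else set())
        for field in ("intercept", "baseline_survival", "mean_linear_predictor",
                      "baseline_risk", "points_to_risk"):
            value = getattr(self, field)
            if field in required and value is None:
                raise ValueError(f"{self.form} model {self.model_id!r} requires {field}")
            if value is not None and field not in allowed:
                raise ValueError(f"{self.form} model {self.model_id!r} must not set {field}")
        if self.baseline_survival is not None and not (0.0 < self.baseline_survival <= 1.0):
            raise ValueError("baseline_survival must lie in (0, 1]")
        if self.baseline_risk is not None and not (0.0 <= self.baseline_risk < 1.0):
            raise ValueError("baseline_risk must lie in [0, 1)")
        if self.points_to_risk is not None:
            pts = [p for p, _ in self.points_to_risk]
            risks = [r for _, r in self.points_to_risk]
            if sorted(pts) != pts or len(set(pts)) != len(pts):
                raise ValueError("points_to_risk breakpoints must be strictly increasing")
            if any(b < a for a, b in zip(risks, risks[1:])):
                raise ValueError("points_to_risk must be non-decreasing in points")
            if any(not 0.0 <= r <= 1.0 for r in risks):
                raise ValueError("points_to_risk risks must lie in [0, 1]")
        if self.applicable_age_range is not None:
            lo, hi = self.applicable_age_range
            if not lo < hi:
                raise ValueError("applicable_age_range lower bound must be below upper")
        if not self.applicable_sexes:
            raise ValueError("applicable_sexes must be non-empty")

        by_name = {c.name: c for c in self.covariates}
        if len(by_name) != len(self.covariates):
            raise ValueError("duplicate covariate names")
        for term in self.terms:
            cov = by_name.get(term.covariate)
            if cov is None:
                raise ValueError(f"term references unknown covariate {term.covariate!r}")
            if cov.kind == "categorical":
                if term.level is None:
                    raise ValueError(f"term on categorical {cov.name!r} needs a level")
                if term.level not in cov.levels:
                    raise ValueError(f"level {term.level!r} not declared for {cov.name!r}")
            elif term.level is not None:
                raise ValueError(f"term on {cov.kind} covariate {cov.name!r} must not set level")
            if self.form == "points" and term.coefficient != int(term.coefficient):
                raise ValueError("points-form coefficients must be integers")
        return self

    # -- helpers ------------------------------------------------------------

    def covariate(self, name: str) -> CovariateDefinition:
        for cov in self.covariates:
            if cov.name == name:
                return cov
        raise KeyError(name)

    @property
    def term_covariates(self) -> list[str]:
        """Covariate names actually referenced by terms (deduplicated, ordered)."""
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.covariate, None)
        return list(seen)


def validate_model_spec(spec: ModelSpec) -> ModelSpec:
    """Re-run every structural invariant and return the validated spec."""
    return ModelSpec.model_validate(spec.model_dump())


# ---------------------------------------------------------------------------
# scoring — per record
# ---------------------------------------------------------------------------

def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value == ""


def _term_value(spec: ModelSpec, term: TermSpec, record: Mapping[str, Any]) -> float:
    try:
        value = record[term.covariate]
    except (KeyError, IndexError):
        raise MissingCovariateError(term.covariate) from None
    if _is_missing(value):
        raise MissingCovariateError(term.covariate)
    cov = spec.covariate(term.covariate)
    if cov.kind == "categorical":
        return 1.0 if str(value) == term.level else 0.0
    if cov.kind == "binary":
        return 1.0 if bool(value) else 0.0
    x = float(value)
    for tr in term.transforms:
        x = tr.apply(x)
    return x


def linear_predictor(spec: ModelSpec, record: Mapping[str, Any]) -> float:
    """Weighted covariate sum (integer point total for points-form models).

    Raises :class:`MissingCovariateError` when the record lacks a required
    value — callers route such records to complete-case handling.
    """
    return float(sum(term.coefficient * _term_value(spec, term, record) for term in spec.terms))


def _risk_from_lp(spec: ModelSpec, lp: np.ndarray | float) -> np.ndarray | float:
    if spec.form == "logistic":
        from scipy.special import expit

        return expit(spec.intercept + lp)
    if spec.form == "cox":
        mean_lp = spec.mean_linear_predictor or 0.0
        return 1.0 - spec.baseline_survival ** np.exp(lp - mean_lp)
    if spec.form == "rr_product":
        return np.minimum(1.0, spec.baseline_risk * np.exp(lp))
    # points: step lookup — risk of the greatest breakpoint ≤ points
    pts = np.array([p for p, _ in spec.points_to_risk])
    risks = np.array([r for _, r in spec.points_to_risk])
    idx = np.clip(np.searchsorted(pts, lp, side="right") - 1, 0, len(pts) - 1)
    return risks[idx]


def applicability(spec: ModelSpec, record: Mapping[str, Any]) -> bool:
    """Advisory flag: sex within the model's target sexes and age within the
    declared range. Deliberately not a hard filter — male-derived models are
    routinely scored on women, flagged rather than blocked."""
    if record["sex"] not in spec.applicable_sexes:
        return False
    if spec.applicable_age_range is not None:
        lo, hi = spec.applicable_age_range
        if not lo <= float(record["age"]) <= hi:
            return False
    return True


def absolute_risk(spec: ModelSpec, record: Mapping[str, Any], *, strict: bool = True) -> float:
    """Absolute risk over the model's native horizon for one record."""
    if strict and not applicability(spec, record):
        raise InapplicableRecordError(
            f"record outside applicability of {spec.model_id!r}"
        )
    lp = linear_predictor(spec, record)
    return float(_risk_from_lp(spec, lp))


def drop_terms(spec: ModelSpec, names: Iterable[str]) -> ModelSpec:
    """Remove every term on the named covariates (sensitivity analyses such as
    dropping aspirin/NSAID/hormonal terms or the deprivation term)."""
    names = list(names)
    present = set(spec.term_covariates)
    unknown = [n for n in names if n not in present]
    if unknown:
        raise KeyError(f"unknown term name(s): {unknown}")
    kept = [t for t in spec.terms if t.covariate not in set(names)]
    return spec.model_copy(update={"terms": kept})


# ---------------------------------------------------------------------------
# scoring — vectorised over a cohort frame
# ---------------------------------------------------------------------------

def _complete_mask(spec: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(cohort), dtype=bool)
    for name in spec.term_covariates:
        if name not in cohort.columns:
            mask[:] = False
            return mask
        col = cohort[name]
        missing = col.isna().to_numpy()
        if col.dtype == object:
            missing |= (col == "").to_numpy()
        mask &= ~missing
    return mask


def linear_predictor_frame(spec: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    """Vectorised linear predictor; NaN where the record is incomplete."""
    complete = _complete_mask(spec, cohort)
    lp = np.zeros(len(cohort))
    for term in spec.terms:
        cov = spec.covariate(term.covariate)
        col = cohort[term.covariate] if term.covariate in cohort.columns else pd.Series(
            np.nan, index=cohort.index
        )
        if cov.kind == "categorical":
            x = (col.astype("string") == term.level).to_numpy(dtype=float)
        elif cov.kind == "binary":
            x = col.fillna(0).astype(float).to_numpy()
            x = (x != 0).astype(float)
        else:
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            for tr in term.transforms:
                x = tr.apply(x)
        lp += term.coefficient * np.nan_to_num(x, nan=0.0)
    lp[~complete] = np.nan
    return lp


def applicability_frame(spec: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    ok = cohort["sex"].isin(spec.applicable_sexes).to_numpy()
    if spec.applicable_age_range is not None:
        lo, hi = spec.applicable_age_range
        age = pd.to_numeric(cohort["age"], errors="coerce").to_numpy(dtype=float)
        ok &= (age >= lo) & (age <= hi)
    return ok


def absolute_risk_frame(spec: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    lp = linear_predictor_frame(spec, cohort)
    risk = np.full(len(cohort), np.nan)
    good = ~np.isnan(lp)
    if good.any():
        risk[good] = _risk_from_lp(spec, lp[good])
    return risk


def score_cohort(spec: ModelSpec, cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every participant, returning one prediction row per record.

    Columns: ``participant_id, model_id, linear_predictor_or_points,
    native_risk, risk_5y, applicable, complete``. Incomplete records carry
    NaN risks; inapplicable ones are scored but flagged.
    """
    lp = linear_predictor_frame(spec, cohort)
    complete = ~np.isnan(lp)
    risk = np.full(len(cohort), np.nan)
    if complete.any():
        risk[complete] = _risk_from_lp(spec, lp[complete])
    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "model_id": spec.model_id,
            "linear_predictor_or_points": lp,
            "native_risk": risk,
            "risk_5y": np.where(
                complete & (spec.native_horizon_years == 5.0), risk, np.nan
            ),
            "applicable": applicability_frame(spec, cohort),
            "complete": complete,
        }
    )
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_model_spec(path: str | pathlib.Path) -> ModelSpec:
    """Load a model spec from a JSON or YAML file (extension decides)."""
    path = pathlib.Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ModelSpec.model_validate(data)


def save_model_spec(spec: ModelSpec, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    data = spec.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
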