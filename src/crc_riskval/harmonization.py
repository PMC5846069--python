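"""Cohort harmonization: derived variables, exclusions, missing-data policy.

The validation cohort is a plain :class:`pandas.DataFrame`, one row per
participant. Required columns:

====================  =====================================================
participant_id        unique identifier
age                   years at baseline
sex                   ``male`` / ``female``
followup_years        non-negative; time from baseline to end of follow-up
event                 0/1 incident colorectal cancer within follow-up
event_time_years      time to diagnosis, present iff event
event_subtype         ``colon`` / ``rectal`` / ``other`` (optional)
prior_diagnosis_codes semicolon-delimited ICD-9/10 codes (may be empty)
death_before_baseline 0/1 data-quality flag
censor_reason         e.g. ``admin`` or ``death`` when followup < 5 years
====================  =====================================================

Risk-factor columns are keyed by covariate name; missing is NaN (empty field
in CSV). Derivation rules build model-ready covariates from raw fields (for
example red meat as the sum of beef, pork and lamb servings); exclusion
operations implement the closed-cohort definition (no prior colorectal
cancer, alive at baseline, five years of potential follow-up with deaths
retained); the extreme-case imputation implements the bracketing analysis
for factors with more than 5% missing data.
"""

from __future__ import annotations

import math
from typing import Any, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .model_spec import CovariateDefinition, ModelSpec

__all__ = [
    "DerivationRule",
    "CodeSet",
    "derive_variables",
    "apply_exclusions",
    "exclude_surveillance",
    "complete_case_mask",
    "extreme_value_impute",
    "load_cohort_csv",
    "write_cohort_csv",
]


class CodeSet(BaseModel):
    """A labelled list of ICD-9/ICD-10 codes, matched by exact membership."""

    model_config = ConfigDict(frozen=True)

    label: str
    codes: list[str]

    @model_validator(mode="after")
    def _non_empty(self) -> "CodeSet":
        if not self.codes:
            raise ValueError(f"code set {self.label!r} must be non-empty")
        for code in self.codes:
            if not code or not code[0].isalnum():
                raise ValueError(f"invalid code {code!r} in {self.label!r}")
        return self


class DerivationRule(BaseModel):
    """One derived-variable rule: target column built from source columns.

    Combinators: ``sum`` (missing if any source missing), ``any`` (true if
    any source true; missing only when nothing is true and something is
    missing), ``threshold`` (categorise a numeric source at a cutoff),
    ``map`` (table lookup), ``constant`` (fill a fixed value — used for
    quantities absent from the raw data, such as a literature-mean
    medication duration).
    """

    model_config = ConfigDict(frozen=True)

    target: str
    sources: list[str] = []
    combinator: Literal["sum", "any", "threshold", "map", "constant"]
    cutoff: Optional[float] = None
    labels: Optional[tuple[str, str]] = None  # (below cutoff, at/above cutoff)
    table: Optional[dict[str, Any]] = None
    value: Optional[Any] = None

    @model_validator(mode="after")
    def _check(self) -> "DerivationRule":
        if self.combinator == "threshold":
            if self.cutoff is None or self.labels is None:
                raise ValueError("threshold rule needs cutoff and labels")
            if len(self.sources) != 1:
                raise ValueError("threshold rule takes exactly one source")
        if self.combinator == "map":
            if self.table is None or len(self.sources) != 1:
                raise ValueError("map rule needs a table and exactly one source")
        if self.combinator == "constant" and self.value is None:
            raise ValueError("constant rule needs a value")
        if self.combinator in ("sum", "any") and not self.sources:
            raise ValueError(f"{self.combinator} rule needs at least one source")
        return self


def _require_sources(cohort: pd.DataFrame, rule: DerivationRule) -> None:
    unknown = [s for s in rule.sources if s not in cohort.columns]
    if unknown:
        raise KeyError(f"rule {rule.target!r}: unknown source field(s) {unknown}")


def derive_variables(cohort: pd.DataFrame, rules: Sequence[DerivationRule]) -> pd.DataFrame:
    """Apply derivation rules in order; each adds or overwrites its target.

    Missingness propagates: any missing source makes the target missing,
    except under ``any`` where a single true source suffices.
    """
    out = cohort.copy()
    for rule in rules:
        _require_sources(out, rule)
        if rule.combinator == "constant":
            out[rule.target] = rule.value
            continue
        src = out[rule.sources]
        if rule.combinator == "sum":
            vals = src.apply(pd.to_numeric, errors="coerce")
            total = vals.sum(axis=1)
            total[vals.isna().any(axis=1)] = np.nan
            out[rule.target] = total
        elif rule.combinator == "any":
            truth = src.apply(lambda c: c.map(lambda v: False if _na(v) else bool(v)))
            any_true = truth.any(axis=1)
            any_missing = src.isna().any(axis=1)
            result = any_true.astype(object)
            result[~any_true & any_missing] = np.nan
            out[rule.target] = result
        elif rule.combinator == "threshold":
            x = pd.to_numeric(src.iloc[:, 0], errors="coerce")
            lo, hi = rule.labels
            cat = pd.Series(np.where(x >= rule.cutoff, hi, lo), index=out.index, dtype=object)
            cat[x.isna()] = np.nan
            out[rule.target] = cat
        else:  # map
            x = src.iloc[:, 0]
            mapped = x.map(lambda v: rule.table.get(str(v), np.nan) if not _na(v) else np.nan)
            out[rule.target] = mapped
    return out


def _na(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _codes_column(cohort: pd.DataFrame) -> pd.Series:
    if "prior_diagnosis_codes" not in cohort.columns:
        return pd.Series("", index=cohort.index)
    return cohort["prior_diagnosis_codes"].fillna("")


def _has_code(cohort: pd.DataFrame, codeset: CodeSet) -> np.ndarray:
    wanted = set(codeset.codes)
    col = _codes_column(cohort)
    return col.map(
        lambda s: bool(wanted.intersection(c.strip() for c in str(s).split(";") if c.strip()))
    ).to_numpy(dtype=bool)


def apply_exclusions(
    cohort: pd.DataFrame,
    prior_crc: CodeSet,
    require_5y: bool = True,
) -> pd.DataFrame:
    """Closed-cohort exclusion pipeline.

    Removes, in order: participants with a prior colorectal-cancer code,
    records with a death date before baseline, and — when ``require_5y`` —
    participants whose follow-up ended before five years for any reason other
    than death (deaths are retained to reflect clinical application of the
    scores). Step counts are recorded in ``DataFrame.attrs['exclusion_flow']``.
    """
    flow = {"total": int(len(cohort))}
    keep = cohort

    prior = _has_code(keep, prior_crc)
    flow["prior_crc"] = int(prior.sum())
    keep = keep.loc[~prior]

    if "death_before_baseline" in keep.columns:
        dead = keep["death_before_baseline"].fillna(0).astype(bool).to_numpy()
    else:
        dead = np.zeros(len(keep), dtype=bool)
    flow["death_before_baseline"] = int(dead.sum())
    keep = keep.loc[~dead]

    if require_5y:
        fup = pd.to_numeric(keep["followup_years"], errors="coerce").to_numpy(dtype=float)
        short = fup < 5.0
        if "censor_reason" in keep.columns:
            short &= (keep["censor_reason"].fillna("") != "death").to_numpy()
        flow["no_5y_followup"] = int(short.sum())
        keep = keep.loc[~short]
    else:
        flow["no_5y_followup"] = 0

    flow["retained"] = int(len(keep))
    keep = keep.copy()
    keep.attrs["exclusion_flow"] = flow
    return keep


def exclude_surveillance(cohort: pd.DataFrame, polyp_ibd: CodeSet) -> pd.DataFrame:
    """Drop participants with a prior colorectal polyp or IBD diagnosis, who
    would likely already be in a colonoscopic surveillance programme."""
    flagged = _has_code(cohort, polyp_ibd)
    out = cohort.loc[~flagged].copy()
    out.attrs = dict(cohort.attrs)
    out.attrs["surveillance_removed"] = int(flagged.sum())
    return out


def complete_case_mask(cohort: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """True where every covariate referenced by the model's terms is observed.

    Computed per model, so the analysable sample size varies between scores.
    """
    from .model_spec import _complete_mask

    return _complete_mask(spec, cohort)


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile of observed values: x_(⌈pct/100·n⌉)."""
    x = np.sort(values)
    k = max(1, math.ceil(pct / 100.0 * len(x)))
    return float(x[k - 1])


def extreme_value_impute(
    cohort: pd.DataFrame,
    covariates: Sequence[CovariateDefinition],
    threshold_pct: float = 5.0,
    direction: Literal["high", "low"] = "high",
) -> pd.DataFrame:
    """Extreme-case imputation for factors with substantial missingness.

    For each listed factor whose missing fraction exceeds ``threshold_pct``
    percent: continuous missing values are set to the observed 90th
    (``high``) or 10th (``low``) nearest-rank percentile; dichotomous missing
    values are set present (``high``) or absent (``low``). Factors at or
    below the threshold, multi-level categorical factors, and all observed
    values are untouched.
    """
    out = cohort.copy()
    out.attrs = dict(cohort.attrs)
    imputed: dict[str, Any] = {}
    for cov in covariates:
        if cov.name not in out.columns or cov.kind == "categorical":
            continue
        col = out[cov.name]
        missing = col.isna()
        if len(col) == 0 or 100.0 * missing.mean() <= threshold_pct:
            continue
        if cov.kind == "continuous":
            observed = pd.to_numeric(col[~missing], errors="coerce").dropna().to_numpy(float)
            if len(observed) == 0:
                continue
            pct = 90.0 if direction == "high" else 10.0
            fill: Any = _nearest_rank_percentile(observed, pct)
        else:  # binary
            fill = 1 if direction == "high" else 0
        out.loc[missing, cov.name] = fill
        imputed[cov.name] = fill
    out.attrs["extreme_imputation"] = {"direction": direction, "filled": imputed}
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty field = missing; codes ';'-delimited)."""
    df = pd.read_csv(path, dtype={"prior_diagnosis_codes": str, "sex": str})
    if "prior_diagnosis_codes" in df.columns:
        df["prior_diagnosis_codes"] = df["prior_diagnosis_codes"].fillna("")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
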