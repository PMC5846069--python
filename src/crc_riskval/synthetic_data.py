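"""Synthetic cohort generator emulating a UK-Biobank-style validation cohort.

Generates per-participant risk factors matching configurable marginal
distributions (defaults reproduce the published baseline characteristics of
the validation population: age ~ truncated normal with mean 56.4 and SD 8.1
on 40–70, 45.5% male, 10.8% family history of colorectal cancer, smoking
54.3/34.4/10.7% never/former/current, the four BMI-category frequencies,
physical activity ~ normal(28.3, 5.5) MET-h/day, 22.3% eating red meat at
least three times a week, and so on), then drives outcomes with a known
generative risk model:

1. each participant's raw 5-year risk comes from ``true_model``;
2. a single multiplicative calibration constant rescales risks so the
   expected incidence equals ``target_incidence_5y`` (0.46% by default);
3. incident events are Bernoulli draws against that risk, with event times
   uniform on (0, 5] — the constant-incidence pattern observed over the
   validation follow-up window;
4. a configurable fraction of non-events is censored before five years
   (reason ``admin``), and a small fraction dies within five years (reason
   ``death``, retained by the closed-cohort rule);
5. missingness is injected completely at random per factor, never touching
   outcome or follow-up.

Factors are sampled independently except for declared age tilts (by default
current smoking falls and NSAID/aspirin use rises with age), since only
marginals are published and pain-relief medication use is known to rise with
age. The generator returns both the cohort and a truth table (true risk,
latent uniform draw, uncensored event time) as an oracle side-channel for
tests; the truth table must never be used for validation itself.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats
from scipy.special import expit, logit

from .model_spec import ModelSpec, absolute_risk_frame
from .presets import default_true_model

__all__ = [
    "FactorSpec",
    "AgeTilt",
    "SyntheticCohortConfig",
    "generate_cohort",
    "inject_missingness",
    "perturbed_model",
]


class FactorSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["truncnorm", "normal", "bernoulli", "categorical"]
    mean: Optional[float] = None
    sd: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    p: Optional[float] = None
    levels: Optional[list[str]] = None
    probs: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "FactorSpec":
        if self.kind in ("truncnorm", "normal"):
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError("normal factors need mean and positive sd")
            if self.kind == "truncnorm" and (self.low is None or self.high is None):
                raise ValueError("truncnorm needs low and high bounds")
        if self.kind == "bernoulli":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("bernoulli needs p in [0, 1]")
        if self.kind == "categorical":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise ValueError("categorical needs matching levels and probs")
            if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-6:
                raise ValueError("categorical probs must be non-negative and sum to 1")
        return self


class AgeTilt(BaseModel):
    """Logistic dependence of a factor on age: the log-odds of the factor
    (or of one categorical level) shifts by ``per_sd`` per SD of age."""

    model_config = ConfigDict(frozen=True)

    factor: str
    level: Optional[str] = None
    per_sd: float


def _table2_factors() -> dict[str, FactorSpec]:
    return {
        "age": FactorSpec(kind="truncnorm", mean=56.4, sd=8.1, low=40.0, high=70.0),
        "sex": FactorSpec(kind="categorical", levels=["female", "male"],
                          probs=[0.545, 0.455]),
        "family_history": FactorSpec(kind="bernoulli", p=0.108),
        "smoking": FactorSpec(kind="categorical",
                              levels=["never", "former", "current"],
                              probs=[0.546, 0.346, 0.108]),
        "bmi_category": FactorSpec(kind="categorical",
                                   levels=["<20", "20-24.9", "25-29.9", ">=30"],
                                   probs=[0.023, 0.308, 0.425, 0.244]),
        "physical_activity": FactorSpec(kind="normal", mean=28.3, sd=5.5),
        "red_meat": FactorSpec(kind="bernoulli", p=0.223),
        "alcohol": FactorSpec(kind="categorical",
                              levels=["non", "former", "current"],
                              probs=[0.042, 0.037, 0.921]),
        "aspirin": FactorSpec(kind="bernoulli", p=0.151),
        "nsaid": FactorSpec(kind="bernoulli", p=0.315),
    }


def _default_missingness() -> dict[str, float]:
    return {
        "physical_activity": 0.117,
        "family_history": 0.040,
        "smoking": 0.005,
        "bmi_category": 0.005,
        "red_meat": 0.013,
        "alcohol": 0.002,
        "aspirin": 0.011,
        "nsaid": 0.010,
    }


class SyntheticCohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = 100_000
    seed: int = 0
    factors: dict[str, FactorSpec] = Field(default_factory=_table2_factors)
    age_tilts: list[AgeTilt] = Field(
        default_factory=lambda: [
            AgeTilt(factor="smoking", level="current", per_sd=-0.25),
            AgeTilt(factor="nsaid", per_sd=0.30),
            AgeTilt(factor="aspirin", per_sd=0.55),
        ]
    )
    true_model: ModelSpec = Field(default_factory=default_true_model)
    target_incidence_5y: float = 0.0046
    censoring_fraction: float = 0.0
    death_fraction: float = 0.005
    colon_fraction: float = 0.72
    missingness: dict[str, float] = Field(default_factory=_default_missingness)
    prior_condition_rates: dict[str, float] = Field(
        default_factory=lambda: {"prior_crc": 0.0046, "death_before_baseline": 6e-6,
                                 "polyp": 0.03, "ibd": 0.007}
    )

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCohortConfig":
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for label, rate in list(self.missingness.items()) + list(
            self.prior_condition_rates.items()
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {label!r} must lie in [0, 1]")
        for name, frac in (
            ("target_incidence_5y", self.target_incidence_5y),
            ("censoring_fraction", self.censoring_fraction),
            ("death_fraction", self.death_fraction),
            ("colon_fraction", self.colon_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        return self


def _sample_factor(spec: FactorSpec, n: int, generator: np.random.Generator):
    if spec.kind == "truncnorm":
        a = (spec.low - spec.mean) / spec.sd
        b = (spec.high - spec.mean) / spec.sd
        return stats.truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=n,
                                   random_state=generator)
    if spec.kind == "normal":
        return generator.normal(spec.mean, spec.sd, size=n)
    if spec.kind == "bernoulli":
        return (generator.random(n) < spec.p).astype(int)
    return generator.choice(np.array(spec.levels, dtype=object), size=n, p=spec.probs)


def _apply_tilt(
    values, spec: FactorSpec, tilt: AgeTilt, z_age: np.ndarray,
    generator: np.random.Generator
):
    """Re-draw a factor with an age-dependent probability, keeping the
    configured marginal at the age mean."""
    if spec.kind == "bernoulli":
        p = expit(logit(spec.p) + tilt.per_sd * z_age)
        return (generator.random(len(z_age)) < p).astype(int)
    if spec.kind == "categorical":
        i = spec.levels.index(tilt.level)
        base = np.array(spec.probs)
        p_level = expit(logit(base[i]) + tilt.per_sd * z_age)
        probs = np.tile(base, (len(z_age), 1))
        others = np.delete(np.arange(len(base)), i)
        scale = (1.0 - p_level) / (1.0 - base[i])
        probs[:, others] = base[others] * scale[:, None]
        probs[:, i] = p_level
        u = generator.random(len(z_age))
        cum = np.cumsum(probs, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        return np.array(spec.levels, dtype=object)[idx]
    raise ValueError(f"age tilt not supported for {spec.kind} factors")


def generate_cohort(config: SyntheticCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, truth). Deterministic given the config and seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    columns: dict[str, Any] = {"participant_id": np.arange(1, n + 1)}

    age_spec = config.factors.get("age")
    tilted = {t.factor: t for t in config.age_tilts}
    for name, spec in config.factors.items():
        columns[name] = _sample_factor(spec, n, rng)
    if age_spec is not None and n > 0:
        z_age = (np.asarray(columns["age"], dtype=float) - age_spec.mean) / age_spec.sd
        for name, tilt in tilted.items():
            if name in config.factors:
                columns[name] = _apply_tilt(columns[name], config.factors[name],
                                            tilt, z_age, rng)

    cohort = pd.DataFrame(columns)

    # outcome generation from the true model, rescaled to the target incidence
    if n > 0:
        raw = absolute_risk_frame(config.true_model, cohort)
        mean_raw = float(np.mean(raw))
        scale = config.target_incidence_5y / mean_raw if mean_raw > 0 else 0.0
        true_risk = raw * scale
        if np.any(true_risk > 1.0):
            raise ValueError("incidence rescaling pushes a participant's risk above 1")
    else:
        true_risk = np.zeros(0)
    latent = rng.random(n)
    event = latent < true_risk
    event_time = rng.uniform(0.0, 5.0, size=n)
    event_time[event & (event_time == 0.0)] = 5.0  # uniform on (0, 5]

    followup = rng.uniform(5.0, 8.4, size=n)
    censor_reason = np.full(n, "", dtype=object)

    non_event_idx = np.flatnonzero(~event)
    n_cens = int(np.rint(config.censoring_fraction * n))
    n_death = int(np.rint(config.death_fraction * n))
    chosen = rng.choice(non_event_idx, size=min(n_cens + n_death, len(non_event_idx)),
                        replace=False) if len(non_event_idx) else np.array([], dtype=int)
    cens_idx, death_idx = chosen[:n_cens], chosen[n_cens:]
    followup[cens_idx] = rng.uniform(0.0, 5.0, size=len(cens_idx))
    censor_reason[cens_idx] = "admin"
    followup[death_idx] = rng.uniform(0.0, 5.0, size=len(death_idx))
    censor_reason[death_idx] = "death"

    subtype = np.full(n, "", dtype=object)
    colon = rng.random(n) < config.colon_fraction
    subtype[event & colon] = "colon"
    subtype[event & ~colon] = "rectal"

    # prior conditions, encoded as ICD codes
    codes = np.full(n, "", dtype=object)
    rates = config.prior_condition_rates
    prior_crc = rng.random(n) < rates.get("prior_crc", 0.0)
    polyp = rng.random(n) < rates.get("polyp", 0.0)
    ibd = rng.random(n) < rates.get("ibd", 0.0)
    for i in np.flatnonzero(prior_crc | polyp | ibd):
        parts = []
        if prior_crc[i]:
            parts.append("C18.4")
        if polyp[i]:
            parts.append("K63.5")
        if ibd[i]:
            parts.append("K51.0")
        codes[i] = ";".join(parts)

    cohort["prior_diagnosis_codes"] = codes
    cohort["death_before_baseline"] = (
        rng.random(n) < rates.get("death_before_baseline", 0.0)
    ).astype(int)
    cohort["followup_years"] = followup
    cohort["event"] = event.astype(int)
    cohort["event_time_years"] = np.where(event, event_time, np.nan)
    cohort["event_subtype"] = subtype
    cohort["censor_reason"] = censor_reason

    cohort = inject_missingness(cohort, config.missingness,
                                rng=np.random.default_rng(rng.integers(2**31)))

    truth = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "true_risk_5y": true_risk,
            "latent_draw": latent,
            "uncensored_event_time": event_time,
        }
    )
    return cohort, truth


_PROTECTED = {
    "participant_id", "followup_years", "event", "event_time_years",
    "event_subtype", "censor_reason", "death_before_baseline",
    "prior_diagnosis_codes",
}


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mask factor values completely at random at per-factor rates.

    Outcome, follow-up and identifier columns are never masked.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = cohort.copy()
    for name, rate in rates.items():
        if name not in out.columns or name in _PROTECTED or rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        col = out[name]
        if col.dtype != object and not pd.api.types.is_float_dtype(col):
            out[name] = col.astype(float)
        out.loc[mask, name] = np.nan
    return out


def perturbed_model(spec: ModelSpec, noise_sd: float, seed: int) -> ModelSpec:
    """Jitter term coefficients with independent Gaussian noise (structure,
    baselines and intercept unchanged). Used for ranking-recovery tests."""
    rng = np.random.default_rng(seed)
    terms = [
        t.model_copy(update={"coefficient": t.coefficient + rng.normal(0.0, noise_sd)})
        for t in spec.terms
    ]
    return spec.model_copy(
        update={"terms": terms, "model_id": f"{spec.model_id}_perturbed{seed}"}
    )
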