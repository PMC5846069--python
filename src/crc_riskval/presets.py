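"""Default code sets and a synthetic reference risk model.

The ICD code sets encode the standard colorectal-cancer definition
(ICD-9 153.0–153.9, 154.0, 154.1, 154.8; ICD-10 C18.0–C18.9, C19, C20,
C21.8) and a surveillance set (colorectal polyp, inflammatory bowel
disease).

``default_true_model`` returns a SYNTHETIC logistic risk model used as the
generative truth for simulated cohorts and as a stand-in spec in examples
and tests. Its coefficients are epidemiologically plausible (risk rising
with age, male sex, family history, smoking history, adiposity and red-meat
intake) and are scaled so the linear predictor has standard deviation near
0.66 on the default cohort (age is truncated to 40–70, so its effective SD
is 6.8, not 8.1), which for a rare outcome yields a discrimination of
roughly AUC ≈ 0.67. It is NOT a transcription of any published model;
real published coefficient sets are user-supplied spec files.
"""

from __future__ import annotations

from .harmonization import CodeSet
from .model_spec import CovariateDefinition, ModelSpec, TermSpec, Transform

__all__ = [
    "crc_code_set",
    "surveillance_code_set",
    "default_true_model",
]


def crc_code_set() -> CodeSet:
    icd9 = [f"153.{i}" for i in range(10)] + ["154.0", "154.1", "154.8"]
    icd10 = [f"C18.{i}" for i in range(10)] + ["C19", "C20", "C21.8"]
    return CodeSet(label="colorectal cancer", codes=icd9 + icd10)


def surveillance_code_set() -> CodeSet:
    # colorectal polyp (K63.5, 211.3) and IBD (Crohn's K50.x, UC K51.x)
    return CodeSet(
        label="polyp or IBD",
        codes=["K63.5", "211.3", "K50", "K50.0", "K50.1", "K50.9",
               "K51", "K51.0", "K51.9", "555", "556"],
    )


def default_true_model() -> ModelSpec:
    """Synthetic logistic 5-year risk model (generative truth for simulation)."""
    covariates = [
        CovariateDefinition(name="age", kind="continuous", unit="years"),
        CovariateDefinition(name="sex", kind="categorical",
                            levels=["female", "male"], reference_level="female"),
        CovariateDefinition(name="family_history", kind="binary"),
        CovariateDefinition(name="smoking", kind="categorical",
                            levels=["never", "former", "current"],
                            reference_level="never"),
        CovariateDefinition(name="bmi_category", kind="categorical",
                            levels=["<20", "20-24.9", "25-29.9", ">=30"],
                            reference_level="20-24.9"),
        CovariateDefinition(name="red_meat", kind="binary"),
    ]
    terms = [
        TermSpec(covariate="age", coefficient=0.088,
                 transforms=[Transform(op="center", param=56.4)]),
        TermSpec(covariate="sex", level="male", coefficient=0.35),
        TermSpec(covariate="family_history", coefficient=0.35),
        TermSpec(covariate="smoking", level="former", coefficient=0.30),
        TermSpec(covariate="smoking", level="current", coefficient=0.15),
        TermSpec(covariate="bmi_category", level="25-29.9", coefficient=0.12),
        TermSpec(covariate="bmi_category", level=">=30", coefficient=0.22),
        TermSpec(covariate="red_meat", coefficient=0.15),
    ]
    return ModelSpec(
        model_id="synthetic_logistic_5y",
        outcome="CRC",
        form="logistic",
        native_horizon_years=5.0,
        intercept=-5.4,
        covariates=covariates,
        terms=terms,
    )
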