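import numpy as np
import pandas as pd
import pytest

from crc_riskval import (
    CovariateDefinition,
    ModelSpec,
    TermSpec,
    Transform,
)


def _base_covariates():
    return [
        CovariateDefinition(name="age", kind="continuous", unit="years"),
        CovariateDefinition(name="sex", kind="categorical",
                            levels=["female", "male"], reference_level="female"),
        CovariateDefinition(name="smoking", kind="categorical",
                            levels=["never", "former", "current"],
                            reference_level="never"),
        CovariateDefinition(name="family_history", kind="binary"),
    ]


@pytest.fixture
def toy_logistic_spec():
    """Logistic model: 0.08 per year of age above 40, 0.4 for male sex."""
    return ModelSpec(
        model_id="toy_logistic",
        form="logistic",
        native_horizon_years=10.0,
        intercept=-6.0,
        covariates=_base_covariates(),
        terms=[
            TermSpec(covariate="age", coefficient=0.08,
                     transforms=[Transform(op="center", param=40.0)]),
            TermSpec(covariate="sex", level="male", coefficient=0.4),
        ],
    )


@pytest.fixture
def toy_cox_spec():
    return ModelSpec(
        model_id="toy_cox",
        form="cox",
        native_horizon_years=10.0,
        baseline_survival=0.99,
        mean_linear_predictor=0.5,
        covariates=_base_covariates(),
        terms=[
            TermSpec(covariate="age", coefficient=0.01,
                     transforms=[Transform(op="center", param=40.0)]),
            TermSpec(covariate="family_history", coefficient=0.3),
        ],
    )


@pytest.fixture
def toy_points_spec():
    return ModelSpec(
        model_id="toy_points",
        form="points",
        native_horizon_years=10.0,
        points_to_risk=[(0, 0.001), (2, 0.005), (4, 0.02)],
        covariates=_base_covariates(),
        terms=[
            TermSpec(covariate="smoking", level="former", coefficient=1),
            TermSpec(covariate="smoking", level="current", coefficient=2),
            TermSpec(covariate="family_history", coefficient=2),
        ],
    )


@pytest.fixture
def toy_rr_spec():
    return ModelSpec(
        model_id="toy_rr",
        form="rr_product",
        native_horizon_years=10.0,
        baseline_risk=0.005,
        covariates=_base_covariates(),
        terms=[
            TermSpec(covariate="family_history", coefficient=np.log(1.8)),
            TermSpec(covariate="smoking", level="current", coefficient=np.log(1.2)),
        ],
    )


@pytest.fixture
def tiny_cohort():
    """Ten deterministic participants with a mix of sexes and outcomes."""
    rng = np.random.default_rng(7)
    n = 10
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": [45, 52, 60, 67, 41, 58, 63, 49, 55, 70],
            "sex": ["male", "female"] * 5,
            "smoking": ["never", "former", "current", "never", "former",
                        "never", "current", "former", "never", "former"],
            "family_history": [0, 1, 0, 0, 1, 0, 0, 1, 0, 1],
            "prior_diagnosis_codes": [""] * n,
            "death_before_baseline": [0] * n,
            "followup_years": [7.0] * n,
            "event": [0, 0, 1, 0, 0, 0, 1, 0, 0, 1],
            "event_time_years": [np.nan, np.nan, 2.5, np.nan, np.nan,
                                 np.nan, 4.0, np.nan, np.nan, 1.0],
            "event_subtype": ["", "", "colon", "", "", "", "rectal", "", "", "colon"],
            "censor_reason": [""] * n,
        }
    )
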