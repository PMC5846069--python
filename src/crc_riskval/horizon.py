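"""Risk-horizon conversion between native (5/10/20-year) and 5-year risks.

Published models state absolute risk over different horizons; comparing them
on a common 5-year horizon requires an assumption about how risk accrues
over time. Two assumptions are supported:

``constant``
    the event hazard is flat, so cumulative hazard scales linearly with
    time: H(t) ∝ t.
``doubling``
    the hazard doubles every ``doubling_period_years`` (default 5), in line
    with incidence rising with age. On the cumulative-hazard scale the
    per-block hazards form a geometric series with ratio 2, extended to
    non-integer block counts by continuous compounding: H(t) ∝ 2^(t/d) − 1.
    A 10-year risk therefore maps to 5 years with hazard fraction
    1/(2²−1) = 1/3, and a 20-year risk with 1/(2⁴−1) = 1/15.

Both are computed on the cumulative-hazard scale H = −log(1−p) by default,
which keeps converted probabilities in [0, 1) for any input and agrees with
simple probability scaling (p₅ = p₁₀/2 or p₁₀/3) to first order at the sub-1%
risks typical of 5-year colorectal-cancer incidence. Probability-scale
arithmetic is available via ``scale="probability"`` since published analyses
rarely print which rule they used.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["HazardAssumption", "convert_risk", "convert_predictions"]


class HazardAssumption(BaseModel):
    model_config = ConfigDict(frozen=True)

    shape: Literal["constant", "doubling"]
    doubling_period_years: float = 5.0

    @model_validator(mode="after")
    def _positive_period(self) -> "HazardAssumption":
        if self.doubling_period_years <= 0:
            raise ValueError("doubling_period_years must be positive")
        return self

    def hazard_fraction(self, native: float, target: float) -> float:
        """H(target)/H(native) under this hazard shape."""
        if self.shape == "constant":
            return target / native
        d = self.doubling_period_years
        return (2.0 ** (target / d) - 1.0) / (2.0 ** (native / d) - 1.0)


CONSTANT = HazardAssumption(shape="constant")
DOUBLING = HazardAssumption(shape="doubling")


def convert_risk(
    p,
    native_horizon: float,
    target_horizon: float,
    assumption: HazardAssumption,
    scale: Literal["hazard", "probability"] = "hazard",
):
    """Convert absolute risk ``p`` from the native to the target horizon.

    Accepts a scalar or array; requires 0 ≤ p < 1 and positive horizons.
    """
    arr = np.asarray(p, dtype=float)
    if native_horizon <= 0 or target_horizon <= 0:
        raise ValueError("horizons must be positive")
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("risk must lie in [0, 1)")
    frac = assumption.hazard_fraction(native_horizon, target_horizon)
    if scale == "probability":
        out = np.clip(arr * frac, 0.0, 1.0)
    else:
        h = -np.log1p(-arr)
        out = -np.expm1(-h * frac)
    return float(out) if np.isscalar(p) else out


def convert_predictions(
    predictions: pd.DataFrame,
    assumption: HazardAssumption,
    horizons: Mapping[str, float] | float,
    target_horizon: float = 5.0,
    force: bool = False,
    scale: Literal["hazard", "probability"] = "hazard",
) -> pd.DataFrame:
    """Fill ``risk_5y`` for every complete prediction row.

    ``horizons`` maps model_id to native horizon (or is a single horizon for
    a homogeneous batch). Models already stated at the target horizon pass
    through unchanged unless ``force`` — forcing re-derives even native
    5-year risks through the same conversion path so that every model is
    treated identically in cross-model comparisons.
    """
    out = predictions.copy()
    if isinstance(horizons, Mapping):
        native = out["model_id"].map(horizons).to_numpy(dtype=float)
    else:
        native = np.full(len(out), float(horizons))
    if np.any(np.isnan(native)):
        raise KeyError("native horizon missing for some model_id")
    risk = out["native_risk"].to_numpy(dtype=float)
    converted = np.full(len(out), np.nan)
    ok = ~np.isnan(risk)
    for h in np.unique(native[ok]):
        sel = ok & (native == h)
        if h == target_horizon and not force:
            converted[sel] = risk[sel]
        else:
            converted[sel] = convert_risk(risk[sel], h, target_horizon, assumption, scale)
    out["risk_5y"] = converted
    return out
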