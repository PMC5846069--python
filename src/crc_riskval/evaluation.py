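"""Discrimination and calibration metrics for external validation.

Implements the metric set used to compare risk models head-to-head on a
common cohort:

* AUC as the Mann–Whitney concordance probability with midrank tie handling,
  with a DeLong confidence interval (Hanley–McNeil available as a fallback
  for very small samples);
* Harrell's C for open-cohort (censored) designs: concordant over comparable
  pairs, a pair being comparable when the shorter follow-up time ends in an
  event, score ties counting one half;
* threshold metrics (sensitivity, specificity, LR+, LR−, PPV, NPV) at
  population-fraction cutoffs — flag the top q of the population, with ties
  at the cutoff resolved in stable participant order so that exactly
  round(q·n) are flagged even for heavily tied point scores;
* decile calibration with a Hosmer–Lemeshow chi-square. Degrees of freedom
  equal the number of groups: nothing is re-estimated on validation data, so
  the development-setting g−2 convention does not apply;
* the age-threshold comparator rule (flag everyone at or above a screening
  age) expressed in the same sensitivity terms as the top-q% rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiscriminationResult",
    "ThresholdMetrics",
    "CalibrationResult",
    "auc",
    "harrell_c",
    "threshold_metrics",
    "metrics_from_rates",
    "calibration_table",
    "age_rule_sensitivity",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    se: float
    harrell_c: Optional[float] = None

    def __post_init__(self):
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("confidence interval must bracket the AUC")


@dataclass(frozen=True)
class ThresholdMetrics:
    q: float
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # %
    specificity: float  # %
    lr_plus: float
    lr_minus: float
    ppv: float  # %
    npv: float  # %


@dataclass(frozen=True)
class CalibrationResult:
    groups: pd.DataFrame  # columns: group, n, mean_predicted, observed, observed_prop
    hl_chi2: float
    hl_df: int
    hl_p: float


def _as_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return y


def auc(scores, outcomes, ci_method: str = "delong") -> DiscriminationResult:
    """Mann–Whitney AUC with midrank ties and a DeLong confidence interval.

    Requires at least one event and one non-event.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(outcomes)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC needs at least one event and one non-event")

    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    area = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    if ci_method == "delong":
        v10 = (r_all[:m] - r_pos) / n          # per-event placement values
        v01 = 1.0 - (r_all[m:] - r_neg) / m    # per-non-event placements
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        var = s10 / m + s01 / n
    elif ci_method == "hanley":
        q1 = area / (2.0 - area)
        q2 = 2.0 * area**2 / (1.0 + area)
        var = (area * (1 - area) + (m - 1) * (q1 - area**2) + (n - 1) * (q2 - area**2)) / (m * n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, area - _Z975 * se)
    hi = min(1.0, area + _Z975 * se)
    return DiscriminationResult(
        auc=float(area), ci_low=lo, ci_high=hi, n=m + n, n_events=m, se=se
    )


def harrell_c(scores, time, event) -> float:
    """Harrell's concordance for censored follow-up.

    A pair is comparable when the shorter observed time is an event (an event
    and a censoring at the same time are ordered event-first). Concordant
    when the earlier event carries the higher score; score ties count ½.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = _as_binary(event).astype(bool)
    n = len(s)
    concordant = 0.0
    ties = 0.0
    comparable = 0
    idx_events = np.flatnonzero(e)
    for start in range(0, len(idx_events), 512):
        chunk = idx_events[start : start + 512]
        ti = t[chunk][:, None]
        si = s[chunk][:, None]
        # j comparable with event i when t_i < t_j, or equal times with j censored
        mask = (ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :])
        comparable += int(mask.sum())
        concordant += float(((si > s[None, :]) & mask).sum())
        ties += float(((si == s[None, :]) & mask).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs (no events, or all events at the latest time)")
    return (concordant + 0.5 * ties) / comparable


def threshold_metrics(
    scores, outcomes, q: float, permissive: bool = False
) -> ThresholdMetrics:
    """Confusion-matrix metrics when flagging the top fraction ``q``.

    The cutoff is the empirical (1−q) quantile; exactly round(q·n) records
    are flagged, breaking ties at the cutoff in stable participant order.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(outcomes)
    n = len(s)
    if not (0.0 < q < 1.0 or (permissive and q == 1.0)):
        raise ValueError("q must lie in (0, 1)")
    k = n if q == 1.0 else int(np.rint(q * n))
    if k < 1:
        raise ValueError(f"q·n = {q * n:.3g} < 1: no records would be flagged")

    order = np.argsort(-s, kind="stable")
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:k]] = True
    cutoff = float(np.quantile(s, 1.0 - q)) if q < 1.0 else float(s.min())

    tp = int((flagged & (y == 1)).sum())
    fp = int((flagged & (y == 0)).sum())
    fn = int((~flagged & (y == 1)).sum())
    tn = int((~flagged & (y == 0)).sum())
    return _metrics_from_counts(q, cutoff, tp, fp, tn, fn)


def _metrics_from_counts(q, cutoff, tp, fp, tn, fn) -> ThresholdMetrics:
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    lr_plus = sens / (100.0 - spec) if spec < 100.0 else float("inf")
    lr_minus = (100.0 - sens) / spec if spec > 0.0 else float("inf")
    ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
    return ThresholdMetrics(
        q=q, cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        lr_plus=lr_plus, lr_minus=lr_minus, ppv=ppv, npv=npv,
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, n: int, n_events: int, q: float = float("nan")
) -> ThresholdMetrics:
    """Reconstruct the full metric set from published sensitivity/specificity.

    Useful for internal-consistency checks of printed validation tables:
    given sensitivity and specificity in percent plus the analysed n and
    event count, the implied confusion matrix determines LR+, LR−, PPV and
    NPV. Counts are rounded to the nearest integer.
    """
    events = n_events
    nonevents = n - n_events
    tp = int(round(sensitivity / 100.0 * events))
    tn = int(round(specificity / 100.0 * nonevents))
    fn = events - tp
    fp = nonevents - tn
    return _metrics_from_counts(q, float("nan"), tp, fp, tn, fn)


def calibration_table(pred_5y, outcomes, g: int = 10) -> CalibrationResult:
    """Decile calibration with a Hosmer–Lemeshow chi-square.

    Groups are equal-count quantile bins of predicted risk with tied
    predictions kept together. χ² = Σ (O−E)²/(E(1−p̄)) with E = n·p̄ per
    group; df equals the number of groups formed; p is the upper tail.
    """
    p = np.asarray(pred_5y, dtype=float)
    y = _as_binary(outcomes)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predictions must lie in [0, 1]")
    if np.unique(p).size == 1:
        bins = np.zeros(len(p), dtype=int)  # constant predictions: one group
    else:
        bins = pd.qcut(p, g, labels=False, duplicates="drop")
    df = pd.DataFrame({"bin": bins, "p": p, "y": y})
    grouped = df.groupby("bin", observed=True)
    table = grouped.agg(n=("y", "size"), mean_predicted=("p", "mean"), observed=("y", "sum"))
    table = table.reset_index(drop=True)
    table.insert(0, "group", np.arange(1, len(table) + 1))
    table["observed_prop"] = table["observed"] / table["n"]

    pbar = table["mean_predicted"].to_numpy()
    if np.any((pbar <= 0.0) | (pbar >= 1.0)):
        raise ValueError("a calibration group has mean predicted risk of exactly 0 or 1")
    expected = table["n"].to_numpy() * pbar
    chi2 = float((((table["observed"].to_numpy() - expected) ** 2)
                  / (expected * (1.0 - pbar))).sum())
    dof = len(table)
    return CalibrationResult(
        groups=table,
        hl_chi2=chi2,
        hl_df=dof,
        hl_p=float(stats.chi2.sf(chi2, dof)),
    )


def age_rule_sensitivity(cohort: pd.DataFrame, age_cutoff: float) -> pd.DataFrame:
    """Sensitivity of the age-threshold screening rule, by sex.

    Flags everyone aged at or above the cutoff at baseline and reports, per
    sex, the sensitivity for incident colorectal cancer and the flagged
    population fraction — the fair comparator for top-q% risk-score rules.
    """
    rows = []
    for sex, sub in cohort.groupby("sex", observed=True):
        age = pd.to_numeric(sub["age"], errors="coerce").to_numpy(float)
        y = _as_binary(sub["event"])
        flagged = age >= age_cutoff
        events = int(y.sum())
        sens = 100.0 * (flagged & (y == 1)).sum() / events if events else float("nan")
        rows.append(
            {
                "sex": sex,
                "age_cutoff": age_cutoff,
                "n": len(sub),
                "n_events": events,
                "flagged_fraction": float(flagged.mean()),
                "sensitivity": sens,
            }
        )
    return pd.DataFrame(rows)
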