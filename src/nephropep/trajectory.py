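"""Per-patient eGFR slope fitting and kidney-function labeling.

Progression under RAS-inhibitor treatment is read off each patient's eGFR
time course with ordinary least squares (eGFR ~ follow-up time), either over
the full follow-up period or per consecutive visit pair. The annualized
percentage slope is 100 × slope / (fitted eGFR at time zero); patients are
then labeled:

* discovery rule (percentage slope): < −10 %/yr → UNCONTROLLED,
  within [−5, +5] %/yr → CONTROLLED, otherwise EXCLUDED
  (losing 5–10 %/yr or gaining > 5 %/yr cannot be labeled with confidence);
* validation rule (absolute): a drop of > 10 mL/min/1.73 m² from baseline
  that also dips under 60 → UNCONTROLLED; a total loss under the cohort
  threshold (5 or 10) with eGFR always above 60 → CONTROLLED; else EXCLUDED.

Boundary semantics are strict on the 10 %/yr cut (a slope of exactly
−10 %/yr is EXCLUDED) and closed on the controlled band; boundaries are
measure-zero under measurement noise, so the choice is documentation, not
substance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "KidneyLabel",
    "SlopeResult",
    "BetweenVisitsResult",
    "fit_egfr_slope",
    "label_discovery",
    "label_validation",
]


class KidneyLabel(str, Enum):
    CONTROLLED = "CONTROLLED"
    UNCONTROLLED = "UNCONTROLLED"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SlopeResult:
    """OLS fit of eGFR on time for one patient and one window.

    ``slope`` is in mL/min/1.73 m² per year, ``intercept`` the fitted eGFR at
    the window's time origin, ``pct_slope`` the annualized percentage slope
    (100 × slope / denominator), ``slope_p`` the two-sided p-value of the
    regression coefficient (NaN when n_points == 2: zero residual df).
    """

    slope: float
    intercept: float
    pct_slope: float
    n_points: int
    slope_p: float
    window: str


@dataclass(frozen=True)
class BetweenVisitsResult:
    """Per-interval slopes plus their arithmetic-mean percentage slope."""

    segments: Tuple[SlopeResult, ...]
    pct_slope: float  # mean of per-interval pct slopes
    window: str = "between_visits"


def _ols(times: np.ndarray, values: np.ndarray, window: str, denominator: str) -> SlopeResult:
    n = times.size
    if n < 2 or np.unique(times).size < 2:
        raise ValueError("slope fit needs >= 2 distinct time points")
    if n == 2:
        slope = (values[1] - values[0]) / (times[1] - times[0])
        intercept = values[0] - slope * times[0]
        p = math.nan
    else:
        fit = stats.linregress(times, values)
        slope, intercept, p = fit.slope, fit.intercept, fit.pvalue
    denom = values[0] if denominator == "baseline" else intercept
    pct = 100.0 * slope / denom if denom != 0 else math.inf * np.sign(slope)
    return SlopeResult(float(slope), float(intercept), float(pct), int(n), float(p), window)


def fit_egfr_slope(
    times: Sequence[float],
    egfr: Sequence[float],
    window: str = "full_period",
    *,
    denominator: str = "intercept",
):
    """Fit the eGFR slope for one patient.

    Parameters
    ----------
    times, egfr
        Visit times (years from baseline, strictly increasing) and matching
        eGFR values.
    window : {'full_period', 'between_visits'}
        ``full_period`` fits one line through all visits and returns a
        :class:`SlopeResult`. ``between_visits`` fits every consecutive visit
        pair — times re-referenced to the interval start so the intercept is
        the fitted eGFR at that start — and returns a
        :class:`BetweenVisitsResult` whose ``pct_slope`` is the arithmetic
        mean of the per-interval percentage slopes.
    denominator : {'intercept', 'baseline'}
        Denominator of the percentage slope: the fitted value at the window's
        time origin (default; robust to baseline noise) or the observed first
        value (sensitivity analysis).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(egfr, dtype=float)
    if t.size != y.size:
        raise ValueError("times and egfr must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit times must be strictly increasing")
    if denominator not in ("intercept", "baseline"):
        raise ValueError(f"unknown denominator {denominator!r}")

    if window == "full_period":
        return _ols(t, y, window, denominator)
    if window == "between_visits":
        segs: List[SlopeResult] = []
        for i in range(t.size - 1):
            segs.append(
                _ols(t[i : i + 2] - t[i], y[i : i + 2], "between_visits", denominator)
            )
        mean_pct = float(np.mean([s.pct_slope for s in segs]))
        return BetweenVisitsResult(tuple(segs), mean_pct)
    raise ValueError(f"unknown window {window!r}")


def label_discovery(pct_slope: float) -> KidneyLabel:
    """Label a patient from the annualized percentage slope (discovery rule).

    Losing more than 10 %/yr → UNCONTROLLED; within the closed band
    [−5, +5] %/yr → CONTROLLED; the 5–10 %/yr loss zone and gains above
    5 %/yr → EXCLUDED. Exactly −10 %/yr falls in the excluded zone ("more
    than 10%" read strictly).
    """
    if not math.isfinite(pct_slope):
        raise ValueError(f"pct_slope must be finite, got {pct_slope!r}")
    if pct_slope < -10.0:
        return KidneyLabel.UNCONTROLLED
    if -5.0 <= pct_slope <= 5.0:
        return KidneyLabel.CONTROLLED
    return KidneyLabel.EXCLUDED


def label_validation(
    egfr: Sequence[float],
    cohort_rule: str,
    *,
    loss_to: str = "min",
) -> KidneyLabel:
    """Label a patient by the stricter absolute validation-cohort rules.

    ``egfr[0]`` is the baseline value, the rest are follow-ups (at least one
    required). UNCONTROLLED requires a drop of more than 10 mL/min/1.73 m²
    from baseline to the worst follow-up together with progression to CKD
    stage 3 (any follow-up below 60). CONTROLLED requires a total loss under
    the cohort threshold — 5 for ``loss_lt_5``, 10 for ``loss_lt_10`` — with
    every eGFR value (baseline included) above 60. Everyone else is EXCLUDED.

    ``loss_to`` picks the follow-up the loss is measured to: the minimum
    (default, most sensitive reading) or the last visit.
    """
    thresholds = {"loss_lt_5": 5.0, "loss_lt_10": 10.0}
    if cohort_rule not in thresholds:
        raise ValueError(f"cohort_rule must be one of {sorted(thresholds)}")
    if loss_to not in ("min", "last"):
        raise ValueError(f"loss_to must be 'min' or 'last'")
    vals = np.asarray(egfr, dtype=float)
    if vals.size < 2:
        raise ValueError("need a baseline and at least one follow-up eGFR")
    baseline, follow = vals[0], vals[1:]
    loss = baseline - (follow.min() if loss_to == "min" else follow[-1])
    if loss > 10.0 and np.any(follow < 60.0):
        return KidneyLabel.UNCONTROLLED
    if loss < thresholds[cohort_rule] and np.all(vals > 60.0):
        return KidneyLabel.CONTROLLED
    return KidneyLabel.EXCLUDED
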