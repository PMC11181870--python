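"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the structure of a ~200-patient diabetic cohort under
RAS-inhibitor treatment: one baseline urine sample per patient, roughly
annual clinical visits over ~3 years, serum creatinine and cystatin C at
every visit, and a samples × peptides urinary intensity matrix with
zero-inflated log-normal intensities (0 = not detected).

A latent per-patient GFR decline rate drives everything: true GFR follows
GFR(t) = GFR0 · (1 + rate·t/100) — linear in time on the relative scale, so
the OLS percentage slope recovers the configured %/yr exactly in the
noise-free limit — and serum markers are back-calculated from the true GFR
by analytically inverting the CKD-EPI creatinine and cystatin equations,
then perturbed by multiplicative log-normal measurement noise. Because
creatinine and cystatin are generated through those two equations, the
combined and EKFC equations agree with truth only up to noise and
functional-form differences, deliberately reproducing the between-equation
labeling discordance the pipeline studies.

Differential peptides are shifted on the log scale in decliners (a majority
down-regulated, collagen-fragment-like; a minority up-regulated,
antitrypsin-like). Detection is Bernoulli with probability logistic in the
peptide's mean log-intensity, calibrated so non-differential peptides hit
the configured base detection frequency on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .egfr import EgfrMethod, invert_egfr

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "write_cohort"]

# cohort demographics: baseline age ~ N(67.5, 8) truncated, 53% female,
# baseline true GFR ~ N(63.3, 16.8) truncated to a plausible adult range
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 67.5, 8.0, 30.0, 90.0
_GFR0_MEAN, _GFR0_SD, _GFR0_LO, _GFR0_HI = 63.3, 16.8, 20.0, 120.0
_FEMALE_PROB = 0.53
_LOG_INTENSITY_MEAN, _LOG_INTENSITY_SD = 10.0, 1.5  # across peptides (ln scale)
_WITHIN_SD = 1.0  # within-group log-intensity sd; effect_size is in these units
_DETECTION_SLOPE = 0.35  # logistic slope per ln-intensity unit


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort; defaults mirror a typical discovery-cohort scale."""

    n_patients: int = 200
    n_visits: int = 4
    visit_interval_mean: float = 1.0  # years
    visit_interval_sd: float = 0.2  # years
    n_peptides: int = 2000
    n_differential: int = 200
    effect_size: float = 1.0  # standardized mean difference on log-intensity
    frac_down: float = 0.8  # fraction of differential peptides down in decliners
    decline_frac: float = 0.5  # fraction of patients with declining GFR
    true_decline_rate: float = -15.0  # %/year
    true_stable_rate: float = 0.0  # %/year
    measurement_cv_creatinine: float = 0.05
    measurement_cv_cystatin: float = 0.05
    detection_base_freq: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "n_visits", "n_peptides", "n_differential"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_down", "decline_frac", "detection_base_freq"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_differential > self.n_peptides:
            raise ValueError("n_differential cannot exceed n_peptides")
        if self.visit_interval_mean <= 0 or self.visit_interval_sd < 0:
            raise ValueError("visit intervals must be positive")
        for name in ("measurement_cv_creatinine", "measurement_cv_cystatin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    true_gfr: pd.DataFrame  # patient_id, visit_index, time_years, true_gfr
    status: pd.Series  # patient_id -> 'decliner' | 'stable'
    peptides: pd.DataFrame  # peptide_id, is_differential, direction (UP/DOWN/None)

    def to_dict(self) -> dict:
        return {
            "status": self.status.to_dict(),
            "true_gfr": self.true_gfr.to_dict(orient="list"),
            "peptides": self.peptides.reset_index().to_dict(orient="list"),
        }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def _calibrate_detection_intercept(base_mean: np.ndarray, target: float) -> float:
    """Intercept c such that mean sigmoid(c + slope·centered-mean) = target."""
    centered = _DETECTION_SLOPE * (base_mean - base_mean.mean())

    def gap(c):
        return np.mean(1.0 / (1.0 + np.exp(-(c + centered)))) - target

    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    return float(optimize.brentq(gap, -40.0, 40.0))


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort: visit table, peptide matrix, ground truth.

    Returns
    -------
    visits : DataFrame
        Long format, one row per visit: patient_id, visit_index, time_years,
        age_baseline, sex, scr_mg_dl, scys_mg_l.
    matrix : DataFrame
        Samples (rows, indexed by patient_id; one baseline urine per
        patient) × peptides (columns), non-negative intensities, 0 = not
        detected.
    truth : GroundTruth

    Raises
    ------
    ValueError
        If the configured rates/follow-up drive any true GFR to <= 0, where
        the estimating equations cannot be inverted.
    """
    rng = np.random.default_rng(config.seed)
    n, v = config.n_patients, config.n_visits
    pat_ids = [f"P{i + 1:04d}" for i in range(n)]
    pad = len(str(config.n_peptides))
    pep_ids = [f"pep{j + 1:0{pad}d}" for j in range(config.n_peptides)]

    sex = np.where(rng.random(n) < _FEMALE_PROB, "F", "M")
    age0 = _truncated_normal(rng, _AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI, n)
    decliner = rng.random(n) < config.decline_frac
    gfr0 = _truncated_normal(rng, _GFR0_MEAN, _GFR0_SD, _GFR0_LO, _GFR0_HI, n)
    rate = np.where(decliner, config.true_decline_rate, config.true_stable_rate)

    intervals = np.maximum(
        rng.normal(config.visit_interval_mean, config.visit_interval_sd, (n, v - 1))
        if v > 1
        else np.zeros((n, 0)),
        0.1,
    )
    times = np.concatenate([np.zeros((n, 1)), np.cumsum(intervals, axis=1)], axis=1)

    true_gfr = gfr0[:, None] * (1.0 + rate[:, None] * times / 100.0)
    if np.any(true_gfr <= 0.0):
        raise ValueError(
            "configured decline rate and follow-up produce non-positive true GFR; "
            "the eGFR equations cannot be inverted there"
        )

    age_at_visit = age0[:, None] + times
    sex_grid = np.repeat(sex[:, None], v, axis=1)
    scr_true = invert_egfr(true_gfr, age_at_visit, sex_grid, EgfrMethod.CKD_EPI_CR)
    scys_true = invert_egfr(true_gfr, age_at_visit, sex_grid, EgfrMethod.CKD_EPI_CYS)
    scr = scr_true * _lognormal_noise(rng, config.measurement_cv_creatinine, (n, v))
    scys = scys_true * _lognormal_noise(rng, config.measurement_cv_cystatin, (n, v))

    visits = pd.DataFrame(
        {
            "patient_id": np.repeat(pat_ids, v),
            "visit_index": np.tile(np.arange(v), n),
            "time_years": times.ravel(),
            "age_baseline": np.repeat(age0, v),
            "sex": np.repeat(sex, v),
            "scr_mg_dl": scr.ravel(),
            "scys_mg_l": scys.ravel(),
        }
    )

    # ------------------------------------------------------------------ peptides
    base_mean = rng.normal(_LOG_INTENSITY_MEAN, _LOG_INTENSITY_SD, config.n_peptides)
    diff_idx = rng.choice(config.n_peptides, size=config.n_differential, replace=False)
    n_down = int(round(config.frac_down * config.n_differential))
    down_mask = np.zeros(config.n_differential, dtype=bool)
    down_mask[: n_down] = True
    rng.shuffle(down_mask)
    delta = np.zeros(config.n_peptides)
    delta[diff_idx] = np.where(down_mask, -1.0, 1.0) * config.effect_size * _WITHIN_SD

    # per-sample mean log-intensity: decliners get the shift
    sample_mean = base_mean[None, :] + np.where(decliner[:, None], delta[None, :], 0.0)

    nondiff = np.ones(config.n_peptides, dtype=bool)
    nondiff[diff_idx] = False
    c = _calibrate_detection_intercept(base_mean[nondiff], config.detection_base_freq)
    lin = c + _DETECTION_SLOPE * (sample_mean - base_mean[nondiff].mean())
    p_detect = 1.0 / (1.0 + np.exp(-lin))
    detected = rng.random((n, config.n_peptides)) < p_detect
    log_intensity = rng.normal(sample_mean, _WITHIN_SD)
    matrix = pd.DataFrame(
        np.where(detected, np.exp(log_intensity), 0.0), index=pd.Index(pat_ids, name="patient_id"),
        columns=pep_ids,
    )

    direction = np.full(config.n_peptides, None, dtype=object)
    direction[diff_idx] = np.where(down_mask, "DOWN", "UP")
    truth = GroundTruth(
        true_gfr=pd.DataFrame(
            {
                "patient_id": np.repeat(pat_ids, v),
                "visit_index": np.tile(np.arange(v), n),
                "time_years": times.ravel(),
                "true_gfr": true_gfr.ravel(),
            }
        ),
        status=pd.Series(
            np.where(decliner, "decliner", "stable"), index=pd.Index(pat_ids, name="patient_id")
        ),
        peptides=pd.DataFrame(
            {"is_differential": ~nondiff, "direction": direction},
            index=pd.Index(pep_ids, name="peptide_id"),
        ),
    )
    return visits, matrix, truth


def write_cohort(
    visits: pd.DataFrame,
    matrix: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write visits.csv, peptides.tsv and ground_truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": outdir / "visits.csv",
        "matrix": outdir / "peptides.tsv",
        "truth": outdir / "ground_truth.json",
    }
    visits.to_csv(paths["visits"], index=False, float_format="%.10g")
    matrix.to_csv(paths["matrix"], sep="\t", float_format="%.10g")
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return paths
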