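"""ROC/AUC evaluation, cross-equation label concordance, baseline-vs-slope
correlation, and cross-cohort verification rates.

The AUC is the Mann–Whitney probability that a random uncontrolled sample
scores above a random controlled one (ties count one half); its confidence
interval and the test against AUC = 0.5 use DeLong's non-parametric
structural-component variance estimator rather than a bootstrap, which is
the convention of the clinical ROC software this pipeline mirrors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import KidneyLabel

__all__ = [
    "RocResult",
    "LabelConcordance",
    "VerificationRate",
    "roc_auc",
    "label_overlap",
    "baseline_slope_correlation",
    "verification_rate",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_pos: int
    n_neg: int
    se: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with DeLong confidence interval and p-value against 0.5.

    ``labels`` marks the positive class: truthy / 1 / 'UNCONTROLLED' /
    :class:`KidneyLabel.UNCONTROLLED` are positives. Both classes must be
    present. With perfectly separated scores the DeLong variance collapses
    to zero; the CI then degenerates to the point estimate and p to 0.
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "biu":
        pos = lab.astype(bool)
    else:
        pos = np.array(
            [x == KidneyLabel.UNCONTROLLED or x == "UNCONTROLLED" or x is True for x in lab]
        )
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("roc_auc needs both classes present")

    x, y = scores[pos], scores[~pos]
    tx = _midrank(x)
    ty = _midrank(y)
    tz = _midrank(np.concatenate([x, y]))
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n  # per-positive structural components
    v01 = 1.0 - (tz[m:] - ty) / m  # per-negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)

    z = stats.norm.ppf(0.5 + level / 2.0)
    if se > 0:
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        lo = hi = auc
        p = 1.0 if auc == 0.5 else 0.0
    lo, hi = min(lo, auc), max(hi, auc)
    return RocResult(float(auc), float(lo), float(hi), float(p), m, n, float(se))


@dataclass
class LabelConcordance:
    """Agreement of controlled/uncontrolled labeling across eGFR methods.

    ``proportion`` uses all commonly labeled patients as denominator;
    ``proportion_non_excluded`` restricts the denominator to patients no
    method excluded — both readings are reported because overlap statistics
    are sensitive to that choice. ``venn_counts`` maps each label to the
    count of patients carrying it under exactly each method subset.
    """

    methods: List[str]
    n_common: int
    n_identical: int
    proportion: float
    n_common_non_excluded: int
    n_identical_non_excluded: int
    proportion_non_excluded: float
    per_label_counts: Dict[str, int] = field(default_factory=dict)
    venn_counts: Dict[str, Dict[Tuple[str, ...], int]] = field(default_factory=dict)


def label_overlap(labels_by_method: Mapping[str, pd.Series]) -> LabelConcordance:
    """Venn-style concordance of per-patient labels across methods.

    Each series maps patient id → label; only patients present under every
    method are compared. ``per_label_counts`` counts patients given the same
    label by *all* methods; the overall proportion is their sum over the
    common total.
    """
    methods = list(labels_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    common = labels_by_method[methods[0]].index
    for m in methods[1:]:
        common = common.intersection(labels_by_method[m].index)
    if len(common) == 0:
        raise ValueError("no shared patients between methods")

    frame = pd.DataFrame(
        {m: labels_by_method[m].reindex(common).map(lambda x: KidneyLabel(x).value) for m in methods}
    )
    identical = frame.nunique(axis=1) == 1
    per_label = frame.loc[identical, methods[0]].value_counts().to_dict()

    non_excl = ~(frame == KidneyLabel.EXCLUDED.value).any(axis=1)
    n_ne = int(non_excl.sum())
    n_ident_ne = int((identical & non_excl).sum())

    venn: Dict[str, Dict[Tuple[str, ...], int]] = {}
    for label in (l.value for l in KidneyLabel):
        has = frame == label
        cells: Dict[Tuple[str, ...], int] = {}
        for r in range(1, len(methods) + 1):
            for subset in itertools.combinations(methods, r):
                inside = has[list(subset)].all(axis=1)
                outside = ~has[[m for m in methods if m not in subset]].any(axis=1)
                cells[subset] = int((inside & outside).sum())
        venn[label] = cells

    n_ident = int(identical.sum())
    return LabelConcordance(
        methods=methods,
        n_common=len(common),
        n_identical=n_ident,
        proportion=n_ident / len(common),
        n_common_non_excluded=n_ne,
        n_identical_non_excluded=n_ident_ne,
        proportion_non_excluded=(n_ident_ne / n_ne) if n_ne else math.nan,
        per_label_counts=per_label,
        venn_counts=venn,
    )


def baseline_slope_correlation(values_a, values_b) -> Tuple[float, float]:
    """Pearson correlation of two per-patient quantities (baseline eGFR or
    percentage slope under two equations); returns (r, two-sided p).

    Pairs with a non-finite entry are dropped; at least 3 finite pairs are
    required. A constant vector has no defined correlation → (nan, nan).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class VerificationRate:
    """How many discovery-significant peptides replicate in a validation
    cohort: same regulation direction, optionally also p < .05 there."""

    mode: str
    n_discovery_significant: int
    n_verified: int
    rate: float  # NaN when nothing was discovery-significant


def verification_rate(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    mode: str = "direction_only",
    p_threshold: float = 0.05,
) -> VerificationRate:
    """Fraction of discovery-significant peptides confirmed in validation.

    Both inputs are screen tables indexed by peptide id with ``p_value`` and
    ``direction`` columns. A discovery peptide absent from the validation
    table cannot be confirmed and counts as unverified.
    """
    if mode not in ("direction_only", "direction_and_p"):
        raise ValueError(f"unknown mode {mode!r}")
    sig = discovery[discovery["p_value"] < p_threshold]
    n_sig = len(sig)
    if n_sig == 0:
        return VerificationRate(mode, 0, 0, math.nan)
    shared = sig.index.intersection(validation.index)
    val = validation.loc[shared]
    same_dir = val["direction"] == sig.loc[shared, "direction"]
    if mode == "direction_and_p":
        same_dir &= val["p_value"] < p_threshold
    n_ver = int(same_dir.sum())
    return VerificationRate(mode, n_sig, n_ver, n_ver / n_sig)
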