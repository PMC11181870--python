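"""Per-peptide differential statistics between uncontrolled and controlled
kidney-function groups, plus peptide–slope correlations and the
between-method agreement regression.

For each peptide the screen reports a two-sided Wilcoxon rank-sum p-value
(exact when the combined group size is small and tie-free, otherwise the
tie- and continuity-corrected normal approximation), the fold change
(mean intensity in the uncontrolled group over the controlled group, zeros
included — a non-detection is a real contribution of zero abundance), the
regulation direction, and per-group detection frequencies. The screen is
deliberately unadjusted: nominal significance drives downstream selection;
Benjamini–Hochberg q-values ride along as metadata only.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import KidneyLabel

__all__ = [
    "wilcoxon_screen",
    "spearman_slope_correlation",
    "method_agreement_regression",
    "EXACT_MAX_N",
]

#: Largest combined group size for which the exact rank-sum null is enumerated
#: (only when the pooled sample is tie-free).
EXACT_MAX_N = 25


def _rank_sum_p(u_vals: np.ndarray, c_vals: np.ndarray) -> float:
    pooled = np.concatenate([u_vals, c_vals])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(u_vals, c_vals, alternative="two-sided", method=method)
    return float(res.pvalue)


def wilcoxon_screen(matrix: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum screen of every peptide, uncontrolled vs controlled.

    Parameters
    ----------
    matrix
        Samples × peptides intensity matrix, already frequency-filtered.
    group_labels
        Sample id → label; only CONTROLLED/UNCONTROLLED rows are used.

    Returns
    -------
    DataFrame indexed by peptide id with columns ``p_value``, ``q_value``
    (Benjamini–Hochberg, metadata only), ``fold_change``, ``direction``
    ('UP'/'DOWN'), ``freq_uncontrolled``, ``freq_controlled`` and
    ``fold_undefined`` (True when the controlled-group mean is zero; the
    direction then comes from the rank statistic instead of the mean ratio,
    and the peptide is flagged rather than dropped).
    """
    labels = group_labels.reindex(matrix.index)
    unc = matrix.loc[labels == KidneyLabel.UNCONTROLLED]
    con = matrix.loc[labels == KidneyLabel.CONTROLLED]
    if len(unc) < 2 or len(con) < 2:
        raise ValueError("need >= 2 samples per group")

    n_u, n_c = len(unc), len(con)
    records = []
    for pep in matrix.columns:
        u_vals = unc[pep].to_numpy(dtype=float)
        c_vals = con[pep].to_numpy(dtype=float)
        p = _rank_sum_p(u_vals, c_vals)
        mean_u, mean_c = u_vals.mean(), c_vals.mean()
        if mean_c == 0.0:
            fold = math.nan
            undefined = True
            # direction from the rank statistic: U above its null mean means
            # uncontrolled stochastically larger
            u_stat = stats.mannwhitneyu(u_vals, c_vals, alternative="two-sided",
                                        method="asymptotic").statistic
            direction = "UP" if u_stat >= n_u * n_c / 2.0 else "DOWN"
        else:
            fold = mean_u / mean_c
            undefined = False
            direction = "UP" if fold > 1.0 else "DOWN"
        records.append(
            (pep, p, fold, direction, (u_vals > 0).mean(), (c_vals > 0).mean(), undefined)
        )

    out = pd.DataFrame.from_records(
        records,
        columns=[
            "peptide_id", "p_value", "fold_change", "direction",
            "freq_uncontrolled", "freq_controlled", "fold_undefined",
        ],
    ).set_index("peptide_id")
    out.insert(1, "q_value", stats.false_discovery_control(out["p_value"].to_numpy()))
    return out


def spearman_slope_correlation(
    matrix: pd.DataFrame, pct_slopes: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of every peptide with the eGFR percentage slope.

    Samples are the intersection of the matrix rows and the finite entries of
    ``pct_slopes``; at least 3 are required. Constant peptide vectors have no
    rank correlation and are recorded as NaN rather than dropped.

    Returns a DataFrame indexed by peptide id with columns ``rho``, ``rho_p``.
    """
    slopes = pct_slopes.reindex(matrix.index)
    mask = np.isfinite(slopes.to_numpy(dtype=float))
    if mask.sum() < 3:
        raise ValueError("need >= 3 samples with a finite percentage slope")
    sub = matrix.loc[mask]
    y = slopes[mask].to_numpy(dtype=float)

    rhos = np.full(sub.shape[1], np.nan)
    ps = np.full(sub.shape[1], np.nan)
    X = sub.to_numpy(dtype=float)
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.ptp(x) == 0.0:
            continue  # constant vector: rho undefined
        rho, p = stats.spearmanr(x, y)
        rhos[j], ps[j] = rho, p
    return pd.DataFrame({"rho": rhos, "rho_p": ps}, index=sub.columns.rename("peptide_id"))


def method_agreement_regression(
    corr_a: pd.DataFrame, corr_b: pd.DataFrame, p_cut: float = 0.1
) -> float:
    """r² of the slope-correlation profiles of two eGFR methods.

    Restricts to peptides whose Spearman p-value is below ``p_cut`` under
    *both* methods, regresses method B's rho on method A's (OLS), and returns
    the coefficient of determination. High r² means the two eGFR equations
    rank the same peptides as slope-associated.
    """
    shared = corr_a.index.intersection(corr_b.index)
    a = corr_a.loc[shared]
    b = corr_b.loc[shared]
    keep = (a["rho_p"] < p_cut) & (b["rho_p"] < p_cut)
    if int(keep.sum()) < 3:
        raise ValueError(
            f"only {int(keep.sum())} shared peptides pass rho_p < {p_cut}; need >= 3"
        )
    fit = stats.linregress(a.loc[keep, "rho"], b.loc[keep, "rho"])
    return float(fit.rvalue**2)
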