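"""Concordance-based biomarker panel selection and the RBF-SVM progression
classifier with take-one-out panel refinement.

Because the controlled/uncontrolled labeling shifts with the eGFR equation
used, candidate biomarkers are required to be nominally significant
(p < 0.05) with one consistent regulation direction under at least three of
the four equations. The surviving panel feeds a support-vector machine with
a radial-basis kernel at fixed hyperparameters (C = 256, gamma = 2e-5 —
no hyperparameter search by design), scored by leave-one-out (LOO)
cross-validated AUC, and refined by greedy backward elimination: repeatedly
drop the single peptide whose removal most increases the LOO AUC, stopping
when no removal helps.

Feature transform: natural log of (intensity + 1) — zeros map to 0 — then
per-feature z-scoring with statistics computed inside each training fold
only, so the LOO estimate never leaks held-out information. The classifier
score is the signed distance to the separating hyperplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

try:  # low-level libsvm entry points: same solver as SVC without the
    # per-call estimator overhead, which dominates at n ~ 200
    from sklearn.svm import _libsvm as _lsvm

    _lsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except ImportError:  # pragma: no cover - fallback to the public estimator
    _HAVE_LIBSVM = False

try:  # fused kernel assembly for the backward-elimination hot loop
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .trajectory import KidneyLabel

__all__ = [
    "ConcordanceCriteria",
    "PanelModel",
    "select_concordant_panel",
    "consistency_filter",
    "train_svm_panel",
    "loo_scores",
    "loo_auc",
    "take_one_out_optimize",
    "DEFAULT_C",
    "DEFAULT_GAMMA",
]

DEFAULT_C = 256.0
DEFAULT_GAMMA = 2e-5


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceCriteria:
    """Cross-equation selection rule for candidate biomarkers."""

    min_methods: int = 3
    p_threshold: float = 0.05
    require_consistent_direction: bool = True

    def __post_init__(self):
        if not 1 <= self.min_methods <= 4:
            raise ValueError("min_methods must be in 1..4")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")


def select_concordant_panel(
    stats_by_method: Mapping[str, pd.DataFrame],
    criteria: ConcordanceCriteria = ConcordanceCriteria(),
) -> List[str]:
    """Select peptides significant with one direction in enough methods.

    ``stats_by_method`` maps an eGFR method name to a screen result
    (DataFrame indexed by peptide id with ``p_value`` and ``direction``
    columns). A peptide absent from a method's table is treated as
    non-significant there. Selection requires at least ``min_methods``
    methods in which the peptide is nominally significant *with one shared
    regulation direction* (i.e. the largest direction-consistent subset of
    significant methods is counted; a significant method with the opposite
    direction does not veto the others — this keeps selection monotone in
    both criteria). Returns peptide ids sorted lexicographically; an empty
    selection is a valid outcome.
    """
    votes: Dict[str, List[str]] = {}
    for table in stats_by_method.values():
        sig = table[table["p_value"] < criteria.p_threshold]
        for pep, direction in sig["direction"].items():
            votes.setdefault(pep, []).append(direction)
    selected = []
    for pep, dirs in votes.items():
        if criteria.require_consistent_direction:
            strength = max(dirs.count("UP"), dirs.count("DOWN"))
        else:
            strength = len(dirs)
        if strength >= criteria.min_methods:
            selected.append(pep)
    return sorted(selected)


def consistency_filter(
    panel: Sequence[str],
    direction_tables: Sequence[Mapping[str, str]],
) -> List[str]:
    """Keep panel peptides whose direction agrees across every table.

    Each entry of ``direction_tables`` maps peptide id → 'UP'/'DOWN' for one
    cohort or one eGFR-method assessment. A peptide missing from any table
    cannot be confirmed and is dropped. Order of the input panel is kept.
    """
    kept = []
    for pep in panel:
        dirs = [t.get(pep) for t in direction_tables]
        if None in dirs:
            continue
        if len(set(dirs)) == 1:
            kept.append(pep)
    return kept


# ---------------------------------------------------------------------------
# SVM panel model
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    """Fitted panel classifier: peptide list, transform stats, SVM state."""

    peptides: List[str]
    C: float
    gamma: float
    log_mean: np.ndarray  # per-feature mean of log1p(intensity) in training
    log_std: np.ndarray  # per-feature std (1.0 where training std was 0)
    svm: SVC = field(repr=False)
    loo_auc: Optional[float] = None
    elimination_trace: List[dict] = field(default_factory=list)

    def decision_scores(self, matrix: pd.DataFrame) -> pd.Series:
        """Signed distance to the hyperplane for each sample (higher =
        more uncontrolled-like)."""
        Z = (np.log1p(matrix[self.peptides].to_numpy(dtype=float)) - self.log_mean) / self.log_std
        return pd.Series(self.svm.decision_function(Z), index=matrix.index)

    def to_dict(self) -> dict:
        """JSON-serializable description (peptides, transform, kernel)."""
        return {
            "peptides": list(self.peptides),
            "C": self.C,
            "gamma": self.gamma,
            "log_mean": self.log_mean.tolist(),
            "log_std": self.log_std.tolist(),
            "loo_auc": self.loo_auc,
            "elimination_trace": self.elimination_trace,
        }


def _binary_labels(group_labels: pd.Series, index: pd.Index) -> np.ndarray:
    labels = group_labels.reindex(index)
    arr = np.asarray([KidneyLabel(x).value if not pd.isna(x) else "" for x in labels])
    is_u = arr == KidneyLabel.UNCONTROLLED.value
    is_c = arr == KidneyLabel.CONTROLLED.value
    if not np.all(is_u | is_c):
        raise ValueError("every sample must be labeled CONTROLLED or UNCONTROLLED")
    return is_u.astype(int)


def _standardize(train: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


def _make_svm(C: float, gamma: float) -> SVC:
    return SVC(C=C, gamma=gamma, kernel="rbf", cache_size=128)


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann–Whitney identity with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def train_svm_panel(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    panel: Sequence[str],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> PanelModel:
    """Fit the RBF-SVM on the panel peptides (full training set).

    Requires at least 5 samples per class and a non-empty panel. The fit is
    deterministic: libsvm's solution for a fixed binary problem has no
    random component.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    y = _binary_labels(group_labels, matrix.index)
    if y.sum() < 5 or (y.size - y.sum()) < 5:
        raise ValueError("need >= 5 samples per class")
    X = np.log1p(matrix[panel].to_numpy(dtype=float))
    mu, sd = _standardize(X)
    svm = _make_svm(C, gamma).fit((X - mu) / sd, y)
    return PanelModel(panel, float(C), float(gamma), mu, sd, svm)


def _fit_decision_rbf(
    Z_train: np.ndarray, y_train: np.ndarray, z_test: np.ndarray, C: float, gamma: float
) -> float:
    """Decision value of one held-out sample, RBF SVM on features.

    Calls libsvm directly; the raw binary decision is negated to match the
    sklearn convention (positive = class 1). Falls back to :class:`SVC`
    when the low-level interface is unavailable.
    """
    if _HAVE_LIBSVM:
        out = _lsvm.fit(
            np.ascontiguousarray(Z_train),
            y_train.astype(np.float64),
            svm_type=0,
            kernel="rbf",
            C=C,
            gamma=gamma,
            tol=1e-3,
            shrinking=0,
        )
        support_vectors, sv_coef, intercept = out[1], out[3], out[4]
        k = np.exp(-gamma * ((support_vectors - z_test) ** 2).sum(axis=1))
        return -(float(sv_coef[0] @ k) + float(intercept[0]))
    svm = _make_svm(C, gamma).fit(Z_train, y_train)
    return float(svm.decision_function(z_test[None, :])[0])


def _fit_decision_precomputed(
    K_train: np.ndarray, y_train: np.ndarray, k_test: np.ndarray, C: float
) -> float:
    """Decision value of one held-out sample, precomputed-kernel SVM."""
    if _HAVE_LIBSVM:
        out = _lsvm.fit(
            K_train,
            y_train.astype(np.float64),
            svm_type=0,
            kernel="precomputed",
            C=C,
            tol=1e-3,
            shrinking=0,
        )
        support, sv_coef, intercept = out[0], out[3], out[4]
        return -(float(sv_coef[0] @ k_test[support]) + float(intercept[0]))
    svm = SVC(C=C, kernel="precomputed").fit(K_train, y_train)
    return float(svm.decision_function(k_test[None, :])[0])


def loo_scores(
    log_X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> np.ndarray:
    """Leave-one-out decision scores on pre-log-transformed features.

    Standardization is recomputed inside every fold from the n−1 training
    samples, so the held-out sample never influences its own score.
    """
    n = log_X.shape[0]
    scores = np.empty(n)
    col_sum = log_X.sum(axis=0)
    col_sq = (log_X**2).sum(axis=0)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = n - 1
        mu = (col_sum - log_X[i]) / m
        var = (col_sq - log_X[i] ** 2) / m - mu**2
        sd = np.sqrt(np.maximum(var, 0.0))
        sd = np.where(sd <= 0.0, 1.0, sd)
        scores[i] = _fit_decision_rbf(
            (log_X[mask] - mu) / sd, y[mask], (log_X[i] - mu) / sd, C, gamma
        )
    return scores


def loo_auc(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    panel: Sequence[str],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """Leave-one-out cross-validated AUC of the panel SVM."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    y = _binary_labels(group_labels, matrix.index)
    log_X = np.log1p(matrix[panel].to_numpy(dtype=float))
    return rank_auc(loo_scores(log_X, y, C, gamma), y)


def _fold_weights(log_X: np.ndarray) -> np.ndarray:
    """Per-fold inverse variances of each feature (fold i excludes sample i).

    Standardization inside a LOO fold subtracts the fold mean and divides by
    the fold std; the mean shift cancels exactly in an RBF kernel (it depends
    on pairwise differences only), so the fold enters the kernel solely
    through these weights. Features constant in a fold get weight 1,
    matching the std->1 convention of :func:`loo_scores`.
    """
    n = log_X.shape[0]
    m = n - 1
    mu = (log_X.sum(axis=0) - log_X) / m
    var = ((log_X**2).sum(axis=0) - log_X**2) / m - mu**2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    return np.where(sd <= 0.0, 1.0, 1.0 / np.maximum(var, 1e-300))


if _HAVE_NUMBA:

    @_numba.njit(cache=False)
    def _assemble_candidate_kernel(M_full, Dq, wq, gamma, i, K_tr, k_te):
        """Fill the training-fold kernel (sample i left out) and the test row
        for the panel minus one feature: K = exp(-gamma (M_full - wq Dq))."""
        nm1 = M_full.shape[0] - 1
        for a in range(nm1):
            ia = a + 1 if a >= i else a
            for b in range(nm1):
                ib = b + 1 if b >= i else b
                K_tr[a, b] = np.exp(-gamma * (M_full[ia, ib] - wq * Dq[ia, ib]))
        for b in range(nm1):
            ib = b + 1 if b >= i else b
            k_te[b] = np.exp(-gamma * (M_full[i, ib] - wq * Dq[i, ib]))


def _removal_aucs(
    log_X: np.ndarray, y: np.ndarray, C: float, gamma: float
) -> Tuple[np.ndarray, float]:
    """LOO AUC of every single-feature removal, plus the full-panel LOO AUC.

    Exploits two structural facts to avoid |panel| independent LOO runs:
    the fold mean cancels in the RBF kernel, and each feature's fold std is
    unaffected by which other features are present — so per fold the
    weighted squared-distance matrix of the full panel is assembled once and
    each candidate removal subtracts one feature's contribution. Agrees
    with :func:`loo_scores` to numerical precision.
    """
    n, d = log_X.shape
    w = _fold_weights(log_X)  # (n, d)
    Dt = np.ascontiguousarray(
        np.moveaxis((log_X[:, None, :] - log_X[None, :, :]) ** 2, 2, 0)
    )  # (d, n, n)
    cand_scores = np.empty((d, n))
    full_scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    K_tr = np.empty((n - 1, n - 1))
    k_te = np.empty(n - 1)
    for i in range(n):
        mask[i] = False
        y_tr = y[mask]
        M_full = np.tensordot(w[i], Dt, axes=1)
        K = np.exp(-gamma * M_full)
        full_scores[i] = _fit_decision_precomputed(
            K[np.ix_(mask, mask)], y_tr, K[i, mask], C
        )
        if _HAVE_NUMBA:
            y64 = y_tr.astype(np.float64)
            for q in range(d):
                _assemble_candidate_kernel(M_full, Dt[q], w[i, q], gamma, i, K_tr, k_te)
                cand_scores[q, i] = _fit_decision_precomputed(K_tr, y64, k_te, C)
        else:  # pragma: no cover - pure-numpy fallback, same numbers
            for q in range(d):
                Kq = np.exp(-gamma * (M_full - w[i, q] * Dt[q]))
                cand_scores[q, i] = _fit_decision_precomputed(
                    Kq[np.ix_(mask, mask)], y_tr, Kq[i, mask], C
                )
        mask[i] = True
    aucs = np.array([rank_auc(cand_scores[q], y) for q in range(d)])
    return aucs, rank_auc(full_scores, y)


def take_one_out_optimize(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    panel: Sequence[str],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> PanelModel:
    """Refine the panel by greedy backward elimination on LOO AUC.

    Each round evaluates the LOO AUC of every single-peptide removal
    (|panel| evaluations); the removal that increases the AUC the most is
    applied, lexicographically smallest peptide id first on ties. The loop
    stops when no removal strictly improves the AUC or only two peptides
    remain, so the returned panel's LOO AUC is never below the input
    panel's. The full elimination trace (per-round candidate count, removed
    peptide, AUC path) is stored on the returned model.
    """
    current = sorted(panel)
    if len(current) < 2:
        raise ValueError("take-one-out needs a panel of >= 2 peptides")
    y = _binary_labels(group_labels, matrix.index)

    log_X = np.log1p(matrix[current].to_numpy(dtype=float))
    aucs, current_auc = _removal_aucs(log_X, y, C, gamma)
    trace: List[dict] = [{"round": 0, "panel_size": len(current), "auc": current_auc}]
    rnd = 0
    while len(current) > 2:
        rnd += 1
        best = int(np.argmax(aucs))  # columns in lexicographic order: first max wins ties
        best_auc = float(aucs[best])
        if best_auc <= current_auc:
            break
        removed = current.pop(best)
        log_X = np.delete(log_X, best, axis=1)
        current_auc = best_auc
        trace.append(
            {
                "round": rnd,
                "removed": removed,
                "n_candidates": len(current) + 1,
                "panel_size": len(current),
                "auc": current_auc,
            }
        )
        if len(current) <= 2:
            break
        aucs, _ = _removal_aucs(log_X, y, C, gamma)

    model = train_svm_panel(matrix, group_labels, current, C, gamma)
    model.loo_auc = current_auc
    model.elimination_trace = trace
    return model
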