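"""Peptide-matrix preprocessing: internal-standard normalization and the
detection-frequency filter.

The peptide matrix is samples × peptides with non-negative intensities;
an entry of exactly 0 means "not detected", never "abundance zero", so zeros
are excluded from the normalization fit and stay exactly zero afterwards.

Normalization rescales each sample by one multiplicative factor fitted to a
set of internal-standard ("housekeeping") peptides: regressing a sample's
log-intensities of the detected standards on the reference log-intensities
with the slope pinned to 1 (a multiplicative model) reduces to an
intercept-only fit, i.e. the factor is exp(mean log-ratio to the reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import KidneyLabel

__all__ = ["NormalizationModel", "normalize", "frequency_filter"]


@dataclass
class NormalizationModel:
    """Per-sample multiplicative scale factors and the reference they target.

    ``skipped_samples`` lists samples with fewer than two detected standards;
    those pass through unscaled (factor 1) and are surfaced rather than
    silently normalized from too little evidence.
    """

    standards: List[str]
    reference_log: pd.Series  # per-standard target log-intensity (natural log)
    scale_factors: pd.Series  # per-sample, dimensionless, > 0
    skipped_samples: List[str] = field(default_factory=list)


def normalize(
    matrix: pd.DataFrame,
    standards: Sequence[str],
    reference: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Normalize each sample to the internal-standard peptides.

    Parameters
    ----------
    matrix
        Samples in rows, peptide ids in columns, intensities >= 0, 0 = not
        detected.
    standards
        Peptide ids of the internal standards; all must be columns of
        ``matrix``.
    reference
        Per-standard target log-intensity (natural log). Defaults to the
        median log-intensity of each standard over the samples detecting it,
        which makes the operation self-contained and idempotent.

    Returns
    -------
    (normalized matrix, NormalizationModel)

    Per sample the fitted factor is exp(mean over detected standards of
    log(intensity) − reference log); all intensities in the sample are
    divided by it, so zeros remain exactly zero. Samples with fewer than two
    detected standards are flagged in the model and left unscaled.
    """
    standards = list(standards)
    missing = [s for s in standards if s not in matrix.columns]
    if missing:
        raise KeyError(f"standards absent from matrix: {missing}")
    if (matrix.values < 0).any():
        raise ValueError("peptide matrix must be non-negative")

    std_block = matrix[standards]
    if reference is None:
        with np.errstate(divide="ignore"):
            logs = np.log(std_block.where(std_block > 0))
        reference = logs.median(axis=0)
        if reference.isna().any():
            bad = reference.index[reference.isna()].tolist()
            raise ValueError(f"standards never detected, no reference possible: {bad}")
    else:
        reference = pd.Series(reference, dtype=float).reindex(standards)
        if reference.isna().any():
            raise ValueError("reference must cover every standard")

    factors = pd.Series(1.0, index=matrix.index, dtype=float)
    skipped: List[str] = []
    for sample, row in std_block.iterrows():
        detected = row[row > 0]
        if detected.size < 2:
            skipped.append(sample)
            continue
        log_ratio = np.log(detected.values) - reference[detected.index].values
        factors[sample] = math.exp(float(np.mean(log_ratio)))

    normalized = matrix.div(factors, axis=0)
    model = NormalizationModel(
        standards=standards,
        reference_log=reference,
        scale_factors=factors,
        skipped_samples=skipped,
    )
    return normalized, model


def frequency_filter(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    threshold: float = 0.30,
) -> List[str]:
    """Keep peptides detected in at least ``threshold`` of either group.

    ``group_labels`` maps sample id → CONTROLLED/UNCONTROLLED (other labels,
    e.g. EXCLUDED, are ignored). A peptide passes when its nonzero fraction
    reaches the threshold (inclusive, >=) in the uncontrolled OR the
    controlled group. Raising the threshold can only shrink the kept set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    labels = group_labels.reindex(matrix.index)
    unc = matrix.loc[labels == KidneyLabel.UNCONTROLLED]
    con = matrix.loc[labels == KidneyLabel.CONTROLLED]
    if len(unc) == 0 or len(con) == 0:
        raise ValueError("both UNCONTROLLED and CONTROLLED groups must be non-empty")
    freq_u = (unc > 0).mean(axis=0)
    freq_c = (con > 0).mean(axis=0)
    keep = (freq_u >= threshold) | (freq_c >= threshold)
    return matrix.columns[keep].tolist()
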