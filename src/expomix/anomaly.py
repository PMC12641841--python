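"""Classification of person × chemical exposure anomalies.

The sparse component of the decomposition captures deviations from the
population co-exposure structure.  To compare deviations across chemicals
with very different residual variability, each column of S is rescaled by
the standard deviation of the corresponding residual column
(residuals = X_scaled − L).  High and Low exposure events are then defined
by the 95th and 5th empirical percentiles of the entire rescaled matrix —
pooled across all participants and chemicals — with everything in between
labelled Sparse (background).

A separate three-tier classifier works directly from censoring status:
below-LOD cells are Sparse, detected values at or below the analyte's
detected-cell median are Low, and values above the median are High.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .panel import ExposurePanel

logger = logging.getLogger(__name__)

HIGH, LOW, SPARSE, MISSING = "High", "Low", "Sparse", "Missing"


@dataclass
class AnomalyGrid:
    """Rescaled sparse deviations with their High/Low/Sparse labels."""

    rescaled: np.ndarray
    labels: np.ndarray        # object array ∈ {High, Low, Sparse, Missing}
    q_hi: float
    q_lo: float

    def counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def residual_matrix(X_scaled: np.ndarray, L: np.ndarray,
                    missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Entrywise residuals X_scaled − L; missing cells propagate as NaN."""
    X = np.asarray(X_scaled, dtype=float)
    L = np.asarray(L, dtype=float)
    if X.shape != L.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {L.shape}")
    R = X - L
    if missing_mask is not None:
        R = np.where(np.asarray(missing_mask, bool), np.nan, R)
    return R


def rescale_sparse(S: np.ndarray, residuals: np.ndarray, robust: bool = False) -> np.ndarray:
    """Divide each column of S by the SD of its residual column.

    ``robust=True`` uses 1.4826·MAD instead of the plain SD, which resists
    inflation of the scale by the spike cells themselves.
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(residuals, dtype=float)
    if S.shape != R.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {R.shape}")
    if robust:
        med = np.nanmedian(R, axis=0)
        sd = 1.4826 * np.nanmedian(np.abs(R - med[None, :]), axis=0)
    else:
        sd = np.nanstd(R, axis=0, ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        raise ValueError(f"zero residual SD for analyte column(s) {np.flatnonzero(bad).tolist()}")
    return S / sd[None, :]


def classify_events(rescaled: np.ndarray, q_hi: float = 0.95, q_lo: float = 0.05) -> AnomalyGrid:
    """Label cells High / Low / Sparse by pooled empirical percentiles.

    Thresholds are the ``q_hi`` and ``q_lo`` quantiles (linear-interpolation
    convention) of all non-missing rescaled values across the whole matrix;
    a cell is High when strictly above the upper threshold, Low when
    strictly below the lower one, Sparse otherwise.  Missing (NaN) cells
    are labelled Missing and excluded from the quantile computation.
    """
    if not (0 <= q_lo < q_hi <= 1):
        raise ValueError("need 0 <= q_lo < q_hi <= 1")
    R = np.asarray(rescaled, dtype=float)
    finite = np.isfinite(R)
    vals = R[finite]
    if vals.size == 0:
        raise ValueError("no non-missing cells to classify")
    hi = float(np.quantile(vals, q_hi))
    lo = float(np.quantile(vals, q_lo))
    if np.unique(vals).size < 2:
        warnings.warn("degenerate rescaled matrix (all values equal): everything is Sparse",
                      RuntimeWarning)
    labels = np.full(R.shape, SPARSE, dtype=object)
    labels[finite & (R > hi)] = HIGH
    labels[finite & (R < lo)] = LOW
    labels[~finite] = MISSING
    return AnomalyGrid(rescaled=R, labels=labels, q_hi=hi, q_lo=lo)


def tier_by_lod_median(panel: ExposurePanel) -> np.ndarray:
    """Three-tier censoring-aware labels: <LOD Sparse, ≤ median Low, else High.

    Medians are computed per analyte over detected cells only.  A detected
    value exactly at the median is Low (below-or-equal convention).  An
    analyte with no detected cells is entirely Sparse (with a warning).
    Missing cells are labelled Missing.
    """
    n, p = panel.shape
    labels = np.full((n, p), SPARSE, dtype=object)
    detect = panel.detect_flag.values
    missing = panel.missing_mask.values
    values = panel.values.values
    for j, col in enumerate(panel.analytes):
        dj = detect[:, j]
        if not dj.any():
            warnings.warn(f"analyte {col!r} has no detected cells; all labelled Sparse",
                          RuntimeWarning)
            continue
        med = np.median(values[dj, j])
        labels[dj & (values[:, j] <= med), j] = LOW
        labels[dj & (values[:, j] > med), j] = HIGH
    labels[missing] = MISSING
    return labels
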