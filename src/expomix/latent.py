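"""Latent co-exposure structure: SVD loadings and correlation denoising.

Operates on the same column-scaled (not centered) matrix that feeds the
decomposition, so the latent space is consistent with the decomposition
input.  Deterministic sign convention: within each loading column the
largest-magnitude entry is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LatentLoadings:
    """Rank-k SVD of the denoised exposure matrix.

    ``loadings`` (analytes × k) have unit-norm columns; ``scores``
    (participants × k) are the left singular vectors scaled by their
    singular values, so scores @ loadings.T reconstructs the rank-k
    approximation.
    """

    loadings: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    analytes: list[str] | None = None


def svd_loadings(L: np.ndarray, k: int, analytes: list[str] | None = None) -> LatentLoadings:
    """Rank-k singular value decomposition of the (scaled) matrix L."""
    L = np.asarray(L, dtype=float)
    if k <= 0 or k > min(L.shape):
        raise ValueError(f"k={k} must be in [1, {min(L.shape)}]")
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    total = float((s ** 2).sum())
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|entry| of each loading column positive
    V = Vt.T
    for c in range(k):
        j = np.argmax(np.abs(V[:, c]))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
            U[:, c] = -U[:, c]
    var = (s ** 2) / total if total > 0 else np.zeros(k)
    return LatentLoadings(loadings=V, scores=U * s, singular_values=s,
                          variance_explained=var, analytes=analytes)


def component_loadings(lat: LatentLoadings, components: list[int],
                       analyte_class: pd.Series | None = None) -> pd.DataFrame:
    """Tidy per-analyte loading table for the requested components (1-based).

    One row per (analyte, component) with the signed loading and, when
    available, the analyte's chemical class — the shape a grouped loading
    bar chart needs.
    """
    k = lat.loadings.shape[1]
    for c in components:
        if not (1 <= c <= k):
            raise ValueError(f"component {c} outside fitted range 1..{k}")
    names = lat.analytes or [f"analyte_{j}" for j in range(lat.loadings.shape[0])]
    rows = []
    for c in components:
        for j, name in enumerate(names):
            rows.append({
                "analyte": name,
                "class": (analyte_class[name] if analyte_class is not None else ""),
                "component": c,
                "loading": float(lat.loadings[j, c - 1]),
            })
    return pd.DataFrame(rows)


def spearman_matrix(M: np.ndarray | pd.DataFrame, min_periods: int = 3,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix (ties mid-ranked).

    Pairs with fewer than ``min_periods`` complete observations are NaN,
    never silently zero.
    """
    if not isinstance(M, pd.DataFrame):
        M = pd.DataFrame(np.asarray(M, dtype=float), columns=columns)
    corr = M.corr(method="spearman", min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def block_correlation_summary(corr: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Mean absolute correlation within and between chemical-class blocks."""
    rows = []
    cls = classes.loc[corr.columns]
    for c in cls.unique():
        inside = cls.index[cls == c]
        outside = cls.index[cls != c]
        block = corr.loc[inside, inside].values
        off = block[np.triu_indices_from(block, k=1)]
        between = corr.loc[inside, outside].values.ravel() if len(outside) else np.array([])
        rows.append({
            "class": c,
            "within_mean_abs": float(np.nanmean(np.abs(off))) if off.size else np.nan,
            "between_mean_abs": float(np.nanmean(np.abs(between))) if between.size else np.nan,
        })
    return pd.DataFrame(rows).set_index("class")


@dataclass
class DenoisingComparison:
    raw_corr: pd.DataFrame
    denoised_corr: pd.DataFrame
    raw_blocks: pd.DataFrame | None
    denoised_blocks: pd.DataFrame | None


def compare_raw_denoised(X: np.ndarray | pd.DataFrame, L: np.ndarray,
                         classes: pd.Series | None = None,
                         columns: list[str] | None = None) -> DenoisingComparison:
    """Spearman structure of the raw matrix vs its low-rank denoised version.

    Denoising through the low-rank component suppresses entrywise noise and
    sparse spikes, so chemical-class blocks should cohere more strongly
    (higher within-block mean |ρ|) in the denoised matrix.
    """
    if isinstance(X, pd.DataFrame):
        columns = columns or list(X.columns)
    Xv = np.asarray(X, dtype=float)
    Lv = np.asarray(L, dtype=float)
    if Xv.shape != Lv.shape:
        raise ValueError(f"shape mismatch: {Xv.shape} vs {Lv.shape}")
    raw = spearman_matrix(Xv, columns=columns)
    den = spearman_matrix(Lv, columns=columns)
    rb = db = None
    if classes is not None:
        rb = block_correlation_summary(raw, classes)
        db = block_correlation_summary(den, classes)
    return DenoisingComparison(raw_corr=raw, denoised_corr=den,
                               raw_blocks=rb, denoised_blocks=db)
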