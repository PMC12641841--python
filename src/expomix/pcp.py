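"""Non-negative low-rank + sparse decomposition under left-censoring (PCP-LOD).

The observed, column-scaled exposure matrix X is modelled as ``X = L + S``:
a non-negative low-rank component L (population co-exposure patterns) plus
a sparse component S (individual exposure spikes).  The fit minimizes

    ‖L‖* + λ‖S‖₁ + (μ/2) · Σ_ij f_ij(L + S)

where for a non-missing *detected* cell ``f_ij = ((L+S)_ij − X_ij)²``; for
a *censored* cell (measured below its LOD) the fit term is the squared
Euclidean distance of ``(L+S)_ij`` to the admissible interval
``[0, LOD_j]`` — zero when the reconstruction already lies below the
detection limit; and *missing* cells contribute nothing.  Censoring is
thus an interval constraint, not an imputed value.

Two decomposition paths are available:

* **Nuclear-norm path** (``rank=None``): the low-rank structure is induced
  purely by the nuclear penalty above (convex).
* **Rank-constrained path** (``rank=r``): the nuclear penalty is replaced
  by the hard constraint rank(L) ≤ r, i.e. the objective becomes
  ``λ‖S‖₁ + (μ/2)·Σ f_ij`` subject to ``rank(L) ≤ r, L ≥ 0``.  Because no
  singular-value shrinkage biases L, this path recovers clean low-rank
  structure essentially exactly, and it matches the treatment of the
  target rank as an explicit tuning parameter.

The solver alternates proximal steps with step size 1/μ: a singular-value
step for L (soft-thresholding on the nuclear path, hard rank-r truncation
on the rank path) followed by projection onto the non-negative orthant,
and entrywise soft-thresholding for S.  The non-negativity projection
after the singular-value step is an inexact prox, so the L-step backtracks
(halving the step, finally keeping the previous iterate) whenever it would
increase the objective; the objective trace is therefore non-increasing by
construction.

Tuning parameters λ (sparsity), μ (fit weight) and the target rank r are
selected by grid search on an LOD-aware reconstruction loss that scores
only detected cells, either on the training cells themselves or on a
held-out random subset of detected cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PCPParams:
    """Tuning parameters of the decomposition."""

    lam: float
    mu: float
    rank: int | None = None
    max_iter: int = 10_000
    tol: float = 1e-6

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if self.lam <= 0 or self.mu <= 0:
            raise ValueError("lam and mu must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rank is not None:
            if self.rank <= 0:
                raise ValueError("rank must be a positive integer")
            if shape is not None and self.rank > min(shape):
                raise ValueError(f"rank {self.rank} exceeds min matrix dimension {min(shape)}")


@dataclass
class PCPResult:
    L: np.ndarray
    S: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    params: PCPParams


@dataclass
class CVReport:
    grid: list[PCPParams]
    losses: list[float]
    holdout_losses: list[float] | None
    best: PCPParams
    best_index: int
    mode: str


def default_lambda(n_rows: int, n_cols: int) -> float:
    """Standard robust-PCA sparsity weight, 1/√max(n, p)."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("dimensions must be positive")
    return 1.0 / np.sqrt(max(n_rows, n_cols))


def default_mu(n_rows: int, n_cols: int) -> float:
    """Default fit weight 10·√max(n, p).

    The per-iteration singular-value shrinkage is 1/μ, so this keeps the
    low-rank bias small relative to desk-scale matrices while leaving the
    noise/fit trade-off to cross-validation.
    """
    return 10.0 * np.sqrt(max(n_rows, n_cols))


def lod_aware_loss(X: np.ndarray, X_hat: np.ndarray, lod: np.ndarray,
                   detect_flag: np.ndarray, missing_mask: np.ndarray | None = None,
                   eval_mask: np.ndarray | None = None) -> float:
    """Reconstruction loss over detected cells only.

    Σ (X_ij − X̂_ij)² over cells that are non-missing and detected (the
    measurement exceeded its detection limit); censored and missing cells
    contribute exactly zero.  ``eval_mask`` optionally restricts the sum
    further (used for held-out scoring).
    """
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    detect = np.asarray(detect_flag, dtype=bool)
    if detect.shape != X.shape:
        raise ValueError("detect_flag shape mismatch")
    use = detect.copy()
    if missing_mask is not None:
        use &= ~np.asarray(missing_mask, dtype=bool)
    if eval_mask is not None:
        use &= np.asarray(eval_mask, dtype=bool)
    diff = np.where(use, X - X_hat, 0.0)
    return float(np.sum(diff * diff))


def _fit_residual(M: np.ndarray, X: np.ndarray, lod: np.ndarray,
                  detect: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Gradient residual of the data term: M − target, zero off-support.

    Detected cells pull M toward X; censored cells pull toward the nearest
    point of [0, LOD]; missing cells exert no pull.
    """
    R = np.zeros_like(M)
    R[detect] = M[detect] - X[detect]
    clipped = np.clip(M, 0.0, lod[None, :])
    R[censored] = M[censored] - clipped[censored]
    return R


def _fit_term(M: np.ndarray, X: np.ndarray, lod: np.ndarray,
              detect: np.ndarray, censored: np.ndarray) -> float:
    d = M[detect] - X[detect]
    clipped = np.clip(M, 0.0, lod[None, :])
    c = M[censored] - clipped[censored]
    return float(d @ d + c @ c)


def _objective(L: np.ndarray, S: np.ndarray, X: np.ndarray, lod: np.ndarray,
               detect: np.ndarray, censored: np.ndarray, lam: float, mu: float,
               use_nuclear: bool) -> float:
    nuc = float(np.linalg.svd(L, compute_uv=False).sum()) if use_nuclear else 0.0
    return nuc + lam * float(np.abs(S).sum()) + 0.5 * mu * _fit_term(L + S, X, lod, detect, censored)


def _svt(M: np.ndarray, tau: float, rank: int | None) -> np.ndarray:
    """Singular-value soft-thresholding, optionally rank-truncated."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    if rank is not None:
        s[rank:] = 0.0
    keep = s > 0
    if not keep.any():
        return np.zeros_like(M)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _rank_proj(M: np.ndarray, rank: int) -> np.ndarray:
    """Best rank-r approximation (Eckart–Young)."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]


def decompose(X_scaled: np.ndarray, lod_scaled: np.ndarray,
              detect_flag: np.ndarray, missing_mask: np.ndarray | None = None,
              params: PCPParams | None = None) -> PCPResult:
    """Fit the censoring-aware low-rank + sparse decomposition.

    Parameters
    ----------
    X_scaled : array (n, p)
        Column-scaled observations. Values at censored or missing cells
        are ignored (they may be NaN).
    lod_scaled : array (p,)
        Per-analyte detection limits on the same scale as ``X_scaled``.
    detect_flag, missing_mask : boolean arrays (n, p)
        Cell states; censored = measured but not detected.
    """
    X = np.array(X_scaled, dtype=float)
    n, p = X.shape
    lod = np.broadcast_to(np.asarray(lod_scaled, dtype=float), (p,))
    detect = np.asarray(detect_flag, dtype=bool)
    missing = (np.zeros((n, p), bool) if missing_mask is None
               else np.asarray(missing_mask, dtype=bool))
    censored = ~detect & ~missing
    if params is None:
        params = PCPParams(lam=default_lambda(n, p), mu=default_mu(n, p))
    params.validate((n, p))
    if not np.all(np.isfinite(X[detect])):
        raise ValueError("non-finite values on detected cells")
    X = np.where(detect, X, 0.0)  # values off the detected support are never read

    lam, mu = params.lam, params.mu
    use_nuclear = params.rank is None
    step = 1.0 / mu

    # --- initialization -------------------------------------------------
    # Spectral warm start from the LOD/√2-substituted matrix (missing cells
    # at the column mean of observed values), followed, on the rank path,
    # by a threshold-continuation phase: the S-threshold decays
    # geometrically from the largest residual down to its final value λ/μ,
    # so the sparse component locks onto genuine spikes before the small
    # final threshold could let it absorb transient low-rank misfit (the
    # rank constraint makes the problem non-convex; without this phase the
    # alternating map can freeze at poor stationary points).
    sub = np.where(detect, X, (lod / np.sqrt(2.0))[None, :] * np.ones((n, p)))
    if missing.any():
        col_mean = np.nanmean(np.where(missing, np.nan, sub), axis=0)
        sub = np.where(missing, col_mean[None, :], sub)
    if use_nuclear:
        L = np.maximum(_svt(sub, step, None), 0.0)
    else:
        L = np.maximum(_rank_proj(sub, params.rank), 0.0)
    S = np.zeros((n, p))
    if not use_nuclear:
        theta = float(np.abs(np.where(detect, X - L, 0.0)).max(initial=0.0))
        usable = detect  # spikes are only identifiable on detected cells
        while theta > lam / mu:
            for _ in range(5):
                M = L + S
                gp = np.where(detect, X - S, L - (M - np.clip(M, 0.0, lod[None, :])))
                gp = np.where(missing, L, gp)
                L = np.maximum(_rank_proj(gp, params.rank), 0.0)
                resid = X - L
                S = np.where(usable,
                             np.sign(resid) * np.maximum(np.abs(resid) - theta, 0.0), 0.0)
            theta = max(0.5 * theta, lam / mu)
            if theta == lam / mu:
                break

    # --- monotone descent loop ------------------------------------------
    trace = []
    obj = _objective(L, S, X, lod, detect, censored, lam, mu, use_nuclear)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # L-step: prox of the low-rank penalty/constraint at the gradient
        # point (nuclear soft-threshold, or hard rank-r truncation), then
        # projection to the non-negative orthant; backtrack if the
        # (inexact) prox would increase the objective.
        R = _fit_residual(L + S, X, lod, detect, censored)
        t = step
        L_new = L
        for _ in range(8):
            grad_pt = L - t * mu * R
            if use_nuclear:
                cand = np.maximum(_svt(grad_pt, t, None), 0.0)
            else:
                cand = np.maximum(_rank_proj(grad_pt, params.rank), 0.0)
            cand_obj = _objective(cand, S, X, lod, detect, censored, lam, mu, use_nuclear)
            if cand_obj <= obj + 1e-12:
                L_new, obj = cand, cand_obj
                break
            t *= 0.5

        # S-step: exact prox (entrywise soft-threshold), always descends
        R = _fit_residual(L_new + S, X, lod, detect, censored)
        S_new = np.sign(S - step * mu * R) * np.maximum(np.abs(S - step * mu * R) - step * lam, 0.0)
        obj = _objective(L_new, S_new, X, lod, detect, censored, lam, mu, use_nuclear)
        trace.append(obj)

        denom = max(np.linalg.norm(L) + np.linalg.norm(S), 1.0)
        delta = (np.linalg.norm(L_new - L) + np.linalg.norm(S_new - S)) / denom
        L, S = L_new, S_new
        if delta < params.tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"PCP-LOD did not converge in {params.max_iter} iterations "
                      f"(last relative change {delta:.2e})", RuntimeWarning)
    return PCPResult(L=L, S=S, objective_trace=np.asarray(trace),
                     converged=converged, n_iter=it, params=params)


def cross_validate(X_scaled: np.ndarray, lod_scaled: np.ndarray,
                   detect_flag: np.ndarray, missing_mask: np.ndarray | None,
                   grid: list[PCPParams], mode: str = "reconstruction",
                   holdout_fraction: float = 0.1, seed: int = 0) -> CVReport:
    """Grid-search λ, μ, r by the LOD-aware reconstruction loss.

    ``mode="reconstruction"`` scores each fit on all detected cells (the
    criterion as published); ``mode="holdout"`` masks a random
    ``holdout_fraction`` of detected cells before fitting and scores only
    those, which penalizes overfitting.  Both losses are reported.  Ties
    break toward the smallest rank, then smallest λ, then smallest μ
    (parsimony, and determinism).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if mode not in ("reconstruction", "holdout"):
        raise ValueError("mode must be 'reconstruction' or 'holdout'")
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    detect = np.asarray(detect_flag, dtype=bool)
    missing = (np.zeros((n, p), bool) if missing_mask is None
               else np.asarray(missing_mask, dtype=bool))

    holdout = None
    if mode == "holdout":
        rng = np.random.default_rng(seed)
        idx = np.argwhere(detect & ~missing)
        k = max(1, int(round(holdout_fraction * len(idx))))
        sel = idx[rng.choice(len(idx), size=k, replace=False)]
        holdout = np.zeros((n, p), dtype=bool)
        holdout[sel[:, 0], sel[:, 1]] = True

    losses, holdout_losses = [], []
    for params in grid:
        try:
            if holdout is None:
                res = decompose(X, lod_scaled, detect, missing, params)
                loss = lod_aware_loss(X, res.L + res.S, lod_scaled, detect, missing)
                h_loss = np.nan
            else:
                res = decompose(X, lod_scaled, detect, missing | holdout, params)
                loss = lod_aware_loss(X, res.L + res.S, lod_scaled, detect, missing)
                h_loss = lod_aware_loss(X, res.L + res.S, lod_scaled, detect,
                                        missing, eval_mask=holdout)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite loss")
        except Exception as exc:  # a failing grid point is logged, not fatal
            logger.warning("grid point %r failed: %s", params, exc)
            loss, h_loss = np.inf, np.inf
        losses.append(float(loss))
        holdout_losses.append(float(h_loss))

    score = holdout_losses if mode == "holdout" else losses
    order = sorted(range(len(grid)),
                   key=lambda i: (score[i],
                                  grid[i].rank if grid[i].rank is not None else np.inf,
                                  grid[i].lam, grid[i].mu))
    best_index = order[0]
    return CVReport(grid=list(grid), losses=losses,
                    holdout_losses=holdout_losses if mode == "holdout" else None,
                    best=grid[best_index], best_index=best_index, mode=mode)
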