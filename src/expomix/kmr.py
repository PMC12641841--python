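"""Bayesian kernel machine regression for chemical mixtures.

Model:  Y_i = h(X_i) + Z_i β + ε_i,   ε_i ~ N(0, σ²)

where h is an unknown smooth exposure–response surface over the M mixture
members, given a Gaussian-process prior with covariance σ²τ·K and the
Gaussian kernel

    K(x_i, x_j) = exp( − Σ_m γ_m (x_im − x_jm)² / ρ )

ρ > 0 controls smoothness (larger ρ, smoother h) and γ_m ∈ {0, 1} are
binary inclusion indicators with prior inclusion probability π, which
yield posterior inclusion probabilities (PIPs) for each mixture member.

Sampling: h is marginalized analytically (Gaussian outcome, so
Y ~ N(Zβ, σ²(I + τK)) in closed form).  Per iteration the sampler draws
β and σ² from their conjugate conditionals, then performs Metropolis
updates of each γ_m (single-flip sweep), of log ρ and of log τ against
the marginal likelihood.  Predictions of h use the Gaussian-process
conditional mean and covariance per posterior draw.

Priors: β ~ N(0, 10⁴·I); σ² ~ Inv-Gamma(0.001, 0.001); log ρ and log τ
uniform on bounded ranges (ρ ∈ [0.1·M, 100·M] scaled by the number of
included coordinates' natural distance scale via the init; τ ∈ [0.01,
100]); γ_m ~ Bernoulli(π), π = 0.5 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = [
    "KMRModel", "KMRPosterior", "EffectEstimate", "gaussian_kernel", "fit",
    "pip", "univariate_effect", "exposure_response_curve", "bivariate_surface",
    "overall_mixture_effect",
]

RHO_BOUNDS = (0.1, 1000.0)
TAU_BOUNDS = (0.01, 100.0)
BETA_PRIOR_VAR = 1.0e4
SIGMA2_PRIOR = (0.001, 0.001)  # Inv-Gamma shape, rate
JITTER = 1e-8


def gaussian_kernel(xi: np.ndarray, xj: np.ndarray, rho: float,
                    included: np.ndarray | None = None) -> float:
    """Similarity exp(−Σ_m γ_m (x_im − x_jm)²/ρ) between two exposure profiles."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    d2 = (xi - xj) ** 2
    if included is not None:
        d2 = d2 * np.asarray(included, dtype=float)
    return float(np.exp(-d2.sum() / rho))


@dataclass
class KMRModel:
    """Data and prior settings for one outcome's mixture regression.

    Exposure columns are standardized to unit SD internally; quantile-based
    effect summaries are taken on the original scale and mapped through
    the stored scaling (a monotone map, so quantiles commute with it).
    """

    exposures: np.ndarray          # n × M, original scale
    covariates: np.ndarray         # n × q (an intercept is added internally)
    outcome: np.ndarray            # length n
    exposure_names: list[str] | None = None
    prior_inclusion: float = 0.5

    def __post_init__(self) -> None:
        X = np.asarray(self.exposures, dtype=float)
        y = np.asarray(self.outcome, dtype=float)
        Z = np.asarray(self.covariates, dtype=float)
        if X.ndim != 2:
            raise ValueError("exposures must be a 2-D matrix")
        n = X.shape[0]
        if y.shape != (n,) or Z.shape[0] != n:
            raise ValueError("outcome/covariate rows must match exposures")
        if n < 30:
            raise ValueError("kernel machine regression needs n >= 30")
        if np.isnan(X).any() or np.isnan(y).any() or np.isnan(Z).any():
            raise ValueError("missing values in the modelling table")
        if not (0 < self.prior_inclusion < 1):
            raise ValueError("prior_inclusion must be in (0, 1)")
        self.exposures = X
        self.outcome = y
        self.covariates = Z
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("constant exposure column")
        self._scale = sd
        self._Xs = X / sd
        self._Z1 = np.column_stack([np.ones(n), Z])

    @property
    def n(self) -> int:
        return self.exposures.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.exposures.shape[1]


@dataclass
class KMRPosterior:
    """Post-fit container: draws, diagnostics and the training data."""

    model: KMRModel
    gamma: np.ndarray       # n_iter × M
    rho: np.ndarray
    tau: np.ndarray
    sigma2: np.ndarray
    beta: np.ndarray        # n_iter × (q+1), column 0 = intercept
    n_iter: int
    n_burn: int
    seed: int
    acceptance_rates: dict[str, float]

    def _kept(self) -> slice:
        return slice(self.n_burn, self.n_iter)


@dataclass
class EffectEstimate:
    estimate: float
    lower95: float
    upper95: float
    context: str = ""

    def __post_init__(self) -> None:
        if not (self.lower95 - 1e-9 <= self.estimate <= self.upper95 + 1e-9):
            raise ValueError("credible interval does not bracket the estimate")


def _marginal_loglik(y: np.ndarray, Z: np.ndarray, beta: np.ndarray, sigma2: float,
                     chol_V: np.ndarray) -> float:
    n = y.shape[0]
    r = y - Z @ beta
    w = solve_triangular(chol_V, r, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(chol_V)).sum()
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + (w @ w) / sigma2)


def _build_V_chol(A: np.ndarray, rho: float, tau: float) -> tuple[np.ndarray, np.ndarray]:
    K = np.exp(A * (-1.0 / rho))
    V = tau * K
    V.flat[:: A.shape[0] + 1] += 1.0 + JITTER
    return K, np.linalg.cholesky(V)


def fit(model: KMRModel, n_iter: int = 2000, n_burn: int = 1000,
        seed: int = 0) -> KMRPosterior:
    """Run the MCMC sampler; fully reproducible from ``seed``.

    Desk-scale defaults (2,000 iterations, 1,000 burn-in) suit n ≤ 600.
    """
    if n_burn >= n_iter:
        raise ValueError("n_burn must be smaller than n_iter")
    rng = np.random.default_rng(seed)
    Xs, Z, y = model._Xs, model._Z1, model.outcome
    n, M = Xs.shape
    q = Z.shape[1]
    pi = model.prior_inclusion
    prior_odds = np.log(pi) - np.log1p(-pi)

    # per-exposure squared-distance matrices, reused by every kernel build
    D = np.empty((M, n, n))
    for m in range(M):
        d = Xs[:, m][:, None] - Xs[:, m][None, :]
        D[m] = d * d

    # initial state
    gamma = np.ones(M, dtype=bool)
    A = D.sum(axis=0)
    off = A[np.triu_indices(n, k=1)]
    rho = float(np.median(off)) if np.median(off) > 0 else 1.0
    rho = float(np.clip(rho, *RHO_BOUNDS))
    tau = 1.0
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sigma2 = max(float(resid @ resid) / max(n - q, 1), 1e-6)

    K, cholV = _build_V_chol(A, rho, tau)
    loglik = _marginal_loglik(y, Z, beta, sigma2, cholV)

    draws_gamma = np.empty((n_iter, M), dtype=bool)
    draws_rho = np.empty(n_iter)
    draws_tau = np.empty(n_iter)
    draws_sigma2 = np.empty(n_iter)
    draws_beta = np.empty((n_iter, q))
    acc = {"gamma": 0, "rho": 0, "tau": 0}
    tries = {"gamma": 0, "rho": 0, "tau": 0}
    a0, b0 = SIGMA2_PRIOR

    for it in range(n_iter):
        # --- β | rest : conjugate Gaussian (prior N(0, c I)) -------------
        Vinv_Z = cho_solve((cholV, True), Z, check_finite=False)
        Vinv_y = cho_solve((cholV, True), y, check_finite=False)
        prec = Z.T @ Vinv_Z / sigma2 + np.eye(q) / BETA_PRIOR_VAR
        cov = np.linalg.inv(prec)
        mean = cov @ (Z.T @ Vinv_y / sigma2)
        beta = rng.multivariate_normal(mean, cov, method="cholesky")

        # --- σ² | rest : conjugate inverse-gamma -------------------------
        r = y - Z @ beta
        w = solve_triangular(cholV, r, lower=True)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * (w @ w)))
        loglik = _marginal_loglik(y, Z, beta, sigma2, cholV)

        # --- γ: single-flip Metropolis on a random half of the
        # coordinates per iteration (full sweeps double the cost for
        # negligible gain in effective sample size at these chain lengths)
        for m in rng.choice(M, size=max(1, M // 2), replace=False):
            tries["gamma"] += 1
            A_prop = A - D[m] if gamma[m] else A + D[m]
            K_prop, cholV_prop = _build_V_chol(A_prop, rho, tau)
            ll_prop = _marginal_loglik(y, Z, beta, sigma2, cholV_prop)
            # prior ratio: + for inclusion, − for exclusion
            dprior = -prior_odds if gamma[m] else prior_odds
            if np.log(rng.uniform()) < ll_prop - loglik + dprior:
                gamma[m] = ~gamma[m]
                A, K, cholV, loglik = A_prop, K_prop, cholV_prop, ll_prop
                acc["gamma"] += 1

        # --- ρ: random walk on log scale ---------------------------------
        tries["rho"] += 1
        rho_prop = float(np.exp(np.log(rho) + rng.normal(scale=0.5)))
        if RHO_BOUNDS[0] <= rho_prop <= RHO_BOUNDS[1]:
            K_prop, cholV_prop = _build_V_chol(A, rho_prop, tau)
            ll_prop = _marginal_loglik(y, Z, beta, sigma2, cholV_prop)
            if np.log(rng.uniform()) < ll_prop - loglik:
                rho, K, cholV, loglik = rho_prop, K_prop, cholV_prop, ll_prop
                acc["rho"] += 1

        # --- τ: random walk on log scale ---------------------------------
        tries["tau"] += 1
        tau_prop = float(np.exp(np.log(tau) + rng.normal(scale=0.5)))
        if TAU_BOUNDS[0] <= tau_prop <= TAU_BOUNDS[1]:
            K_prop, cholV_prop = _build_V_chol(A, rho, tau_prop)
            ll_prop = _marginal_loglik(y, Z, beta, sigma2, cholV_prop)
            if np.log(rng.uniform()) < ll_prop - loglik:
                tau, K, cholV, loglik = tau_prop, K_prop, cholV_prop, ll_prop
                acc["tau"] += 1

        if not np.isfinite(loglik):
            raise FloatingPointError(
                f"non-finite marginal likelihood at iteration {it} "
                f"(rho={rho}, tau={tau}, sigma2={sigma2})")

        draws_gamma[it] = gamma
        draws_rho[it] = rho
        draws_tau[it] = tau
        draws_sigma2[it] = sigma2
        draws_beta[it] = beta

    rates = {k: acc[k] / tries[k] for k in acc}
    return KMRPosterior(model=model, gamma=draws_gamma, rho=draws_rho, tau=draws_tau,
                        sigma2=draws_sigma2, beta=draws_beta, n_iter=n_iter,
                        n_burn=n_burn, seed=seed, acceptance_rates=rates)


def pip(posterior: KMRPosterior) -> np.ndarray:
    """Posterior inclusion probability per exposure (post-burn-in mean of γ)."""
    return posterior.gamma[posterior._kept()].mean(axis=0)


# ---------------------------------------------------------------------------
# h prediction and effect summaries
# ---------------------------------------------------------------------------

def _quantile_point(posterior: KMRPosterior, q_per_exposure: np.ndarray) -> np.ndarray:
    """Exposure profile at given per-exposure quantiles, on the fitted scale."""
    X = posterior.model.exposures
    point = np.array([np.quantile(X[:, m], q_per_exposure[m]) for m in range(X.shape[1])])
    return point / posterior.model._scale


def _h_samples(posterior: KMRPosterior, points: np.ndarray, thin: int = 5,
               max_draws: int = 200) -> np.ndarray:
    """Sample h at ``points`` (g × M, scaled) per thinned posterior draw.

    For each retained draw the Gaussian-process conditional of h given the
    data is formed analytically and one h-vector is sampled from it.
    Returns an array (n_draws, g).
    """
    model = posterior.model
    Xs, Z, y = model._Xs, model._Z1, model.outcome
    n, M = Xs.shape
    kept = np.arange(posterior.n_burn, posterior.n_iter)
    if thin > 1:
        kept = kept[::thin]
    if len(kept) > max_draws:
        kept = kept[np.linspace(0, len(kept) - 1, max_draws).astype(int)]
    g = points.shape[0]
    rng = np.random.default_rng(posterior.seed + 100_003)

    # distances from grid points to training points and among grid points
    d_train = np.empty((M, g, n))
    d_grid = np.empty((M, g, g))
    for m in range(M):
        dt = points[:, m][:, None] - Xs[:, m][None, :]
        dg = points[:, m][:, None] - points[:, m][None, :]
        d_train[m] = dt * dt
        d_grid[m] = dg * dg
    D_train = np.empty((M, n, n))
    for m in range(M):
        d = Xs[:, m][:, None] - Xs[:, m][None, :]
        D_train[m] = d * d

    out = np.empty((len(kept), g))
    # distance aggregates depend only on the inclusion pattern, which changes
    # rarely along a well-mixed chain: cache them per unique γ
    cache: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for idx, it in enumerate(kept):
        gam = posterior.gamma[it].astype(float)
        rho = posterior.rho[it]
        tau = posterior.tau[it]
        s2 = posterior.sigma2[it]
        beta = posterior.beta[it]
        # gam all-zero is handled by the general path: K becomes the all-ones
        # matrix, i.e. h collapses to a constant shared across all points
        key = posterior.gamma[it].tobytes()
        if key not in cache:
            cache[key] = (np.tensordot(gam, D_train, axes=1),
                          np.tensordot(gam, d_train, axes=1),
                          np.tensordot(gam, d_grid, axes=1))
        A, a_tg, a_gg = cache[key]
        K = np.exp(-A / rho)
        K_star = np.exp(-a_tg / rho)          # g × n
        K_grid = np.exp(-a_gg / rho)          # g × g
        V = tau * K + np.eye(n) * (1.0 + JITTER)
        cf = cho_factor(V, lower=True)
        r = y - Z @ beta
        mean = tau * (K_star @ cho_solve(cf, r))
        B = cho_solve(cf, K_star.T)           # n × g
        cov = s2 * (tau * K_grid - tau * tau * (K_star @ B))
        cov = 0.5 * (cov + cov.T) + np.eye(g) * 1e-10
        try:
            cl = cholesky(cov, lower=True)
        except np.linalg.LinAlgError:
            w, Q = np.linalg.eigh(cov)
            cl = Q * np.sqrt(np.clip(w, 0.0, None))
        out[idx] = mean + cl @ rng.standard_normal(g)
    return out


def _summarize(samples: np.ndarray, context: str) -> EffectEstimate:
    return EffectEstimate(
        estimate=float(np.mean(samples)),
        lower95=float(np.quantile(samples, 0.025)),
        upper95=float(np.quantile(samples, 0.975)),
        context=context,
    )


def univariate_effect(posterior: KMRPosterior, exposure: int, from_q: float = 0.25,
                      to_q: float = 0.75, others_at: float = 0.5) -> EffectEstimate:
    """Effect of moving one exposure between two of its quantiles.

    Posterior summary of h(x_m = Q(to_q), others at Q(others_at)) −
    h(x_m = Q(from_q), same others).
    """
    M = posterior.model.n_exposures
    ctx = (f"exposure {exposure}: Q({from_q})→Q({to_q}), others at Q({others_at})")
    if from_q == to_q:
        return EffectEstimate(0.0, 0.0, 0.0, ctx)
    X = posterior.model.exposures
    if np.quantile(X[:, exposure], to_q) == np.quantile(X[:, exposure], from_q):
        warnings.warn(f"exposure {exposure} has a degenerate {from_q}-{to_q} "
                      "interquantile range; contrast is zero-width", RuntimeWarning)
    qs = np.full(M, others_at)
    qs_hi, qs_lo = qs.copy(), qs.copy()
    qs_hi[exposure], qs_lo[exposure] = to_q, from_q
    pts = np.vstack([_quantile_point(posterior, qs_hi), _quantile_point(posterior, qs_lo)])
    h = _h_samples(posterior, pts)
    return _summarize(h[:, 0] - h[:, 1], ctx)


def exposure_response_curve(posterior: KMRPosterior, exposure: int,
                            grid: np.ndarray | list[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
                            others_at: float = 0.5, ref_q: float = 0.25,
                            interaction_background: tuple[float, float] = (0.25, 0.75),
                            ) -> tuple[list[EffectEstimate], list[EffectEstimate]]:
    """Exposure–response curve plus an interaction contrast.

    The curve gives, for each grid quantile q, the posterior contrast
    h(x_m=Q(q), others at Q(others_at)) − h(x_m=Q(ref_q), same others); a
    single-point grid therefore reduces to :func:`univariate_effect` with
    ``from_q=ref_q``.  The interaction contrast repeats the curve with the
    background exposures at the high vs the low quantile of
    ``interaction_background`` and reports the difference — zero (up to
    posterior noise) when h is additive in the mixture members.
    """
    M = posterior.model.n_exposures
    grid = list(grid)
    lo_bg, hi_bg = interaction_background

    def curve_points(bg: float) -> np.ndarray:
        rows = []
        for q in grid + [ref_q]:
            qs = np.full(M, bg)
            qs[exposure] = q
            rows.append(_quantile_point(posterior, qs))
        return np.vstack(rows)

    pts_main = curve_points(others_at)
    h_main = _h_samples(posterior, pts_main)
    curve = [
        _summarize(h_main[:, i] - h_main[:, -1],
                   f"exposure {exposure} at Q({q}) vs Q({ref_q}), others at Q({others_at})")
        for i, q in enumerate(grid)
    ]
    h_lo = _h_samples(posterior, curve_points(lo_bg))
    h_hi = _h_samples(posterior, curve_points(hi_bg))
    contrast = [
        _summarize((h_hi[:, i] - h_hi[:, -1]) - (h_lo[:, i] - h_lo[:, -1]),
                   f"interaction: exposure {exposure} at Q({q}), background "
                   f"Q({hi_bg}) vs Q({lo_bg})")
        for i, q in enumerate(grid)
    ]
    return curve, contrast


def bivariate_surface(posterior: KMRPosterior, exposure_a: int, exposure_b: int,
                      b_at: tuple[float, ...] = (0.25, 0.5, 0.75),
                      a_grid: np.ndarray | list[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
                      ) -> dict[float, list[EffectEstimate]]:
    """Predicted h along exposure *a* with exposure *b* pinned at quantiles.

    All remaining exposures sit at their medians.  When ``a == b`` the
    conditioning is vacuous and the univariate curve is returned for each
    requested quantile (the diagonal convention of a pairwise panel grid).
    """
    M = posterior.model.n_exposures
    a_grid = list(a_grid)
    out: dict[float, list[EffectEstimate]] = {}
    for qb in b_at:
        rows = []
        for qa in a_grid:
            qs = np.full(M, 0.5)
            qs[exposure_a] = qa
            if exposure_b != exposure_a:
                qs[exposure_b] = qb
            rows.append(_quantile_point(posterior, qs))
        h = _h_samples(posterior, np.vstack(rows))
        out[qb] = [
            _summarize(h[:, i],
                       f"h at exposure {exposure_a}=Q({qa}), exposure {exposure_b}=Q({qb})")
            for i, qa in enumerate(a_grid)
        ]
    return out


def overall_mixture_effect(posterior: KMRPosterior,
                           grid: np.ndarray | list[float] = (0.25, 0.35, 0.5, 0.65, 0.75),
                           ) -> list[EffectEstimate]:
    """Joint mixture effect: all exposures at quantile q vs all at the median."""
    M = posterior.model.n_exposures
    grid = list(grid)
    pts = np.vstack([_quantile_point(posterior, np.full(M, q)) for q in grid]
                    + [_quantile_point(posterior, np.full(M, 0.5))])
    h = _h_samples(posterior, pts)
    out = []
    for i, q in enumerate(grid):
        if q == 0.5:
            out.append(EffectEstimate(0.0, 0.0, 0.0, "all exposures at Q(0.5) vs Q(0.5)"))
        else:
            out.append(_summarize(h[:, i] - h[:, -1],
                                  f"all exposures at Q({q}) vs Q(0.5)"))
    return out
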