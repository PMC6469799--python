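"""Multi-trait finite mixture of regressions (MFMR).

Each latent subtype k has its own coefficients for the "heterogeneous"
design G (whose intercept column carries the subtype main effects), while
the "homogeneous" design X has coefficients shared across subtypes.
Quantitative traits are Gaussian with per-subtype residual variances;
binary traits use probit links on a unit latent scale.  Traits are
conditionally independent given the subtype.

Fitting is by Expectation Conditional-Maximization: the E-step updates
responsibilities; CM-steps solve the responsibility-weighted least-squares
problem per quantitative trait (jointly over shared and subtype-specific
coefficients) and a responsibility-weighted probit regression per binary
trait on an expanded design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "TraitMatrix",
    "CovariateSet",
    "SubtypePosterior",
    "MFMRParams",
    "FitOptions",
    "fit_mfmr",
    "e_step",
    "cm_step_quantitative",
    "cm_step_binary",
    "log_likelihood",
    "cv_select_K",
    "predict_subtypes",
]

_LOG2PI = np.log(2 * np.pi)


# ----------------------------------------------------------------------
# data containers


@dataclass
class TraitMatrix:
    """Quantitative trait block (N, P) and binary trait block (N, B)."""

    quant: np.ndarray
    binary: np.ndarray
    names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.quant = np.atleast_2d(np.asarray(self.quant, dtype=float))
        self.binary = np.asarray(self.binary)
        if self.binary.size == 0:
            self.binary = np.zeros((self.quant.shape[0], 0), dtype=int)
        self.binary = np.atleast_2d(self.binary).astype(int)
        if self.quant.shape[0] != self.binary.shape[0]:
            raise ValueError("quant and binary blocks must share N")
        if np.isnan(self.quant).any():
            raise ValueError("missing values in quantitative traits; impute first")
        bad = ~np.isin(self.binary, (0, 1))
        if bad.any():
            raise ValueError("binary traits must contain only 0/1")
        if self.names is None:
            self.names = [f"q{j+1}" for j in range(self.quant.shape[1])] + [
                f"b{j+1}" for j in range(self.binary.shape[1])
            ]
        if len(self.names) != self.quant.shape[1] + self.binary.shape[1]:
            raise ValueError("names must cover all traits")

    @property
    def n_samples(self) -> int:
        return self.quant.shape[0]

    @property
    def n_quant(self) -> int:
        return self.quant.shape[1]

    @property
    def n_binary(self) -> int:
        return self.binary.shape[1]


@dataclass
class CovariateSet:
    """Homogeneous design X (shared effects) and heterogeneous design G.

    G's first column must be an intercept; its subtype-specific
    coefficients are the subtype main effects.  X may be empty (N, 0).
    """

    homogeneous: np.ndarray
    heterogeneous: np.ndarray
    hom_names: Optional[list[str]] = None
    het_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.heterogeneous = np.atleast_2d(np.asarray(self.heterogeneous, dtype=float))
        n = self.heterogeneous.shape[0]
        if self.homogeneous is None or np.size(self.homogeneous) == 0:
            self.homogeneous = np.zeros((n, 0))
        self.homogeneous = np.atleast_2d(np.asarray(self.homogeneous, dtype=float))
        if self.homogeneous.shape[0] != n:
            raise ValueError("X and G must share N")
        g0 = self.heterogeneous[:, 0]
        if not np.allclose(g0, g0[0]) or g0[0] == 0:
            raise ValueError("first column of the heterogeneous design must be an intercept")
        if np.ptp(self.homogeneous, axis=0).size and (np.ptp(self.homogeneous, axis=0) == 0).any():
            raise ValueError("constant column in X: the intercept belongs in G")
        if self.hom_names is None:
            self.hom_names = [f"x{j+1}" for j in range(self.homogeneous.shape[1])]
        if self.het_names is None:
            self.het_names = ["intercept"] + [
                f"g{j}" for j in range(1, self.heterogeneous.shape[1])
            ]

    @property
    def n_samples(self) -> int:
        return self.heterogeneous.shape[0]

    @property
    def n_hom(self) -> int:
        return self.homogeneous.shape[1]

    @property
    def n_het(self) -> int:
        return self.heterogeneous.shape[1]


@dataclass
class SubtypePosterior:
    """Membership probabilities Z (N, K) and mixing proportions p (K,)."""

    Z: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.p = np.asarray(self.p, dtype=float)
        if not np.allclose(self.Z.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("responsibility rows must sum to 1")
        if (self.Z < -1e-9).any() or (self.Z > 1 + 1e-9).any():
            raise ValueError("responsibilities must lie in [0,1]")
        if not np.isclose(self.p.sum(), 1.0, atol=1e-6):
            raise ValueError("mixing proportions must sum to 1")

    @property
    def n_subtypes(self) -> int:
        return self.Z.shape[1]

    @property
    def hard_labels(self) -> np.ndarray:
        """1-based argmax labels."""
        return self.Z.argmax(axis=1) + 1


@dataclass
class MFMRParams:
    """Fitted generative model.

    ``beta_quant`` has shape (K, L, P); its intercept row (l = 0) carries
    the subtype main effects.  Binary-trait coefficients live on the unit
    probit scale.
    """

    alpha_quant: np.ndarray  # (Q, P)
    beta_quant: np.ndarray  # (K, L, P)
    sigma2: np.ndarray  # (K, P) > 0
    alpha_binary: np.ndarray  # (Q, B)
    beta_binary: np.ndarray  # (K, L, B)
    p: np.ndarray  # (K,)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if (np.asarray(self.sigma2) <= 0).any():
            raise ValueError("sigma2 must be positive")

    @property
    def n_subtypes(self) -> int:
        return len(self.p)

    @property
    def gamma_quant(self) -> np.ndarray:
        """Subtype main effects on quantitative traits (K, P)."""
        return self.beta_quant[:, 0, :]


@dataclass
class FitOptions:
    K: int = 2
    n_restarts: int = 10
    gmm_init: bool = True
    max_iter: int = 1000
    rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


# ----------------------------------------------------------------------
# likelihood pieces


def _log_component_densities(
    params: MFMRParams, traits: TraitMatrix, covariates: CovariateSet
) -> np.ndarray:
    """(N, K) log density of each sample's traits under each subtype."""
    x, g = covariates.homogeneous, covariates.heterogeneous
    n, k = traits.n_samples, params.n_subtypes
    out = np.zeros((n, k))
    if traits.n_quant:
        base = x @ params.alpha_quant if covariates.n_hom else 0.0
        for j in range(k):
            mu = base + g @ params.beta_quant[j]
            resid2 = (traits.quant - mu) ** 2
            s2 = params.sigma2[j]
            out[:, j] += (-0.5 * (_LOG2PI + np.log(s2)) - 0.5 * resid2 / s2).sum(axis=1)
    if traits.n_binary:
        base_b = x @ params.alpha_binary if covariates.n_hom else 0.0
        sign = 2.0 * traits.binary - 1.0  # {0,1} -> {-1,1}
        for j in range(k):
            eta = base_b + g @ params.beta_binary[j]
            out[:, j] += norm.logcdf(sign * eta).sum(axis=1)
    return out


def log_likelihood(
    params: MFMRParams, traits: TraitMatrix, covariates: CovariateSet
) -> float:
    """Observed-data mixture log-likelihood, computed in log space."""
    dens = _log_component_densities(params, traits, covariates)
    with np.errstate(divide="ignore"):
        logp = np.log(params.p)
    return float(logsumexp(dens + logp[None, :], axis=1).sum())


def e_step(
    params: MFMRParams, traits: TraitMatrix, covariates: CovariateSet
) -> SubtypePosterior:
    """Posterior responsibilities under the current parameters."""
    dens = _log_component_densities(params, traits, covariates)
    with np.errstate(divide="ignore"):
        logp = np.log(params.p)
    logz = dens + logp[None, :]
    logz -= logsumexp(logz, axis=1, keepdims=True)
    z = np.exp(logz)
    if np.isnan(z).any():
        raise FloatingPointError("NaN responsibilities")
    return SubtypePosterior(Z=z, p=params.p.copy())


def predict_subtypes(
    params: MFMRParams, traits: TraitMatrix, covariates: CovariateSet
) -> SubtypePosterior:
    """E-step under frozen parameters (out-of-sample subtype assignment)."""
    if traits.n_quant != params.alpha_quant.shape[1] or traits.n_binary != params.alpha_binary.shape[1]:
        raise ValueError("trait schema does not match the fitted model")
    if covariates.n_hom != params.alpha_quant.shape[0] or covariates.n_het != params.beta_quant.shape[1]:
        raise ValueError("covariate schema does not match the fitted model")
    return e_step(params, traits, covariates)


# ----------------------------------------------------------------------
# CM steps


def cm_step_quantitative(
    responsibilities: SubtypePosterior,
    traits: TraitMatrix,
    covariates: CovariateSet,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact CM update for quantitative-trait coefficients and variances.

    Per trait, jointly solves the responsibility-weighted least squares in
    the shared coefficients alpha and per-subtype coefficients beta_k
    (weights Z_ik / sigma2_kt via per-subtype Gram blocks), then updates
    sigma2 as the responsibility-weighted residual mean square.

    Returns ``(alpha, beta, sigma2)``.
    """
    return _cm_quant_weighted(responsibilities, traits, covariates, None, ridge)


def _solve_quant(xx, xg, gg, xy, gy, z, x, g, y, ridge, sigma2=None):
    k, q, l = xg.shape[0], xg.shape[1], xg.shape[2]
    n, p = y.shape
    dim = q + k * l
    alpha = np.zeros((q, p))
    beta = np.zeros((k, l, p))
    if sigma2 is None:
        sigma2_w = np.ones((k, p))
    else:
        sigma2_w = sigma2
    for t in range(p):
        a = np.zeros((dim, dim))
        b = np.zeros(dim)
        for j in range(k):
            w = 1.0 / sigma2_w[j, t]
            a[:q, :q] += w * xx[j]
            sl = slice(q + j * l, q + (j + 1) * l)
            a[:q, sl] = w * xg[j]
            a[sl, :q] = w * xg[j].T
            a[sl, sl] = w * gg[j]
            b[:q] += w * xy[j][:, t]
            b[sl] = w * gy[j][:, t]
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            warnings.warn("singular weighted normal equations; ridge fallback")
            sol = np.linalg.solve(a + ridge * np.trace(a) / dim * np.eye(dim), b)
        alpha[:, t] = sol[:q]
        beta[:, :, t] = sol[q:].reshape(k, l)

    # responsibility-weighted residual mean square per subtype/trait
    sigma2_new = np.empty((k, p))
    base = x @ alpha if q else 0.0
    zsum = z.sum(axis=0)
    for j in range(k):
        resid2 = (y - base - g @ beta[j]) ** 2
        sigma2_new[j] = (z[:, j] @ resid2) / np.maximum(zsum[j], 1e-12)
    sigma2_new = np.maximum(sigma2_new, 1e-10)
    return alpha, beta, sigma2_new


def _cm_quant_weighted(responsibilities, traits, covariates, sigma2, ridge=1e-8):
    """CM update using the current sigma2 as weights (exact conditional max)."""
    x, g = covariates.homogeneous, covariates.heterogeneous
    y = traits.quant
    z = responsibilities.Z
    k = z.shape[1]
    q, l = x.shape[1], g.shape[1]
    p = y.shape[1]
    xx = np.empty((k, q, q))
    xg = np.empty((k, q, l))
    gg = np.empty((k, l, l))
    xy = np.empty((k, q, p))
    gy = np.empty((k, l, p))
    for j in range(k):
        w = z[:, j]
        xw = x * w[:, None]
        gw = g * w[:, None]
        xx[j] = xw.T @ x
        xg[j] = xw.T @ g
        gg[j] = gw.T @ g
        xy[j] = xw.T @ y
        gy[j] = gw.T @ y
    return _solve_quant(xx, xg, gg, xy, gy, z, x, g, y, ridge, sigma2=sigma2)


def _weighted_probit(
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    coef0: Optional[np.ndarray] = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    clamp: float = 30.0,
) -> np.ndarray:
    """Fisher-scoring maximizer of the weighted probit log-likelihood.

    Step-halving guarantees the objective never decreases.  Coefficients
    exceeding ``clamp`` in absolute value (quasi-separation) are clipped
    with a warning.
    """
    n, d = design.shape
    coef = np.zeros(d) if coef0 is None else coef0.copy()
    sign = 2.0 * y - 1.0

    def loglik(c):
        return float(weights @ norm.logcdf(sign * (design @ c)))

    ll = loglik(coef)
    for _ in range(max_iter):
        eta = design @ coef
        se = sign * eta
        # stable inverse Mills ratio: phi(eta)/Phi(se) per observation
        mills = np.exp(norm.logpdf(eta) - norm.logcdf(se))
        score = design.T @ (weights * sign * mills)
        # expected information weights: phi(eta)^2 / (Phi(eta) Phi(-eta))
        phi = np.exp(norm.logpdf(eta))
        denom = np.exp(norm.logcdf(eta) + norm.logcdf(-eta))
        info_w = weights * phi * phi / np.maximum(denom, 1e-300)
        fisher = design.T @ (design * info_w[:, None])
        try:
            step = np.linalg.solve(fisher + 1e-10 * np.eye(d), score)
        except np.linalg.LinAlgError:
            step = score / max(np.trace(fisher) / d, 1e-8)
        new_ll, scale = -np.inf, 1.0
        for _ in range(25):
            cand = coef + scale * step
            new_ll = loglik(cand)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(new_ll) or new_ll < ll - 1e-9:
            break
        coef = coef + scale * step
        if new_ll - ll < tol * (abs(ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    if np.abs(coef).max() > clamp:
        warnings.warn("probit coefficients clamped (possible separation)")
        coef = np.clip(coef, -clamp, clamp)
    return coef


def cm_step_binary(
    responsibilities: SubtypePosterior,
    traits: TraitMatrix,
    covariates: CovariateSet,
    alpha0: Optional[np.ndarray] = None,
    beta0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CM update for binary-trait probit coefficients.

    Realized as a responsibility-weighted probit regression on the
    expanded design [X, I_K (x) G] with rows replicated per subtype and
    responsibilities as case weights; alpha is shared across subtypes,
    beta_k subtype-specific.  Returns ``(alpha, beta)``.
    """
    x, g = covariates.homogeneous, covariates.heterogeneous
    yb = traits.binary
    z = responsibilities.Z
    n, b = yb.shape
    q, l = x.shape[1], g.shape[1]
    k = z.shape[1]
    if b == 0:
        return np.zeros((q, 0)), np.zeros((k, l, 0))
    for t in range(b):
        if yb[:, t].min() == yb[:, t].max():
            raise ValueError(f"binary trait {t} is constant; drop it before fitting")

    # expanded design: (n*k, q + k*l)
    big = np.zeros((n * k, q + k * l))
    for j in range(k):
        rows = slice(j * n, (j + 1) * n)
        if q:
            big[rows, :q] = x
        big[rows, q + j * l : q + (j + 1) * l] = g
    w = z.T.reshape(-1)  # subtype-major to match row blocks
    alpha = np.zeros((q, b))
    beta = np.zeros((k, l, b))
    for t in range(b):
        yy = np.tile(yb[:, t], k)
        c0 = None
        if alpha0 is not None and beta0 is not None:
            c0 = np.concatenate([alpha0[:, t], beta0[:, :, t].reshape(-1)])
        coef = _weighted_probit(big, yy, w, coef0=c0)
        alpha[:, t] = coef[:q]
        beta[:, :, t] = coef[q:].reshape(k, l)
    return alpha, beta


# ----------------------------------------------------------------------
# standardization helpers (fit-internal)


def _column_stats(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = m.mean(axis=0) if m.size else np.zeros(m.shape[1])
    sd = m.std(axis=0) if m.size else np.ones(m.shape[1])
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _destandardize(
    params: MFMRParams,
    mu_y: np.ndarray,
    sd_y: np.ndarray,
    mu_x: np.ndarray,
    sd_x: np.ndarray,
    mu_g: np.ndarray,
    sd_g: np.ndarray,
) -> MFMRParams:
    """Map coefficients fit on standardized data back to the original scale."""
    k = params.n_subtypes
    q, p = params.alpha_quant.shape
    b = params.alpha_binary.shape[1]

    c0 = sd_g[0]  # value of the original intercept column

    def back(alpha_s, beta_s, sd_out, mu_out):
        # standardized model: y_std = x_std @ a + [1, g_std] @ b
        alpha = alpha_s / sd_x[:, None] * sd_out[None, :] if q else alpha_s.copy()
        beta = np.empty_like(beta_s)
        if beta_s.shape[1] > 1:
            beta[:, 1:, :] = (
                beta_s[:, 1:, :] / sd_g[1:][None, :, None] * sd_out[None, None, :]
            )
        # fold centering shifts and the trait mean into the intercept row
        shift = np.zeros((beta_s.shape[0], beta_s.shape[2]))
        if q:
            shift = shift + ((mu_x / sd_x) @ alpha_s)[None, :]
        if beta_s.shape[1] > 1:
            shift = shift + np.einsum("l,klt->kt", mu_g[1:] / sd_g[1:], beta_s[:, 1:, :])
        beta[:, 0, :] = ((beta_s[:, 0, :] - shift) * sd_out[None, :] + mu_out[None, :]) / c0
        return alpha, beta

    alpha_q, beta_q = back(params.alpha_quant, params.beta_quant, sd_y, mu_y)
    alpha_b, beta_b = back(params.alpha_binary, params.beta_binary, np.ones(b), np.zeros(b))
    sigma2 = params.sigma2 * (sd_y**2)[None, :]
    return MFMRParams(
        alpha_quant=alpha_q,
        beta_quant=beta_q,
        sigma2=sigma2,
        alpha_binary=alpha_b,
        beta_binary=beta_b,
        p=params.p,
        loglik_trace=params.loglik_trace,
        converged=params.converged,
        degenerate=params.degenerate,
    )


def _canonicalize(params: MFMRParams, post: SubtypePosterior):
    """Deterministic subtype ordering: largest mixing proportion first."""
    order = np.argsort(-params.p, kind="stable")
    params = MFMRParams(
        alpha_quant=params.alpha_quant,
        beta_quant=params.beta_quant[order],
        sigma2=params.sigma2[order],
        alpha_binary=params.alpha_binary,
        beta_binary=params.beta_binary[order],
        p=params.p[order],
        loglik_trace=params.loglik_trace,
        converged=params.converged,
        degenerate=params.degenerate,
    )
    post = SubtypePosterior(Z=post.Z[:, order], p=params.p.copy())
    return params, post


# ----------------------------------------------------------------------
# fitting


def _init_responsibilities(
    n: int, k: int, rng: np.random.Generator, traits=None, covariates=None, gmm=False
) -> np.ndarray:
    if gmm and traits is not None and traits.n_quant >= 1 and k > 1:
        try:
            from sklearn.mixture import GaussianMixture

            y = traits.quant
            design = np.hstack([covariates.homogeneous, covariates.heterogeneous])
            resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
                reg_covar=1e-4,
            ).fit(resid)
            z = gm.predict_proba(resid)
            return 0.9 * z + 0.1 / k
        except Exception:  # pragma: no cover - init fallback only
            pass
    z = rng.dirichlet(np.full(k, 2.0), size=n)
    return z


def _single_fit(
    traits: TraitMatrix,
    covariates: CovariateSet,
    opts: FitOptions,
    z0: np.ndarray,
) -> tuple[MFMRParams, SubtypePosterior]:
    n, k = traits.n_samples, opts.K
    z = z0
    p = z.mean(axis=0)
    sigma2 = None
    alpha_b = beta_b = None
    post = SubtypePosterior(Z=z, p=p / p.sum())
    trace: list[float] = []
    params = None
    prev_ll = -np.inf
    converged = False
    for it in range(opts.max_iter):
        if sigma2 is None:
            alpha_q, beta_q, sigma2 = cm_step_quantitative(post, traits, covariates)
        else:
            alpha_q, beta_q, sigma2 = _cm_quant_weighted(post, traits, covariates, sigma2)
        if traits.n_binary:
            alpha_b, beta_b = cm_step_binary(post, traits, covariates, alpha_b, beta_b)
        else:
            alpha_b = np.zeros((covariates.n_hom, 0))
            beta_b = np.zeros((k, covariates.n_het, 0))
        p = np.maximum(post.Z.mean(axis=0), 1e-12)
        p = p / p.sum()
        params = MFMRParams(
            alpha_quant=alpha_q,
            beta_quant=beta_q,
            sigma2=sigma2,
            alpha_binary=alpha_b,
            beta_binary=beta_b,
            p=p,
        )
        ll = log_likelihood(params, traits, covariates)
        trace.append(ll)
        post = e_step(params, traits, covariates)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < opts.rel_tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    params.loglik_trace = trace
    params.converged = converged
    params.degenerate = bool(post.Z.sum(axis=0).min() < max(k, 5))
    return params, post


def fit_mfmr(
    traits: TraitMatrix,
    covariates: CovariateSet,
    opts: Optional[FitOptions] = None,
) -> tuple[MFMRParams, SubtypePosterior]:
    """Fit MFMR by ECM with multiple restarts; best final likelihood wins.

    Quantitative traits and non-intercept covariates are standardized
    internally; returned coefficients are on the original scale.  Subtypes
    are ordered largest-first to fix label switching.
    """
    opts = opts or FitOptions()
    n = traits.n_samples
    if n <= covariates.n_hom + opts.K * covariates.n_het:
        raise ValueError("need N > Q + K*L samples")
    design = np.hstack([covariates.homogeneous, covariates.heterogeneous])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient [X G] design")

    mu_y, sd_y = _column_stats(traits.quant)
    mu_x, sd_x = _column_stats(covariates.homogeneous)
    mu_g, sd_g = _column_stats(covariates.heterogeneous)
    mu_g, sd_g = mu_g.copy(), sd_g.copy()
    mu_g[0], sd_g[0] = 0.0, covariates.heterogeneous[0, 0]  # keep intercept as-is

    traits_s = TraitMatrix(
        quant=(traits.quant - mu_y) / sd_y, binary=traits.binary, names=traits.names
    )
    cov_s = CovariateSet(
        homogeneous=(covariates.homogeneous - mu_x) / sd_x if covariates.n_hom else covariates.homogeneous,
        heterogeneous=np.hstack(
            [
                np.ones((n, 1)),
                (covariates.heterogeneous[:, 1:] - mu_g[1:]) / sd_g[1:],
            ]
        ),
        hom_names=covariates.hom_names,
        het_names=covariates.het_names,
    )

    rng = np.random.default_rng(opts.seed)
    best: tuple[float, MFMRParams, SubtypePosterior] | None = None
    best_nondegen: tuple[float, MFMRParams, SubtypePosterior] | None = None
    n_inits = opts.n_restarts + (1 if opts.gmm_init and opts.K > 1 else 0)
    if opts.K == 1:
        n_inits = 1
    for r in range(n_inits):
        use_gmm = opts.gmm_init and opts.K > 1 and r == 0
        z0 = _init_responsibilities(n, opts.K, rng, traits_s, cov_s, gmm=use_gmm)
        params, post = _single_fit(traits_s, cov_s, opts, z0)
        ll = params.loglik_trace[-1]
        if best is None or ll > best[0]:
            best = (ll, params, post)
        if not params.degenerate and (best_nondegen is None or ll > best_nondegen[0]):
            best_nondegen = (ll, params, post)
    _, params, post = best_nondegen if best_nondegen is not None else best
    if best_nondegen is None:
        warnings.warn("all restarts produced a near-empty subtype; degeneracy flagged")
    # shift trace to the original-scale likelihood (constant Jacobian term)
    jac = -float(n * np.log(sd_y).sum()) if traits.n_quant else 0.0
    params.loglik_trace = [ll - jac for ll in params.loglik_trace]
    params = _destandardize(params, mu_y, sd_y, mu_x, sd_x, mu_g, sd_g)
    params, post = _canonicalize(params, post)
    return params, post


# ----------------------------------------------------------------------
# model selection & serialization helpers


def cv_select_K(
    traits: TraitMatrix,
    covariates: CovariateSet,
    k_grid: Optional[list[int]] = None,
    n_folds: int = 5,
    seed: int = 0,
    opts: Optional[FitOptions] = None,
) -> dict:
    """Cross-validated held-out log-likelihood per K, relative to K = 1.

    Returns ``{"k_grid": ..., "per_fold": (n_folds, len(k_grid)) array,
    "mean": ...}`` where values are held-out log-likelihood differences
    from the K = 1 baseline of the same fold.
    """
    k_grid = sorted(set(k_grid or [1, 2, 3]))
    if 1 not in k_grid:
        k_grid = [1] + k_grid
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    n = traits.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    raw = np.zeros((n_folds, len(k_grid)))
    base = opts or FitOptions()
    for f, test_idx in enumerate(folds):
        if len(test_idx) < 5:
            raise ValueError("fold too small")
        train_idx = np.setdiff1d(perm, test_idx)
        tr_tr = TraitMatrix(
            quant=traits.quant[train_idx], binary=traits.binary[train_idx], names=traits.names
        )
        cov_tr = CovariateSet(
            homogeneous=covariates.homogeneous[train_idx],
            heterogeneous=covariates.heterogeneous[train_idx],
            hom_names=covariates.hom_names,
            het_names=covariates.het_names,
        )
        tr_te = TraitMatrix(
            quant=traits.quant[test_idx], binary=traits.binary[test_idx], names=traits.names
        )
        cov_te = CovariateSet(
            homogeneous=covariates.homogeneous[test_idx],
            heterogeneous=covariates.heterogeneous[test_idx],
            hom_names=covariates.hom_names,
            het_names=covariates.het_names,
        )
        for ki, k in enumerate(k_grid):
            o = FitOptions(
                K=k,
                n_restarts=base.n_restarts,
                gmm_init=base.gmm_init,
                max_iter=base.max_iter,
                rel_tol=base.rel_tol,
                seed=base.seed + 1000 * f + k,
            )
            params, _ = fit_mfmr(tr_tr, cov_tr, o)
            raw[f, ki] = log_likelihood(params, tr_te, cov_te)
    rel = raw - raw[:, [k_grid.index(1)]]
    return {"k_grid": k_grid, "per_fold": rel, "mean": rel.mean(axis=0)}


def params_to_dict(params: MFMRParams) -> dict:
    return {
        "format_version": 1,
        "alpha_quant": params.alpha_quant.tolist(),
        "beta_quant": params.beta_quant.tolist(),
        "sigma2": params.sigma2.tolist(),
        "alpha_binary": params.alpha_binary.tolist(),
        "beta_binary": params.beta_binary.tolist(),
        "p": params.p.tolist(),
        "converged": bool(params.converged),
        "degenerate": bool(params.degenerate),
    }


def params_from_dict(d: dict) -> MFMRParams:
    if d.get("format_version") != 1:
        raise ValueError("unsupported model format version")
    return MFMRParams(
        alpha_quant=np.asarray(d["alpha_quant"], dtype=float),
        beta_quant=np.asarray(d["beta_quant"], dtype=float),
        sigma2=np.asarray(d["sigma2"], dtype=float),
        alpha_binary=np.asarray(d["alpha_binary"], dtype=float),
        beta_binary=np.asarray(d["beta_binary"], dtype=float),
        p=np.asarray(d["p"], dtype=float),
        converged=bool(d.get("converged", False)),
        degenerate=bool(d.get("degenerate", False)),
    )
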