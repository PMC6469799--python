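"""Polygenic subtype validation: heritability partitioning with a
homogeneous genetic kernel plus a subtype-specific (interaction) kernel.

The model is y = Xb + u_hom + u_het + e with

    cov(y) = s2_hom * K + s2_het * (K o ZZ') + s2_e * I

where K is the genetic relationship matrix, Z holds probabilistic subtype
memberships and `o` is the elementwise product.  Variance components are
estimated by average-information REML with nonnegativity projection and
EM fallback steps.  The constrained fit with s2_het = 0 is the standard
single-kernel (GREML) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "GRM",
    "VarianceComponents",
    "compute_grm",
    "het_kernel",
    "fit_iid_gxemm",
    "reml_loglik",
    "test_components",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_gcta",
    "read_grm_gcta",
]


@dataclass
class GRM:
    matrix: np.ndarray
    n_snps: int
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.matrix = m
        if self.sample_ids is None:
            self.sample_ids = [f"s{i+1}" for i in range(m.shape[0])]


def compute_grm(genotypes: np.ndarray, sample_ids: Optional[list[str]] = None) -> GRM:
    """GRM from column-standardized genotypes: A A' / M.

    Monomorphic SNPs are dropped with a warning; missing entries (NaN) are
    mean-imputed per SNP before standardization.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    if np.isnan(g).any():
        mu = np.nanmean(g, axis=0)
        ix = np.where(np.isnan(g))
        g[ix] = mu[ix[1]]
    sd = g.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic SNPs")
    g = g[:, keep]
    if g.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left")
    a = (g - g.mean(axis=0)) / g.std(axis=0)
    k = a @ a.T / a.shape[1]
    return GRM(matrix=k, n_snps=a.shape[1], sample_ids=sample_ids)


def het_kernel(grm: GRM | np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Subtype-specific kernel: K o (Z Z'), soft memberships propagated."""
    k = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    z = np.atleast_2d(np.asarray(Z, dtype=float))
    if z.shape[0] != k.shape[0]:
        raise ValueError("Z rows must match GRM dimension")
    if not np.allclose(z.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Z rows must lie on the simplex")
    return k * (z @ z.T)


@dataclass
class VarianceComponents:
    sigma2_hom: float
    sigma2_het: float
    sigma2_e: float
    h2_hom: float
    h2_het: float
    h2_iid: float
    h2_greml: float
    se_sigma2: np.ndarray  # (3,)
    se_h2: np.ndarray  # (h2_hom, h2_het, h2_iid)
    loglik_full: float
    loglik_greml: float
    loglik_null: float
    converged: bool
    family: str = "quantitative"
    ascertained: bool = False
    extra: dict = field(default_factory=dict)


def _residualize(y: np.ndarray, x: Optional[np.ndarray]):
    """Fixed-effect design with an intercept guaranteed."""
    if x is None or np.size(x) == 0:
        return np.ones((len(y), 1))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    has_const = any(
        np.allclose(x[:, j], x[0, j]) and x[0, j] != 0 for j in range(x.shape[1])
    )
    if not has_const:
        x = np.hstack([np.ones((len(y), 1)), x])
    return x


def reml_loglik(theta: np.ndarray, y: np.ndarray, x: np.ndarray, kernels: list[np.ndarray]) -> float:
    """Direct REML log-likelihood at variance components ``theta``
    (one per kernel, noise last).  Used both by the fitter and as an
    independent evaluation for grid-search cross-checks."""
    n = len(y)
    v = theta[-1] * np.eye(n)
    for t, k in zip(theta[:-1], kernels):
        v = v + t * k
    try:
        cf = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.log(np.diag(cf)).sum()
    vi_y = np.linalg.solve(cf.T, np.linalg.solve(cf, y))
    vi_x = np.linalg.solve(cf.T, np.linalg.solve(cf, x))
    xvx = x.T @ vi_x
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xvx, x.T @ vi_y)
    py = vi_y - vi_x @ beta
    return float(-0.5 * (logdet_v + logdet_xvx + y @ py))


def _reml_fit(
    y: np.ndarray,
    x: np.ndarray,
    kernels: list[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """AI-REML with step-halving and EM fallback; components projected to
    be nonnegative.  Returns (theta, cov(theta), loglik, converged)."""
    n = len(y)
    vary = float(np.var(y))
    nk = len(kernels)
    theta = np.full(nk + 1, vary / (nk + 1))
    all_k = kernels + [np.eye(n)]
    floor = 1e-8 * vary

    def build(theta):
        v = theta[-1] * np.eye(n)
        for t, k in zip(theta[:-1], kernels):
            v = v + t * k
        return v

    ll = reml_loglik(theta, y, x, kernels)
    ai = np.eye(nk + 1)
    converged = False
    for it in range(max_iter):
        v = build(theta)
        try:
            vi = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            theta = np.maximum(theta, floor) * 1.1
            continue
        vix = vi @ x
        xvx_i = np.linalg.inv(x.T @ vix)
        p = vi - vix @ xvx_i @ vix.T
        py = p @ y
        kpy = [k @ py for k in all_k]
        pkpy = [p @ kp for kp in kpy]
        score = np.array(
            [-0.5 * (np.sum(p * k) - py @ kp) for k, kp in zip(all_k, kpy)]
        )
        ai = np.array(
            [[0.5 * (kpy[i] @ pkpy[j]) for j in range(nk + 1)] for i in range(nk + 1)]
        )
        # active set: keep boundary components with inward-pointing scores only
        free = [i for i in range(nk + 1) if theta[i] > floor or score[i] > 0]
        if nk not in free:
            free.append(nk)  # noise variance always free
        step = np.zeros(nk + 1)
        sub = np.ix_(free, free)
        try:
            step[free] = np.linalg.solve(ai[sub] + 1e-10 * np.eye(len(free)), score[free])
        except np.linalg.LinAlgError:
            step[free] = score[free] * (vary / n)
        new_ll, scale, cand = -np.inf, 1.0, theta
        for _ in range(12):
            cand = np.maximum(theta + scale * step, 0.0)
            cand[-1] = max(cand[-1], floor)
            new_ll = reml_loglik(cand, y, x, kernels)
            if new_ll >= ll - 1e-10:
                break
            scale *= 0.5
        if new_ll < ll - 1e-8:  # AI direction failed; EM fallback
            em = theta.copy()
            for i in free:
                em[i] = theta[i] + (theta[i] ** 2 / n) * (py @ kpy[i] - np.sum(p * all_k[i]))
            em = np.maximum(em, 0.0)
            em[-1] = max(em[-1], floor)
            cand_ll = reml_loglik(em, y, x, kernels)
            if cand_ll < ll:
                converged = True  # no ascent direction left
                break
            cand, new_ll = em, cand_ll
        improved = new_ll - ll
        theta = cand
        ll = new_ll
        if improved < tol * (abs(ll) + 1.0):
            converged = True
            break
    # s.e. from the expected information at the converged estimate
    # (AI is a data-dependent approximation and under-covers in moderate n)
    try:
        v = build(theta)
        vi = np.linalg.inv(v)
        vix = vi @ x
        p = vi - vix @ np.linalg.inv(x.T @ vix) @ vix.T
        pk = [p @ k for k in all_k]
        info = np.array(
            [[0.5 * np.sum(pk[i] * pk[j].T) for j in range(nk + 1)] for i in range(nk + 1)]
        )
        cov = np.linalg.inv(info + 1e-12 * np.eye(nk + 1))
        if (np.diag(cov) < 0).any():
            warnings.warn("negative-definite information at optimum")
            cov = np.abs(cov)
    except np.linalg.LinAlgError:
        cov = np.full((nk + 1, nk + 1), np.nan)
    if not converged:
        warnings.warn("REML did not fully converge; boundary-constrained estimate returned")
    return theta, cov, ll, converged


def fit_iid_gxemm(
    y: np.ndarray,
    fixed_effects: Optional[np.ndarray],
    grm: GRM | np.ndarray,
    het: np.ndarray,
    family: str = "quantitative",
    ascertained: bool = False,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VarianceComponents:
    """Fit the two-kernel interaction mixed model plus its nested nulls.

    Heritability fractions are computed on the fixed-effect-residualized
    variance scale, weighting each component by the mean diagonal of its
    kernel (so kernels need not have unit diagonal).  Also fits the
    s2_het = 0 (GREML) and all-noise nulls for downstream tests.
    """
    y = np.asarray(y, dtype=float).ravel()
    k_hom = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    k_het = np.asarray(het, dtype=float)
    if k_hom.shape != (len(y), len(y)) or k_het.shape != k_hom.shape:
        raise ValueError("kernel dimensions must match len(y)")
    x = _residualize(y, fixed_effects)

    theta, cov, ll_full, converged = _reml_fit(y, x, [k_hom, k_het], max_iter, tol)
    theta_g, _, ll_greml, _ = _reml_fit(y, x, [k_hom], max_iter, tol)
    # all-noise null: REML variance of residuals
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    s2_null = float(resid @ resid / (len(y) - x.shape[1]))
    ll_null = reml_loglik(np.array([s2_null]), y, x, [])

    d = np.array([float(np.mean(np.diag(k_hom))), float(np.mean(np.diag(k_het))), 1.0])
    contrib = theta * d
    total = contrib.sum()
    h2_hom = contrib[0] / total
    h2_het = contrib[1] / total
    h2_iid = h2_hom + h2_het

    dg = np.array([float(np.mean(np.diag(k_hom))), 1.0])
    contrib_g = theta_g * dg
    h2_greml = contrib_g[0] / contrib_g.sum()

    # delta-method s.e. for the h2 fractions
    se_h2 = np.full(3, np.nan)
    if np.isfinite(cov).all():
        grads = []
        for which in ("hom", "het", "iid"):
            num = {
                "hom": contrib[0],
                "het": contrib[1],
                "iid": contrib[0] + contrib[1],
            }[which]
            dnum = {
                "hom": np.array([d[0], 0.0, 0.0]),
                "het": np.array([0.0, d[1], 0.0]),
                "iid": np.array([d[0], d[1], 0.0]),
            }[which]
            grads.append(dnum / total - num * d / total**2)
        se_h2 = np.array([float(np.sqrt(max(g @ cov @ g, 0.0))) for g in grads])

    return VarianceComponents(
        sigma2_hom=float(theta[0]),
        sigma2_het=float(theta[1]),
        sigma2_e=float(theta[2]),
        h2_hom=float(h2_hom),
        h2_het=float(h2_het),
        h2_iid=float(h2_iid),
        h2_greml=float(h2_greml),
        se_sigma2=np.sqrt(np.maximum(np.diag(cov), 0.0)) if np.isfinite(cov).all() else np.full(3, np.nan),
        se_h2=se_h2,
        loglik_full=float(ll_full),
        loglik_greml=float(ll_greml),
        loglik_null=float(ll_null),
        converged=converged,
        family=family,
        ascertained=ascertained,
        extra={"theta_greml": theta_g.tolist()},
    )


def test_components(fit: VarianceComponents) -> dict:
    """Wald test for total genetic variance > 0 and boundary-aware LRT for
    the subtype-specific component.

    The LRT null is the 50:50 mixture of a point mass at zero and
    chi-square(1) (single variance component on the boundary).  For
    ascertained binary traits no p-values are emitted (None), matching the
    conservative reporting convention.
    """
    if fit.family == "binary" and fit.ascertained:
        return {"wald_p": None, "lrt_p": None, "lrt_stat": None}
    if not np.isfinite(fit.loglik_greml):
        raise ValueError("constrained (GREML) fit unavailable")
    se = fit.se_h2[2]
    if np.isfinite(se) and se > 0:
        zstat = fit.h2_iid / se
        wald_p = float(stats.norm.sf(zstat))
    else:
        wald_p = np.nan
    lrt = max(2.0 * (fit.loglik_full - fit.loglik_greml), 0.0)
    lrt_p = 1.0 if lrt == 0 else float(0.5 * stats.chi2.sf(lrt, df=1))
    return {"wald_p": wald_p, "lrt_p": lrt_p, "lrt_stat": float(lrt)}


# ----------------------------------------------------------------------
# GRM I/O


def write_grm_tsv(grm: GRM, path) -> None:
    import pandas as pd

    df = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t")


def read_grm_tsv(path) -> GRM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM(matrix=df.to_numpy(), n_snps=0, sample_ids=list(df.index.astype(str)))


def write_grm_gcta(grm: GRM, prefix: str) -> None:
    """GCTA binary GRM triple: .grm.bin, .grm.N.bin, .grm.id."""
    n = grm.matrix.shape[0]
    iu = np.tril_indices(n)
    vals = grm.matrix[iu].astype(np.float32)
    vals.tofile(f"{prefix}.grm.bin")
    np.full(vals.shape, grm.n_snps, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix: str) -> GRM:
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    nsnp = int(np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)[0])
    mat = np.zeros((n, n))
    iu = np.tril_indices(n)
    mat[iu] = vals
    mat = mat + np.tril(mat, -1).T
    return GRM(matrix=mat, n_snps=nsnp, sample_ids=ids)
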