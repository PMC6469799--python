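"""Covariate-by-subtype interaction tests, genome scans, and genomic control.

The working model for a focal covariate g, background covariates and an
N x K subtype-probability matrix Z is

    trait ~ background + z + g + g*z

fit by linear regression for quantitative traits and logistic regression
for binary traits, with the soft membership probabilities used directly as
regressors.  Three tests are exposed: homogeneity (1 df, on the main
effect with interactions fixed at zero), heterogeneity (K-1 df, on the
interaction block), and global (K df, jointly on main effect plus
interactions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

MODES = ("homogeneity", "heterogeneity", "global")


@dataclass
class TestSpec:
    """One trait / one focal covariate test request."""

    __test__ = False  # not a pytest class

    y: np.ndarray
    family: str  # "quantitative" | "binary"
    focal: np.ndarray
    subtype_probs: np.ndarray  # (N, K)
    background: Optional[np.ndarray] = None
    mode: str = "heterogeneity"

    def __post_init__(self) -> None:
        if self.family not in ("quantitative", "binary"):
            raise ValueError("family must be 'quantitative' or 'binary'")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.focal = np.asarray(self.focal, dtype=float).ravel()
        z = np.atleast_2d(np.asarray(self.subtype_probs, dtype=float))
        if z.shape[0] != len(self.y):
            raise ValueError("subtype_probs must have one row per sample")
        if not np.allclose(z.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("subtype_probs rows must sum to 1")
        self.subtype_probs = z
        if self.background is not None:
            self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
            if self.background.shape[0] != len(self.y):
                raise ValueError("background must have one row per sample")


@dataclass
class TestResult:
    __test__ = False  # not a pytest class

    statistic: float
    df: int
    p_value: float
    mode: str
    family: str
    effects: np.ndarray  # per-subtype effect of the focal covariate (K,)
    ses: np.ndarray
    n: int
    extra: dict = field(default_factory=dict)


def _design(spec: TestSpec, with_focal: bool, with_inter: bool):
    """Build the regression design, dropping the largest subtype's column.

    Returns (design matrix, index of focal column or None, slice of
    interaction columns or None, reference subtype index, kept subtype
    indices).
    """
    z = spec.subtype_probs
    n, k = z.shape
    ref = int(np.argmax(z.sum(axis=0)))
    keep = [j for j in range(k) if j != ref]
    if k > 1 and np.allclose(z.std(axis=0), 0):
        raise ValueError("no subtype variation: responsibilities are constant")
    cols = [np.ones((n, 1))]
    if spec.background is not None and spec.background.size:
        cols.append(spec.background)
    if keep:
        cols.append(z[:, keep])
    focal_ix = inter_sl = None
    if with_focal:
        focal_ix = sum(c.shape[1] for c in cols)
        cols.append(spec.focal[:, None])
    if with_inter and keep:
        start = sum(c.shape[1] for c in cols)
        cols.append(spec.focal[:, None] * z[:, keep])
        inter_sl = slice(start, start + len(keep))
    x = np.hstack(cols)
    return x, focal_ix, inter_sl, ref, keep


def _ols_fit(x: np.ndarray, y: np.ndarray):
    """OLS coefficients, covariance and log-likelihood (Gaussian MLE)."""
    n, d = x.shape
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as e:
        raise ValueError("collinear design in interaction test") from e
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    rss = float(resid @ resid)
    dof = n - d
    s2 = rss / max(dof, 1)
    cov = xtx_inv * s2
    sigma2_mle = rss / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0)
    return coef, cov, ll, dof


def _logit_fit(x: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, x)
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
            ok = res.mle_retvals.get("converged", True)
        except np.linalg.LinAlgError:
            res, ok = None, False
        if not ok:
            res = model.fit(disp=0, maxiter=1000, method="bfgs")
        try:
            cov = np.asarray(res.cov_params())
        except np.linalg.LinAlgError:
            cov = np.full((x.shape[1], x.shape[1]), np.nan)
    return np.asarray(res.params), cov, float(res.llf)


def interaction_test(spec: TestSpec) -> TestResult:
    """Run the homogeneity / heterogeneity / global test for one focal covariate.

    Linear traits use Wald chi-square tests; binary traits use likelihood
    ratio tests between nested logistic fits.  Per-subtype effects are
    reported as main effect + interaction with delta-method standard
    errors (from the full interaction model, or the main-effect model for
    the homogeneity test).
    """
    k = spec.subtype_probs.shape[1]
    if k < 2 and spec.mode != "homogeneity":
        raise ValueError("no subtype variation: need K >= 2 for interaction tests")
    if spec.mode == "homogeneity":
        x, fix, _, ref, keep = _design(spec, with_focal=True, with_inter=False)
        df = 1
        test_cols = [fix]
    elif spec.mode == "heterogeneity":
        x, fix, isl, ref, keep = _design(spec, with_focal=True, with_inter=True)
        df = k - 1
        test_cols = list(range(isl.start, isl.stop))
    else:  # global
        x, fix, isl, ref, keep = _design(spec, with_focal=True, with_inter=True)
        df = k
        test_cols = [fix] + list(range(isl.start, isl.stop))

    if spec.family == "quantitative":
        coef, cov, _, _ = _ols_fit(x, spec.y)
        c = coef[test_cols]
        v = cov[np.ix_(test_cols, test_cols)]
        try:
            stat = float(c @ np.linalg.solve(v, c))
        except np.linalg.LinAlgError as e:
            raise ValueError("singular covariance for tested block") from e
        p = float(stats.chi2.sf(stat, df))
    else:
        coef, cov, ll_full = _logit_fit(x, spec.y)
        if spec.mode == "homogeneity":
            x0, _, _, _, _ = _design(spec, with_focal=False, with_inter=False)
        elif spec.mode == "heterogeneity":
            x0, _, _, _, _ = _design(spec, with_focal=True, with_inter=False)
        else:
            x0, _, _, _, _ = _design(spec, with_focal=False, with_inter=False)
        _, _, ll_null = _logit_fit(x0, spec.y)
        stat = max(2.0 * (ll_full - ll_null), 0.0)
        p = float(stats.chi2.sf(stat, df))

    effects, ses = _per_subtype_effects(spec, coef, cov, k, ref, keep)
    return TestResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        mode=spec.mode,
        family=spec.family,
        effects=effects,
        ses=ses,
        n=len(spec.y),
        extra={"reference_subtype": ref},
    )


def _per_subtype_effects(spec, coef, cov, k, ref, keep):
    """delta + beta_k decomposition with delta-method standard errors."""
    # locate focal / interaction columns by rebuilding the design layout
    has_inter = spec.mode in ("heterogeneity", "global") and k > 1
    n_bg = spec.background.shape[1] if spec.background is not None and spec.background.size else 0
    fix = 1 + n_bg + (k - 1)
    effects = np.full(k, np.nan)
    ses = np.full(k, np.nan)
    delta = coef[fix]
    effects[ref] = delta
    ses[ref] = np.sqrt(cov[fix, fix])
    if has_inter:
        for pos, j in enumerate(keep):
            ix = fix + 1 + pos
            effects[j] = delta + coef[ix]
            ses[j] = np.sqrt(cov[fix, fix] + cov[ix, ix] + 2 * cov[fix, ix])
    else:
        effects[:] = delta
        ses[:] = np.sqrt(cov[fix, fix])
    return effects, ses


def droptest_large_covariate(
    y: np.ndarray,
    family: str,
    focal: np.ndarray,
    subtype_probs: np.ndarray,
    background: Optional[np.ndarray] = None,
    extra_conditioning: Optional[np.ndarray] = None,
    mode: str = "heterogeneity",
) -> TestResult:
    """Heterogeneity test for a large-effect covariate that was included
    homogeneously during subtype fitting, with optional extra conditioning
    covariates (e.g. disease status)."""
    focal = np.asarray(focal, dtype=float).ravel()
    if extra_conditioning is not None:
        extra = np.atleast_2d(np.asarray(extra_conditioning, dtype=float))
        if extra.shape[0] != len(focal):
            extra = extra.T
        for j in range(extra.shape[1]):
            if np.allclose(extra[:, j], focal):
                raise ValueError("extra_conditioning duplicates the focal covariate")
        background = (
            extra if background is None or not np.size(background)
            else np.hstack([np.atleast_2d(background), extra])
        )
    spec = TestSpec(
        y=y, family=family, focal=focal, subtype_probs=subtype_probs,
        background=background, mode=mode,
    )
    return interaction_test(spec)


def genome_scan(
    genotypes: np.ndarray,
    y: np.ndarray,
    family: str,
    subtype_probs: np.ndarray,
    background: Optional[np.ndarray] = None,
    mode: str = "gxe_global",
    snp_ids: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-SNP scan with a frozen subtype posterior.

    ``mode``: ``gwas`` (1-df homogeneous test), ``gxe_global`` (K df) or
    ``het`` (K-1 df).  Monomorphic SNPs yield NA rows with a reason code.
    """
    mode_map = {"gwas": "homogeneity", "gxe_global": "global", "het": "heterogeneity"}
    if mode not in mode_map:
        raise ValueError("mode must be 'gwas', 'gxe_global' or 'het'")
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if g.shape[0] != len(y):
        raise ValueError("genotypes must be samples x SNPs")
    m = g.shape[1]
    k = np.atleast_2d(subtype_probs).shape[1]
    ids = snp_ids or [f"snp{j+1}" for j in range(m)]
    rows = []
    for j in range(m):
        snp = g[:, j]
        if np.ptp(snp) == 0:
            rows.append(
                dict(snp_id=ids[j], mode=mode, stat=np.nan, df=np.nan, p=np.nan,
                     reason="monomorphic",
                     **{f"beta{s+1}": np.nan for s in range(k)},
                     **{f"se{s+1}": np.nan for s in range(k)})
            )
            continue
        res = interaction_test(
            TestSpec(y=y, family=family, focal=snp, subtype_probs=subtype_probs,
                     background=background, mode=mode_map[mode])
        )
        rows.append(
            dict(snp_id=ids[j], mode=mode, stat=res.statistic, df=res.df,
                 p=res.p_value, reason="",
                 **{f"beta{s+1}": res.effects[s] for s in range(k)},
                 **{f"se{s+1}": res.ses[s] for s in range(k)})
        )
    return pd.DataFrame(rows)


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor from 1-df p-values.

    Median of the implied chi-square(1) statistics over the chi-square(1)
    median (0.4549...).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def subtype_specific_effects(result: TestResult, scale: str = "linear") -> pd.DataFrame:
    """Per-subtype effect table with +/- 2 s.e. intervals.

    ``scale='odds_ratio'`` exponentiates logistic-fit effects and interval
    endpoints.
    """
    if result.effects is None or result.ses is None or np.isnan(result.ses).all():
        raise ValueError("result lacks effect covariance information")
    if scale not in ("linear", "odds_ratio"):
        raise ValueError("scale must be 'linear' or 'odds_ratio'")
    est, se = result.effects, result.ses
    lo, hi = est - 2 * se, est + 2 * se
    if scale == "odds_ratio":
        if result.family != "binary":
            raise ValueError("odds ratios only apply to logistic fits")
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
    return pd.DataFrame(
        {
            "subtype": np.arange(1, len(est) + 1),
            "estimate": est,
            "lower_2se": lo,
            "upper_2se": hi,
            "se": se,
        }
    )
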