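"""Pre-clustering missing-data handling.

Two single-imputation routes: EM on a joint multivariate Gaussian over
columns (missing entries replaced by conditional expectations), and an
iterative soft-thresholded / truncated SVD completion for wide matrices.
Binary columns are thresholded to {0,1} after imputation; observed
entries are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class ImputationResult:
    completed: np.ndarray
    mask_missing: np.ndarray  # True where the entry was imputed
    method: str
    details: dict = field(default_factory=dict)


def _threshold_binary(x: np.ndarray, mask: np.ndarray, binary_cols: Optional[Sequence[int]]):
    if binary_cols:
        for j in binary_cols:
            col = x[:, j]
            imputed = mask[:, j]
            col[imputed] = (col[imputed] >= 0.5).astype(float)
    return x


def mvn_impute(
    matrix: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    binary_cols: Optional[Sequence[int]] = None,
    ridge: float = 1e-8,
) -> ImputationResult:
    """EM imputation under a single multivariate Gaussian over columns.

    Rows are i.i.d. samples.  Each EM iteration replaces missing entries
    with their conditional expectations given the observed entries of the
    same row, accumulating conditional covariances into the scatter
    update.  Convergence is monitored on the completed-data log-likelihood.
    """
    x = np.asarray(matrix, dtype=float).copy()
    n, p = x.shape
    mask = np.isnan(x)
    if mask.all(axis=0).any():
        raise ValueError("column(s) fully missing")
    if (np.sum(~mask, axis=0) < 2).any():
        raise ValueError("each column needs at least 2 observed values")
    if not mask.any():
        return ImputationResult(x, mask, "mvn", {"n_iter": 0})

    # init: column-mean fill
    col_means = np.nanmean(np.where(mask, np.nan, x), axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(mask[i].tobytes(), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = x.mean(axis=0)
        xc = x - mu
        sigma = xc.T @ xc / n
        # conditional covariance corrections from the previous E-step are
        # folded in below; start from the completed-data scatter
        corr = np.zeros((p, p))
        for key, rows in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            if not miss.any():
                continue
            obs = ~miss
            s_oo = sigma[np.ix_(obs, obs)] + ridge * np.eye(obs.sum())
            s_mo = sigma[np.ix_(miss, obs)]
            try:
                w = np.linalg.solve(s_oo, s_mo.T).T  # (n_miss, n_obs)
            except np.linalg.LinAlgError:
                warnings.warn("non-PD observed covariance; extra ridge applied")
                w = np.linalg.solve(s_oo + 1e-4 * np.trace(s_oo) / len(s_oo) * np.eye(len(s_oo)), s_mo.T).T
            cond_mean = mu[miss] + (x[np.ix_(rows, np.flatnonzero(obs))] - mu[obs]) @ w.T
            x[np.ix_(rows, np.flatnonzero(miss))] = cond_mean
            cond_cov = sigma[np.ix_(miss, miss)] - w @ s_mo.T
            corr[np.ix_(miss, miss)] += len(rows) * cond_cov
        mu = x.mean(axis=0)
        xc = x - mu
        sigma = (xc.T @ xc + corr) / n
        sign, logdet = np.linalg.slogdet(sigma + ridge * np.eye(p))
        if sign <= 0:
            logdet = np.inf
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1):
            break
        prev_ll = ll

    completed = np.asarray(matrix, dtype=float).copy()
    completed[mask] = x[mask]
    completed = _threshold_binary(completed, mask, binary_cols)
    return ImputationResult(
        completed, mask, "mvn", {"n_iter": n_iter, "mean": mu, "cov": sigma}
    )


def lowrank_impute(
    matrix: np.ndarray,
    rank: Optional[int] = None,
    penalty: Optional[float] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    binary_cols: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> ImputationResult:
    """Iterative SVD completion (soft-threshold when ``penalty`` is given,
    hard truncation to ``rank`` otherwise).  Observed entries are restored
    exactly in the output."""
    x0 = np.asarray(matrix, dtype=float)
    n, p = x0.shape
    mask = np.isnan(x0)
    if rank is None and penalty is None:
        raise ValueError("supply rank or penalty")
    if rank is not None and rank >= min(n, p):
        raise ValueError("rank must be below min(n_rows, n_cols)")
    if not mask.any():
        return ImputationResult(x0.copy(), mask, "lowrank", {"n_iter": 0})
    col_means = np.nanmean(x0, axis=0)
    x = x0.copy()
    x[mask] = np.take(col_means, np.where(mask)[1])
    prev = x.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        if penalty is not None:
            s = np.maximum(s - penalty, 0.0)
        if rank is not None:
            s[rank:] = 0.0
        fit = (u * s) @ vt
        x = np.where(mask, fit, x0)
        delta = np.linalg.norm(x - prev) / (np.linalg.norm(prev) + 1e-12)
        prev = x.copy()
        if delta < tol:
            break
    completed = np.where(mask, x, x0)
    completed = _threshold_binary(completed, mask, binary_cols)
    return ImputationResult(completed, mask, "lowrank", {"n_iter": n_iter, "rank": rank, "penalty": penalty})
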