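"""Comparator subtype estimators and clustering-evaluation metrics.

GMM (covariate-unaware mixture on the quantitative traits), CCA and
principal-component subtype scores, subsampled adjusted Rand index, and a
cross-validated co-clustering stability measure for the mixture model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import mfmr as _mfmr


@dataclass
class SubtypeEstimate:
    source: str  # gmm | cca | y_pc | g_pc | thresholded
    z: np.ndarray  # (N,) continuous score or (N, K) responsibilities
    loadings: Optional[np.ndarray] = None
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def responsibilities(self) -> np.ndarray:
        """(N, K) matrix; continuous scores are not convertible."""
        if self.z.ndim != 2:
            raise ValueError("estimate holds a continuous score, not responsibilities")
        return self.z

    @property
    def hard_labels(self) -> np.ndarray:
        if self.z.ndim == 2:
            return self.z.argmax(axis=1) + 1
        raise ValueError("continuous score has no hard labels")


def _scale(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    mu, sd = m.mean(axis=0), m.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (m - mu) / sd


def _canonical_sign(z: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    r = np.corrcoef(z, anchor)[0, 1]
    return -z if np.isfinite(r) and r < 0 else z


def fit_gmm(quant_traits: np.ndarray, K: int, seed: int = 0, n_restarts: int = 5) -> SubtypeEstimate:
    """EM-fit Gaussian mixture (full covariances) on quantitative traits only."""
    from sklearn.mixture import GaussianMixture

    y = np.atleast_2d(np.asarray(quant_traits, dtype=float))
    if K == 1:
        return SubtypeEstimate(source="gmm", z=np.ones((y.shape[0], 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            n_init=n_restarts,
            random_state=seed,
            reg_covar=1e-6,
            max_iter=500,
        ).fit(y)
    if not gm.converged_:
        warnings.warn("GMM did not converge")
    z = gm.predict_proba(y)
    order = np.argsort(-z.mean(axis=0), kind="stable")
    return SubtypeEstimate(
        source="gmm", z=z[:, order], converged=bool(gm.converged_),
        extra={"means": gm.means_[order]},
    )


def cca_subtype(all_traits: np.ndarray, G: np.ndarray) -> SubtypeEstimate:
    """Top canonical pair of (scaled traits, scaled covariates); the
    phenotypic canonical variate is returned as a unit-variance score."""
    y = _scale(np.atleast_2d(all_traits))
    g = _scale(np.atleast_2d(G))
    if g.shape[1] == 0:
        raise ValueError("G must be non-empty")
    n = y.shape[0]
    # canonical directions via whitened cross-covariance SVD
    uy, sy, vty = np.linalg.svd(y, full_matrices=False)
    ug, sg, vtg = np.linalg.svd(g, full_matrices=False)
    ry = (sy > 1e-10 * sy[0]).sum()
    rg = (sg > 1e-10 * sg[0]).sum()
    if ry == 0 or rg == 0:
        raise ValueError("rank-deficient inputs to CCA")
    c = uy[:, :ry].T @ ug[:, :rg]
    uu, ss, vv = np.linalg.svd(c)
    z = uy[:, :ry] @ uu[:, 0]
    z = z / z.std()
    z = _canonical_sign(z, y[:, 0])
    load = vty[:ry].T @ (uu[:, 0] / np.where(sy[:ry] > 0, sy[:ry], 1.0))
    return SubtypeEstimate(source="cca", z=z, loadings=load, extra={"corr": float(ss[0])})


def pc_subtype(matrix: np.ndarray, source: str = "phenotype", threshold: bool = False) -> SubtypeEstimate:
    """Top principal-component score of a centered/scaled matrix; optional
    median-threshold binarization."""
    if source not in ("phenotype", "genotype"):
        raise ValueError("source must be 'phenotype' or 'genotype'")
    m = _scale(np.atleast_2d(matrix))
    if np.allclose(m, 0):
        raise ValueError("constant matrix has no principal component")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    z = u[:, 0] * s[0]
    z = z / z.std()
    z = _canonical_sign(z, m[:, 0])
    tag = "y_pc" if source == "phenotype" else "g_pc"
    if threshold:
        zb = (z > np.median(z)).astype(float)
        resp = np.column_stack([1 - zb, zb])
        return SubtypeEstimate(source="thresholded", z=resp, loadings=vt[0], extra={"from": tag})
    return SubtypeEstimate(source=tag, z=z, loadings=vt[0])


def adjusted_rand_subsampled(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    n_subsample: int = 300,
    seed: int = 0,
) -> float:
    """Adjusted Rand index over pairs within a random subsample
    (exact when N <= n_subsample)."""
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) > n_subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(a), size=n_subsample, replace=False)
        a, b = a[idx], b[idx]
    return float(adjusted_rand_score(a, b))


def coclustering_stability(
    traits: _mfmr.TraitMatrix,
    covariates: _mfmr.CovariateSet,
    K: int,
    n_folds: int = 5,
    seed: int = 0,
    opts: Optional[_mfmr.FitOptions] = None,
    max_pairs: int = 200_000,
) -> float:
    """Fraction of originally co-clustered pairs that stay co-clustered
    when each fold is held out, refit on the remainder, and re-assigned.

    Co-clustering of a pair is label-permutation invariant, so label
    switching between refits does not matter.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if K == 1:
        return 1.0
    base = opts or _mfmr.FitOptions(K=K, seed=seed)
    params, post = _mfmr.fit_mfmr(traits, covariates, base)
    ref = post.hard_labels
    if len(np.unique(ref)) < 2:
        raise ValueError("degenerate single-cluster reference fit")
    n = traits.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    kept = total = 0
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        tr = _mfmr.TraitMatrix(
            quant=traits.quant[train_idx], binary=traits.binary[train_idx], names=traits.names
        )
        cv = _mfmr.CovariateSet(
            homogeneous=covariates.homogeneous[train_idx],
            heterogeneous=covariates.heterogeneous[train_idx],
            hom_names=covariates.hom_names,
            het_names=covariates.het_names,
        )
        o = _mfmr.FitOptions(
            K=K, n_restarts=base.n_restarts, gmm_init=base.gmm_init,
            max_iter=base.max_iter, rel_tol=base.rel_tol, seed=base.seed + 17 * (f + 1),
        )
        pf, _ = _mfmr.fit_mfmr(tr, cv, o)
        te = _mfmr.TraitMatrix(
            quant=traits.quant[test_idx], binary=traits.binary[test_idx], names=traits.names
        )
        ce = _mfmr.CovariateSet(
            homogeneous=covariates.homogeneous[test_idx],
            heterogeneous=covariates.heterogeneous[test_idx],
            hom_names=covariates.hom_names,
            het_names=covariates.het_names,
        )
        new = _mfmr.predict_subtypes(pf, te, ce).hard_labels
        old = ref[test_idx]
        m = len(test_idx)
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m) if old[i] == old[j]]
        if len(pairs) > max_pairs // n_folds:
            sel = rng.choice(len(pairs), size=max_pairs // n_folds, replace=False)
            pairs = [pairs[s] for s in sel]
        for i, j in pairs:
            total += 1
            kept += int(new[i] == new[j])
    if total == 0:
        raise ValueError("no co-clustered pairs in the reference clustering")
    return kept / total
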