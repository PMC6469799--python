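"""Replicate-level evaluation harness for the simulation study.

Convenience drivers that draw replicate cohorts, fit the subtype
estimators, run the SNP-by-subtype heterogeneity tests, and aggregate
false/true-positive rates.  Used by the benchmark script and the
acceptance test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .assoc import TestSpec, interaction_test
from .baselines import cca_subtype, fit_gmm, pc_subtype
from .mfmr import FitOptions, fit_mfmr
from .simulate import StructureSpec, draw_genotypes, make_scenario, weir_cockerham_fst

FAST_FIT = dict(n_restarts=2, max_iter=150, rel_tol=1e-6)


def _fit_opts(seed: int) -> FitOptions:
    return FitOptions(K=2, seed=seed, **FAST_FIT)


def _score_to_probs(z: np.ndarray) -> np.ndarray:
    """Map a continuous subtype score onto two pseudo-membership columns.

    The heterogeneity test design is affine-invariant in z, so any
    monotone affine rescaling gives the identical test.
    """
    u = (z - z.min()) / (z.max() - z.min())
    return np.column_stack([1 - u, u])


def _het_pvalues(ds, Z, snp_indices, use_background=True, quant_only=True, mode="heterogeneity"):
    out = []
    for j in snp_indices:
        g = ds.genotypes[:, j].astype(float)
        bg = np.delete(ds.covariates.homogeneous, j, axis=1) if use_background else None
        n_traits = ds.traits.n_quant if quant_only else ds.traits.n_quant + ds.traits.n_binary
        for t in range(n_traits):
            if t < ds.traits.n_quant:
                y, fam = ds.traits.quant[:, t], "quantitative"
            else:
                y, fam = ds.traits.binary[:, t - ds.traits.n_quant].astype(float), "binary"
            res = interaction_test(
                TestSpec(y=y, family=fam, focal=g, subtype_probs=Z,
                         background=bg, mode=mode)
            )
            out.append(res.p_value)
    return np.asarray(out)


def _oracle_probs(ds) -> np.ndarray:
    k = int(np.max(ds.z_true))
    return np.eye(k)[np.asarray(ds.z_true, dtype=int) - 1].astype(float)


def estimator_probs(ds, method: str, seed: int) -> np.ndarray:
    """Subtype-probability matrix for one estimator on one draw."""
    if method == "oracle":
        return _oracle_probs(ds)
    if method == "mfmr":
        _, post = fit_mfmr(ds.traits, ds.covariates, _fit_opts(seed))
        return post.Z
    if method == "gmm":
        return fit_gmm(ds.traits.quant, 2, seed=seed, n_restarts=2).z
    if method == "cca":
        allt = np.hstack([ds.traits.binary, ds.traits.quant])
        return _score_to_probs(cca_subtype(allt, ds.covariates.homogeneous).z)
    if method == "ypc":
        return _score_to_probs(pc_subtype(ds.traits.quant).z)
    raise ValueError(f"unknown estimator {method!r}")


# GMM mirrors covariate-unaware two-step testing: no background covariates
_USES_BACKGROUND = {"oracle": True, "mfmr": True, "gmm": False, "cca": True, "ypc": True}


def k1_null_fpr(
    n_reps: int,
    n_samples: int,
    seed: int,
    nominal: float = 0.01,
    methods: Sequence[str] = ("mfmr", "gmm"),
) -> dict:
    """Het-test FPR per replicate on no-subtype draws with homogeneous SNPs."""
    fpr = {m: [] for m in methods}
    for rep in range(n_reps):
        ds = make_scenario("baseline_k1", {"n_samples": n_samples}, seed=seed + rep)
        snps = range(ds.genotypes.shape[1])
        for m in methods:
            Z = estimator_probs(ds, m, seed=seed + rep)
            p = _het_pvalues(ds, Z, snps, use_background=_USES_BACKGROUND[m])
            fpr[m].append(float(np.mean(p < nominal)))
    return {m: np.asarray(v) for m, v in fpr.items()}


def power_ordering(
    n_reps: int,
    n_samples: int,
    seed: int,
    nominal: float = 0.01,
    methods: Sequence[str] = ("oracle", "mfmr", "gmm", "cca", "ypc"),
) -> dict:
    """Het-test TPR per replicate on heterogeneous SNPs (K=2 baseline)."""
    tpr = {m: [] for m in methods}
    for rep in range(n_reps):
        ds = make_scenario("baseline_k2", {"n_samples": n_samples}, seed=seed + rep)
        het = [j for j, r in enumerate(ds.snp_roles) if r == "het"]
        for m in methods:
            Z = estimator_probs(ds, m, seed=seed + rep)
            p = _het_pvalues(ds, Z, het, use_background=_USES_BACKGROUND[m])
            tpr[m].append(float(np.mean(p < nominal)))
    return {m: np.asarray(v) for m, v in tpr.items()}


def rho_ge_fpr(
    rhos: Iterable[float],
    n_reps: int,
    n_samples: int,
    seed: int,
    nominal: float = 0.01,
    methods: Sequence[str] = ("mfmr", "oracle"),
) -> dict:
    """Het-test FPR on null+homogeneous SNPs across the G-E correlation grid."""
    out = {m: {} for m in methods}
    for rho in rhos:
        per = {m: [] for m in methods}
        for rep in range(n_reps):
            ds = make_scenario(
                "baseline_k2", {"n_samples": n_samples, "rho_ge": float(rho)},
                seed=seed + rep,
            )
            nulls = [j for j, r in enumerate(ds.snp_roles) if r in ("null", "hom")]
            for m in methods:
                Z = estimator_probs(ds, m, seed=seed + rep)
                p = _het_pvalues(ds, Z, nulls, use_background=_USES_BACKGROUND[m])
                per[m].append(float(np.mean(p < nominal)))
        for m in methods:
            out[m][float(rho)] = np.asarray(per[m])
    return out


def fst_recovery(
    n_samples: int = 2000,
    n_snps: int = 10_000,
    fst: float = 0.1,
    seed: int = 0,
) -> dict:
    """Balding-Nichols draw followed by Weir-Cockerham estimation."""
    geno, _, pops = draw_genotypes(
        n_samples, n_snps, structure=StructureSpec(fst=fst, n_structure_snps=n_snps),
        rng=seed,
    )
    overall, per_snp = weir_cockerham_fst(geno, pops)
    mean_of_ratios, _ = weir_cockerham_fst(geno, pops, average="mean")
    return {
        "fst": overall,
        "fst_mean_of_ratios": mean_of_ratios,
        "per_snp": per_snp,
        "n_snps": n_snps,
        "n_samples": n_samples,
    }


def cca_inflation(
    n_reps: int,
    n_samples: int,
    seed: int,
    nominal: float = 0.01,
) -> dict:
    """FPR of the het test on a trait with no heterogeneity, for CCA vs MFMR.

    The tested trait keeps its subtype main effect but carries no
    subtype-specific SNP effects; the heterogeneous SNPs are tested, so
    every rejection on this trait is a false positive.
    """
    n_quant = 27
    het_mask = tuple([True] * (n_quant - 1) + [False])
    main_mask = tuple([True] * n_quant)
    p_cca, p_mfmr = [], []
    for rep in range(n_reps):
        ds = make_scenario(
            "baseline_k2",
            {
                "n_samples": n_samples,
                "h2_hom": 0.004,
                "h2_het": 0.04,
                "trait_het_mask": het_mask,
                "trait_main_mask": main_mask,
            },
            seed=seed + rep,
        )
        z_mfmr = estimator_probs(ds, "mfmr", seed=seed + rep)
        z_cca = estimator_probs(ds, "cca", seed=seed + rep)
        y = ds.traits.quant[:, -1]
        for j, r in enumerate(ds.snp_roles):
            if r != "het":
                continue
            g = ds.genotypes[:, j].astype(float)
            bg = np.delete(ds.covariates.homogeneous, j, axis=1)
            for Z, sink in ((z_cca, p_cca), (z_mfmr, p_mfmr)):
                sink.append(
                    interaction_test(
                        TestSpec(y=y, family="quantitative", focal=g,
                                 subtype_probs=Z, background=bg,
                                 mode="heterogeneity")
                    ).p_value
                )
    return {
        "cca_fpr": float(np.mean(np.asarray(p_cca) < nominal)),
        "mfmr_fpr": float(np.mean(np.asarray(p_mfmr) < nominal)),
        "n_tests": len(p_cca),
    }
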