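"""Synthetic cohort generation for subtype-model benchmarking.

Generates multi-trait cohorts with latent subtypes, homogeneous /
heterogeneous / null SNP effects, cross-trait correlated noise, and a set
of named stress scenarios (heavy-tailed noise, nonlinear genotype effects,
continuous latent scores, case/control ascertainment, genotype-subtype
correlation, two-population structure).  All draws are reproducible from a
single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mfmr import CovariateSet, TraitMatrix

SNP_ROLES = ("null", "hom", "het")

SCENARIOS = (
    "baseline_k1",
    "baseline_k2",
    "k_gt_2",
    "t5_noise",
    "nonlinear_square",
    "nonlinear_exp",
    "continuous_z",
    "continuous_z_2x",
    "case_control",
    "ge_correlation",
    "population_structure",
    "swap_trait_covariate",
)


@dataclass
class StructureSpec:
    """Two-population Balding-Nichols structure."""

    n_populations: int = 2
    fst: float = 0.1
    n_structure_snps: int = 10_000
    mixture: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        if len(self.mixture) != self.n_populations:
            raise ValueError("mixture length must equal n_populations")
        if not np.isclose(sum(self.mixture), 1.0):
            raise ValueError("mixture must sum to 1")


@dataclass
class AscertainmentSpec:
    population_prevalence: float = 0.2
    sample_case_fraction: float = 0.5
    trait_index: int = 0

    def __post_init__(self) -> None:
        for v in (self.population_prevalence, self.sample_case_fraction):
            if not 0 < v < 1:
                raise ValueError("prevalence/fraction must be in (0,1)")


@dataclass
class SimulationConfig:
    """All knobs of the generative model.

    Variance fractions are on the per-trait scale: each quantitative trait
    has unit total variance split between homogeneous SNP effects
    (``h2_hom``), subtype-specific SNP effects (``h2_het``), subtype main
    effects (``h2_z``) and residual noise.
    """

    n_samples: int = 1000
    k_true: int = 2
    n_quant: int = 27
    n_binary: int = 3
    n_snps: int = 12
    snp_roles: Optional[tuple[str, ...]] = None  # default 4 null / 4 hom / 4 het
    h2_hom: float = 0.04
    h2_het: float = 0.004
    h2_z: float = 0.2
    het_scale: float = 1.0  # post-hoc multiplier on heterogeneous effect sizes
    rho_ge: float = 0.0
    mixing: Optional[tuple[float, ...]] = None  # default uniform
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise_family: str = "gaussian"  # or "t5"
    noise_correlated: bool = True
    snp_transform: str = "identity"  # or "square", "exponentiate"
    continuous_z: bool = False
    ascertainment: Optional[AscertainmentSpec] = None
    structure: Optional[StructureSpec] = None
    h2_pop: float = 0.0  # population main effects on traits (structure mode)
    binary_prevalences: Optional[tuple[float, ...]] = None
    trait_het_mask: Optional[tuple[bool, ...]] = None  # per quant trait
    trait_main_mask: Optional[tuple[bool, ...]] = None  # subtype mains per quant trait
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.k_true < 1:
            raise ValueError("n_samples must be > 0 and k_true >= 1")
        if self.snp_roles is None:
            self.snp_roles = _default_roles(self.n_snps, self.k_true, self.continuous_z)
        self.snp_roles = tuple(self.snp_roles)
        if len(self.snp_roles) != self.n_snps:
            raise ValueError("snp_roles must have one label per SNP")
        if any(r not in SNP_ROLES for r in self.snp_roles):
            raise ValueError(f"snp_roles entries must be in {SNP_ROLES}")
        s = self.het_scale**2
        budget = self.h2_hom + s * self.h2_het + s * self.h2_z + self.h2_pop
        if budget >= 1:
            raise ValueError(f"variance budget {budget:.3f} >= 1")
        if not 0 <= self.rho_ge <= 1:
            raise ValueError("rho_ge must be in [0,1]")
        if self.mixing is None:
            self.mixing = tuple(np.full(self.k_true, 1.0 / self.k_true))
        if not np.isclose(sum(self.mixing), 1.0) or len(self.mixing) != self.k_true:
            raise ValueError("mixing must be a length-k_true simplex vector")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.noise_family not in ("gaussian", "t5"):
            raise ValueError("noise_family must be 'gaussian' or 't5'")
        if self.snp_transform not in ("identity", "square", "exponentiate"):
            raise ValueError("bad snp_transform")
        if self.binary_prevalences is None:
            self.binary_prevalences = tuple(
                (0.2, 0.35, 0.5)[:self.n_binary]
            ) if self.n_binary <= 3 else tuple(np.linspace(0.2, 0.5, self.n_binary))
        if any(not 0 < q < 1 for q in self.binary_prevalences):
            raise ValueError("binary prevalences must be in (0,1)")
        if len(self.binary_prevalences) != self.n_binary:
            raise ValueError("need one prevalence per binary trait")
        for fld in ("trait_het_mask", "trait_main_mask"):
            v = getattr(self, fld)
            if v is not None:
                setattr(self, fld, tuple(v))
                if len(v) != self.n_quant:
                    raise ValueError(f"{fld} must match n_quant")


def _default_roles(n_snps: int, k_true: int, continuous_z: bool) -> tuple[str, ...]:
    if k_true == 1 and not continuous_z:
        return ("hom",) * n_snps
    base = n_snps // 3
    roles = ["null"] * base + ["hom"] * base + ["het"] * (n_snps - 2 * base)
    return tuple(roles)


@dataclass
class SimulatedDataset:
    """A fully drawn cohort plus generative ground truth."""

    genotypes: np.ndarray  # (N, M) int in {0,1,2}
    snp_mafs: np.ndarray
    snp_roles: tuple[str, ...]
    traits: TraitMatrix
    covariates: CovariateSet
    z_true: np.ndarray  # int labels 1..K, or real-valued when continuous
    effect_sizes: dict
    config: SimulationConfig
    structure_snps: Optional[np.ndarray] = None
    population_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotypes must be coded 0/1/2")
        if self.traits.binary.size and not np.isin(self.traits.binary, (0, 1)).all():
            raise ValueError("binary traits must be 0/1")
        if not self.config.continuous_z:
            if not np.isin(self.z_true, np.arange(1, self.config.k_true + 1)).all():
                raise ValueError("z_true labels must be in 1..K")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


# ----------------------------------------------------------------------
# genotypes


def draw_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    structure: Optional[StructureSpec] = None,
    rng: np.random.Generator | int | None = None,
):
    """Draw an additive 0/1/2 genotype matrix.

    Unstructured SNPs are Binomial(2, maf) with maf ~ Uniform(maf_range).
    Under a :class:`StructureSpec`, per-population frequencies follow the
    Balding-Nichols Beta model around an ancestral frequency drawn
    Uniform(0.05, 0.95).

    Returns ``(genotypes, mafs)`` or ``(genotypes, mafs, population_labels)``
    when structured.
    """
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if structure is None:
        mafs = rng.uniform(lo, hi, size=m)
        geno = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
        return geno, mafs
    anc = rng.uniform(0.05, 0.95, size=m)
    f = structure.fst
    a, b = anc * (1 - f) / f, (1 - anc) * (1 - f) / f
    pop_freqs = np.stack(
        [np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4) for _ in range(structure.n_populations)]
    )  # (n_pop, m)
    labels = rng.choice(structure.n_populations, size=n, p=list(structure.mixture))
    geno = rng.binomial(2, pop_freqs[labels, :]).astype(np.int8)
    return geno, anc, labels


def weir_cockerham_fst(
    genotypes: np.ndarray, population_labels: np.ndarray, average: str = "ratio"
):
    """Weir-Cockerham (1984) F_ST from 0/1/2 genotypes and population labels.

    ``average='ratio'`` returns sum(a)/sum(a+b+c) across SNPs (the standard
    multi-SNP estimator); ``average='mean'`` averages per-SNP ratios.
    Also returns the vector of per-SNP estimates.
    """
    g = np.asarray(genotypes, dtype=float)
    pops = np.unique(population_labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([(population_labels == p).sum() for p in pops], dtype=float)
    p_i = np.stack([g[population_labels == p].mean(axis=0) / 2 for p in pops])  # (r, m)
    # observed heterozygote frequency per population
    h_i = np.stack([(g[population_labels == p] == 1).mean(axis=0) for p in pops])
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / n_i.sum()
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / n_i.sum()
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(denom > 0, a / denom, np.nan)
    if average == "ratio":
        overall = float(np.nansum(a) / np.nansum(np.where(denom > 0, denom, np.nan)))
    elif average == "mean":
        overall = float(np.nanmean(per_snp))
    else:
        raise ValueError("average must be 'ratio' or 'mean'")
    return overall, per_snp


# ----------------------------------------------------------------------
# subtypes


def draw_subtypes(
    n: int,
    k: int,
    mixing: Sequence[float],
    rho_ge: float = 0.0,
    snp_score: Optional[np.ndarray] = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw subtype labels in 1..k, optionally correlated with a genetic score.

    rho_ge = 0 gives i.i.d. Categorical(mixing) labels; rho_ge = 1 gives
    labels that are a deterministic threshold function of ``snp_score``
    (cut at the mixing quantiles); intermediate values copy the
    score-determined label with probability rho_ge and draw i.i.d.
    otherwise.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 1 or len(mixing) != k or not np.isclose(mixing.sum(), 1.0):
        raise ValueError("mixing must be a length-k simplex vector")
    if not 0 <= rho_ge <= 1:
        raise ValueError("rho_ge must be in [0,1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if k == 1:
        return np.ones(n, dtype=int)
    iid = rng.choice(k, size=n, p=mixing) + 1
    if rho_ge == 0:
        return iid
    if snp_score is None:
        raise ValueError("snp_score required when rho_ge > 0")
    score = np.asarray(snp_score, dtype=float)
    # rank-based thresholding at mixing quantiles => deterministic label
    ranks = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    cuts = np.floor(np.cumsum(mixing) * n + 1e-9).astype(int)
    det = np.searchsorted(cuts[:-1], ranks, side="right") + 1
    copy = rng.random(n) < rho_ge
    return np.where(copy, det, iid)


# ----------------------------------------------------------------------
# traits


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _scale_to_variance(component: np.ndarray, target: float) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each column to have exactly the target empirical variance."""
    v = component.var(axis=0)
    scale = np.where(v > 0, np.sqrt(target / np.where(v > 0, v, 1.0)), 0.0)
    return component * scale, scale


def _draw_noise(
    rng: np.random.Generator, n: int, p: int, family: str, correlated: bool
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if family == "t5":
        eps = rng.standard_t(5, size=(n, p)) / np.sqrt(5.0 / 3.0)
    else:
        eps = rng.standard_normal((n, p))
    sigma = None
    if correlated and p > 1:
        # random correlation matrix via a scaled Wishart draw
        w = rng.standard_normal((2 * p, p))
        s = w.T @ w / (2 * p)
        d = np.sqrt(np.diag(s))
        sigma = s / np.outer(d, d)
        eps = eps @ np.linalg.cholesky(sigma).T
    return eps, sigma


def _build_signal(
    rng: np.random.Generator,
    config: SimulationConfig,
    g_std: np.ndarray,
    z_true: np.ndarray,
    n_traits: int,
    het_mask: np.ndarray,
    main_mask: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Signal components for a block of traits; each column target-variance scaled."""
    n = g_std.shape[0]
    roles = np.asarray(config.snp_roles)
    hom_idx = np.flatnonzero(roles == "hom")
    het_idx = np.flatnonzero(roles == "het")
    k = config.k_true
    info: dict = {}

    signal = np.zeros((n, n_traits))
    if hom_idx.size and config.h2_hom > 0:
        b_hom = rng.standard_normal((hom_idx.size, n_traits))
        comp = g_std[:, hom_idx] @ b_hom
        comp, sc = _scale_to_variance(comp, config.h2_hom)
        info["beta_hom"] = b_hom * sc
        signal += comp
    else:
        info["beta_hom"] = np.zeros((hom_idx.size, n_traits))

    if config.continuous_z:
        zc = np.asarray(z_true, dtype=float)
        if het_idx.size and config.h2_het > 0:
            b_het = rng.standard_normal((het_idx.size, n_traits))
            comp = (g_std[:, het_idx] @ b_het) * zc[:, None]
            comp, sc = _scale_to_variance(comp, config.h2_het)
            comp *= het_mask * config.het_scale
            info["beta_het"] = b_het * sc * config.het_scale
            signal += comp
        if config.h2_z > 0:
            gam = rng.standard_normal(n_traits)
            comp = zc[:, None] * gam[None, :]
            comp, sc = _scale_to_variance(comp, config.h2_z)
            comp *= main_mask * config.het_scale
            info["gamma"] = gam * sc * config.het_scale
            signal += comp
    elif k > 1:
        zi = np.asarray(z_true, dtype=int) - 1
        if het_idx.size and config.h2_het > 0:
            b_het = rng.standard_normal((k, het_idx.size, n_traits))
            b_het -= b_het.mean(axis=0, keepdims=True)
            comp = np.einsum("im,imt->it", g_std[:, het_idx], b_het[zi])
            comp, sc = _scale_to_variance(comp, config.h2_het)
            comp *= het_mask * config.het_scale
            info["beta_het"] = b_het * sc * config.het_scale
            signal += comp
        if config.h2_z > 0:
            gam = rng.standard_normal((k, n_traits))
            gam -= gam.mean(axis=0, keepdims=True)
            comp = gam[zi]
            comp, sc = _scale_to_variance(comp, config.h2_z)
            comp *= main_mask * config.het_scale
            info["gamma"] = gam * sc * config.het_scale
            signal += comp
    return signal, info


def synthesize_traits(
    config: SimulationConfig,
    genotypes: np.ndarray,
    z_true: np.ndarray,
    rng: np.random.Generator | int | None = None,
    population_labels: Optional[np.ndarray] = None,
) -> tuple[TraitMatrix, CovariateSet, dict]:
    """Draw quantitative and binary traits given genotypes and subtype labels.

    SNP effects act on (optionally transformed, then column-standardized)
    genotypes.  Each variance component is rescaled to hit its configured
    trait-variance fraction exactly in-sample; residual noise fills the
    remainder.  Binary traits are probit-thresholded latent traits.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] != len(z_true):
        raise ValueError("genotypes and z_true must have matching N")
    if g.shape[1] != config.n_snps:
        raise ValueError("genotypes must have config.n_snps columns")
    n = g.shape[0]

    if config.snp_transform == "square":
        g_eff = g**2
    elif config.snp_transform == "exponentiate":
        g_eff = np.exp(g / 2.0)
    else:
        g_eff = g
    g_std = _standardize_columns(g_eff)

    het_mask = (
        np.asarray(config.trait_het_mask, dtype=float)
        if config.trait_het_mask is not None
        else np.ones(config.n_quant)
    )
    main_mask = (
        np.asarray(config.trait_main_mask, dtype=float)
        if config.trait_main_mask is not None
        else het_mask
    )

    signal_q, info_q = _build_signal(
        rng, config, g_std, z_true, config.n_quant, het_mask, main_mask
    )
    ones_b = np.ones(config.n_binary)
    signal_b, info_b = _build_signal(
        rng, config, g_std, z_true, config.n_binary, ones_b, ones_b
    )

    pop_comp_q = np.zeros((n, config.n_quant))
    pop_comp_b = np.zeros((n, config.n_binary))
    if config.h2_pop > 0 and population_labels is not None:
        pc = _standardize_columns(np.asarray(population_labels, float)[:, None])
        pop_comp_q = pc @ (rng.standard_normal((1, config.n_quant)))
        pop_comp_q, _ = _scale_to_variance(pop_comp_q, config.h2_pop)
        pop_comp_b = pc @ (rng.standard_normal((1, config.n_binary)))
        pop_comp_b, _ = _scale_to_variance(pop_comp_b, config.h2_pop)

    def finish(signal: np.ndarray, pop_comp: np.ndarray, n_traits: int):
        total = signal + pop_comp
        sig_var = total.var(axis=0)
        noise_var = np.clip(1.0 - sig_var, 1e-3, None)
        eps, sigma = _draw_noise(rng, n, n_traits, config.noise_family, config.noise_correlated)
        eps = _standardize_columns(eps) * np.sqrt(noise_var)
        return total + eps, sigma, sig_var

    y_quant, sigma_q, sig_var_q = finish(signal_q, pop_comp_q, config.n_quant)
    latent_b, sigma_b, sig_var_b = finish(signal_b, pop_comp_b, config.n_binary)
    y_binary = np.zeros((n, config.n_binary), dtype=int)
    thresholds = []
    for j, prev in enumerate(config.binary_prevalences):
        cut = np.quantile(latent_b[:, j], 1 - prev)
        y_binary[:, j] = (latent_b[:, j] > cut).astype(int)
        thresholds.append(float(cut))

    trait_names = [f"q{t+1}" for t in range(config.n_quant)] + [
        f"b{t+1}" for t in range(config.n_binary)
    ]
    traits = TraitMatrix(
        quant=y_quant,
        binary=y_binary,
        names=trait_names,
    )
    covariates = CovariateSet(
        homogeneous=g,
        heterogeneous=np.ones((n, 1)),
        hom_names=[f"snp{j+1}" for j in range(config.n_snps)],
        het_names=["intercept"],
    )
    effect_sizes = {
        "quant": info_q,
        "binary": info_b,
        "binary_thresholds": thresholds,
        "noise_corr_quant": sigma_q,
        "realized_signal_var_quant": sig_var_q,
        "realized_signal_var_binary": sig_var_b,
    }
    return traits, covariates, effect_sizes


# ----------------------------------------------------------------------
# ascertainment


def ascertain_case_control(
    dataset: SimulatedDataset,
    trait_index: int = 0,
    case_fraction: float = 0.5,
    n_target: Optional[int] = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Subsample a drawn cohort to a target case fraction of a binary trait.

    All row-aligned arrays (genotypes, traits, z_true, covariates) are
    subset identically.  Raises when the population draw holds too few
    cases, naming the required oversampling factor.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    yb = dataset.traits.binary[:, trait_index]
    n = len(yb)
    cases = np.flatnonzero(yb == 1)
    controls = np.flatnonzero(yb == 0)
    prevalence = len(cases) / n
    if np.isclose(prevalence, case_fraction, atol=0.5 / n):
        return dataset
    if n_target is None:
        # use every case when oversampling cases, else every control
        if case_fraction > prevalence:
            n_target = int(np.floor(len(cases) / case_fraction))
        else:
            n_target = int(np.floor(len(controls) / (1 - case_fraction)))
    n_cases = int(round(n_target * case_fraction))
    n_controls = n_target - n_cases
    if n_cases > len(cases):
        need = n_cases / max(len(cases), 1)
        raise ValueError(
            f"insufficient cases: need {n_cases}, have {len(cases)}; "
            f"oversample the population draw by >= {need:.2f}x"
        )
    if n_controls > len(controls):
        need = n_controls / max(len(controls), 1)
        raise ValueError(
            f"insufficient controls: need {n_controls}, have {len(controls)}; "
            f"oversample the population draw by >= {need:.2f}x"
        )
    keep = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    keep.sort()
    return _subset_rows(dataset, keep)


def _subset_rows(dataset: SimulatedDataset, idx: np.ndarray) -> SimulatedDataset:
    traits = TraitMatrix(
        quant=dataset.traits.quant[idx],
        binary=dataset.traits.binary[idx],
        names=list(dataset.traits.names),
    )
    cov = CovariateSet(
        homogeneous=dataset.covariates.homogeneous[idx],
        heterogeneous=dataset.covariates.heterogeneous[idx],
        hom_names=list(dataset.covariates.hom_names),
        het_names=list(dataset.covariates.het_names),
    )
    return dataclasses.replace(
        dataset,
        genotypes=dataset.genotypes[idx],
        traits=traits,
        covariates=cov,
        z_true=dataset.z_true[idx],
        structure_snps=None
        if dataset.structure_snps is None
        else dataset.structure_snps[idx],
        population_labels=None
        if dataset.population_labels is None
        else dataset.population_labels[idx],
    )


# ----------------------------------------------------------------------
# top-level draws


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full cohort from a :class:`SimulationConfig`."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    oversample = 1
    if config.ascertainment is not None:
        asc = config.ascertainment
        oversample = int(
            np.ceil(
                max(
                    asc.sample_case_fraction / asc.population_prevalence,
                    (1 - asc.sample_case_fraction) / (1 - asc.population_prevalence),
                )
                * 1.3
            )
        )
    n_draw = n * oversample

    structure_snps = None
    pop_labels = None
    if config.structure is not None:
        all_geno, mafs, pop_labels = draw_genotypes(
            n_draw,
            config.structure.n_structure_snps,
            config.maf_range,
            structure=config.structure,
            rng=rng,
        )
        causal_idx = rng.choice(config.structure.n_structure_snps, size=config.n_snps, replace=False)
        causal_idx.sort()
        geno = all_geno[:, causal_idx]
        mafs = mafs[causal_idx]
        structure_snps = all_geno
    else:
        geno, mafs = draw_genotypes(n_draw, config.n_snps, config.maf_range, rng=rng)

    if config.continuous_z:
        z_true = rng.standard_normal(n_draw)
    else:
        score = None
        if config.rho_ge > 0:
            roles = np.asarray(config.snp_roles)
            use = np.flatnonzero(roles != "null")
            if use.size == 0:
                use = np.arange(config.n_snps)
            score = _standardize_columns(geno[:, use].astype(float)).sum(axis=1)
        z_true = draw_subtypes(
            n_draw, config.k_true, config.mixing, config.rho_ge, score, rng=rng
        )

    traits, covariates, effects = synthesize_traits(
        config, geno, z_true, rng=rng, population_labels=pop_labels
    )
    ds = SimulatedDataset(
        genotypes=np.asarray(geno),
        snp_mafs=mafs,
        snp_roles=config.snp_roles,
        traits=traits,
        covariates=covariates,
        z_true=z_true,
        effect_sizes=effects,
        config=config,
        structure_snps=structure_snps,
        population_labels=pop_labels,
    )
    if config.ascertainment is not None:
        asc = config.ascertainment
        ds = ascertain_case_control(
            ds, asc.trait_index, asc.sample_case_fraction, n_target=n, rng=rng
        )
    return ds


def _swap_trait_covariate(ds: SimulatedDataset, direction: str) -> SimulatedDataset:
    """Mislabel one variable: last quant trait -> covariate, or first SNP -> trait."""
    tr, cov = ds.traits, ds.covariates
    if direction == "trait_to_covariate":
        moved = tr.quant[:, -1:]
        traits = TraitMatrix(
            quant=tr.quant[:, :-1],
            binary=tr.binary,
            names=[nm for nm in tr.names if nm != tr.names[tr.quant.shape[1] - 1]],
        )
        covariates = CovariateSet(
            homogeneous=np.hstack([cov.homogeneous, moved]),
            heterogeneous=cov.heterogeneous,
            hom_names=list(cov.hom_names) + ["swapped_trait"],
            het_names=list(cov.het_names),
        )
    elif direction == "covariate_to_trait":
        moved = cov.homogeneous[:, :1].astype(float)
        traits = TraitMatrix(
            quant=np.hstack([tr.quant, moved]),
            binary=tr.binary,
            names=tr.names[: tr.quant.shape[1]]
            + ["swapped_snp"]
            + tr.names[tr.quant.shape[1]:],
        )
        covariates = CovariateSet(
            homogeneous=cov.homogeneous[:, 1:],
            heterogeneous=cov.heterogeneous,
            hom_names=list(cov.hom_names[1:]),
            het_names=list(cov.het_names),
        )
    else:
        raise ValueError("direction must be 'trait_to_covariate' or 'covariate_to_trait'")
    return dataclasses.replace(ds, traits=traits, covariates=covariates)


def make_scenario(name: str, overrides: Optional[dict] = None, seed: int = 0) -> SimulatedDataset:
    """Draw one of the canonical named scenarios.

    ``overrides`` updates :class:`SimulationConfig` fields before drawing
    (and carries ``direction`` for the swap scenario).
    """
    overrides = dict(overrides or {})
    direction = overrides.pop("direction", "trait_to_covariate")
    base: dict = dict(n_samples=3000, seed=seed)
    if name == "baseline_k1":
        base.update(k_true=1, h2_het=0.0, h2_z=0.0)
    elif name == "baseline_k2":
        base.update(k_true=2)
    elif name == "k_gt_2":
        base.update(k_true=3)
    elif name == "t5_noise":
        base.update(k_true=1, h2_het=0.0, h2_z=0.0, noise_family="t5")
    elif name == "nonlinear_square":
        base.update(k_true=1, h2_het=0.0, h2_z=0.0, snp_transform="square")
    elif name == "nonlinear_exp":
        base.update(k_true=1, h2_het=0.0, h2_z=0.0, snp_transform="exponentiate")
    elif name == "continuous_z":
        base.update(continuous_z=True, h2_z=0.1, k_true=1)
    elif name == "continuous_z_2x":
        base.update(continuous_z=True, h2_z=0.1, k_true=1, het_scale=2.0)
    elif name == "case_control":
        base.update(k_true=2, ascertainment=AscertainmentSpec(0.2, 0.5, 0))
    elif name == "ge_correlation":
        base.update(k_true=2, rho_ge=overrides.pop("rho_ge", 0.5))
    elif name == "population_structure":
        base.update(k_true=2, structure=StructureSpec(), h2_pop=0.1)
    elif name == "swap_trait_covariate":
        base.update(k_true=2)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base.update(overrides)
    ds = simulate_dataset(SimulationConfig(**base))
    if name == "swap_trait_covariate":
        ds = _swap_trait_covariate(ds, direction)
    return ds
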