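"""End-to-end orchestration: read or simulate a dataset, impute, fit the
mixture, run step-2 tests, and write a reproducible results bundle."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assoc, gxemm, io as rio, mfmr
from .impute import lowrank_impute, mvn_impute
from .simulate import SCENARIOS, make_scenario

ROLES = ("trait_quant", "trait_binary", "covariate_hom", "covariate_het", "id", "ignore")


@dataclass
class RunConfig:
    """Declarative description of a full run (YAML-loadable)."""

    # either file inputs ...
    phenotypes: Optional[str] = None
    covariates: Optional[str] = None
    genotypes: Optional[str] = None  # TSV path or PLINK prefix
    column_roles: dict = field(default_factory=dict)  # name -> role
    # ... or a simulation scenario
    scenario: Optional[str] = None
    scenario_overrides: dict = field(default_factory=dict)

    K: Optional[int] = 2
    k_grid: Optional[list[int]] = None
    n_restarts: int = 10
    max_iter: int = 500
    rel_tol: float = 1e-8
    focal_covariates: dict = field(default_factory=dict)  # name -> mfmr|mfmrx|mfmr+
    test_modes: list[str] = field(default_factory=lambda: ["heterogeneity"])
    scan_mode: Optional[str] = None  # gwas | gxe_global | het
    run_gxemm: bool = False
    n_pcs: int = 0
    bonferroni_m: Optional[int] = None
    lambda_gc_ceiling: float = 1.5
    impute_method: str = "mvn"  # or "lowrank"
    lowrank_rank: int = 5
    seed: int = 0
    outdir: str = "rgwas_out"
    force: bool = False

    def __post_init__(self) -> None:
        if self.scenario is None and self.phenotypes is None:
            raise ValueError("config needs either input files or a simulation scenario")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name, role in self.column_roles.items():
            if role not in ROLES:
                raise ValueError(f"column {name!r}: unknown role {role!r}")
        for name, mode in self.focal_covariates.items():
            if mode not in ("mfmr", "mfmrx", "mfmr+"):
                raise ValueError(f"focal covariate {name!r}: mode must be mfmr|mfmrx|mfmr+")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _subseed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed fan-out from the global seed."""
    h = np.uint64(seed)
    for ch in stage:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**63 - 1))
    return int(h % (2**31 - 1))


def read_dataset(config: RunConfig):
    """Load and role-assign TSV/PLINK inputs, inner-joined on sample ID."""
    pheno = rio.read_table(config.phenotypes)
    frames = {"phenotypes": pheno}
    if config.covariates:
        frames["covariates"] = rio.read_table(config.covariates)
    geno = sample_ids_g = snp_ids = None
    if config.genotypes:
        gpath = Path(config.genotypes)
        if gpath.suffix in (".tsv", ".txt") or gpath.exists():
            geno, sample_ids_g, snp_ids = rio.read_genotypes_tsv(config.genotypes)
        else:
            geno, sample_ids_g, snp_ids = rio.read_plink(config.genotypes)
        frames["genotypes"] = pd.DataFrame(geno, index=pd.Index([str(s) for s in sample_ids_g]), columns=snp_ids)

    ids = None
    for df in frames.values():
        ids = df.index if ids is None else ids.intersection(df.index)
    n_drop = max(len(df) for df in frames.values()) - len(ids)
    if len(ids) == 0:
        raise ValueError("no overlapping sample IDs across input files")
    if n_drop:
        warnings.warn(f"dropped {n_drop} samples without matches across files")
    frames = {k: df.loc[ids] for k, df in frames.items()}

    merged = pd.concat([frames["phenotypes"], frames.get("covariates", pd.DataFrame(index=ids))], axis=1)
    qcols, bcols, xcols, gcols = [], [], [], []
    for name in merged.columns:
        role = config.column_roles.get(name, "trait_quant")
        if role == "trait_quant":
            qcols.append(name)
        elif role == "trait_binary":
            vals = merged[name].dropna().unique()
            if not set(vals).issubset({0, 1, 0.0, 1.0}):
                raise ValueError(f"binary column {name!r} contains non-0/1 values")
            bcols.append(name)
        elif role == "covariate_hom":
            xcols.append(name)
        elif role == "covariate_het":
            gcols.append(name)
        # id / ignore: skipped

    quant = merged[qcols].to_numpy(dtype=float)
    binary = merged[bcols].to_numpy(dtype=float)
    x = merged[xcols].to_numpy(dtype=float) if xcols else np.zeros((len(ids), 0))
    g_extra = merged[gcols].to_numpy(dtype=float) if gcols else np.zeros((len(ids), 0))

    return {
        "sample_ids": list(ids),
        "quant": quant,
        "binary": binary,
        "quant_names": qcols,
        "binary_names": bcols,
        "x": x,
        "x_names": xcols,
        "g_extra": g_extra,
        "g_names": gcols,
        "genotypes": frames["genotypes"].to_numpy() if "genotypes" in frames else None,
        "snp_ids": snp_ids,
    }


def _dataset_from_scenario(config: RunConfig):
    ds = make_scenario(config.scenario, config.scenario_overrides,
                       seed=_subseed(config.seed, "simulate"))
    n = ds.n_samples
    return {
        "sample_ids": [f"s{i+1}" for i in range(n)],
        "quant": ds.traits.quant,
        "binary": ds.traits.binary.astype(float),
        "quant_names": ds.traits.names[: ds.traits.n_quant],
        "binary_names": ds.traits.names[ds.traits.n_quant:],
        "x": ds.covariates.homogeneous,
        "x_names": ds.covariates.hom_names,
        "g_extra": np.zeros((n, 0)),
        "g_names": [],
        "genotypes": np.asarray(ds.genotypes, dtype=float),
        "snp_ids": [f"snp{j+1}" for j in range(ds.genotypes.shape[1])],
        "_truth": ds,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute impute -> fit -> step-2 tests; returns the results bundle."""
    data = _dataset_from_scenario(config) if config.scenario else read_dataset(config)
    n = len(data["sample_ids"])
    log = {"seed": config.seed, "stages": []}

    # --- impute ---------------------------------------------------------
    joint = np.hstack([data["quant"], data["binary"], data["x"], data["g_extra"]])
    if np.isnan(joint).any():
        bin_ix = list(range(data["quant"].shape[1], data["quant"].shape[1] + data["binary"].shape[1]))
        if config.impute_method == "mvn":
            res = mvn_impute(joint, binary_cols=bin_ix)
        else:
            res = lowrank_impute(joint, rank=config.lowrank_rank, binary_cols=bin_ix,
                                 seed=_subseed(config.seed, "impute"))
        joint = res.completed
        log["stages"].append({"impute": res.method, "n_imputed": int(res.mask_missing.sum())})
    p, b, q = data["quant"].shape[1], data["binary"].shape[1], data["x"].shape[1]
    quant = joint[:, :p]
    binary = joint[:, p:p + b].astype(int)
    x = joint[:, p + b:p + b + q]
    g_extra = joint[:, p + b + q:]

    # focal-covariate placement
    x_cols, g_cols = list(data["x_names"]), []
    x_mat, g_mat = x, np.zeros((n, 0))
    for name, mode in config.focal_covariates.items():
        if name not in x_cols:
            continue
        j = x_cols.index(name)
        col = x_mat[:, j:j + 1]
        if mode in ("mfmrx", "mfmr+"):
            x_mat = np.delete(x_mat, j, axis=1)
            x_cols.pop(j)
        if mode == "mfmr+":
            g_mat = np.hstack([g_mat, col])
            g_cols.append(name)

    traits = mfmr.TraitMatrix(quant=quant, binary=binary,
                              names=data["quant_names"] + data["binary_names"])
    het = np.hstack([np.ones((n, 1)), g_extra, g_mat])
    cov = mfmr.CovariateSet(
        homogeneous=x_mat, heterogeneous=het,
        hom_names=x_cols, het_names=["intercept"] + data["g_names"] + g_cols,
    )

    # --- fit ------------------------------------------------------------
    k = config.K
    cv = None
    if config.k_grid:
        cv = mfmr.cv_select_K(traits, cov, config.k_grid, seed=_subseed(config.seed, "cv"),
                              opts=mfmr.FitOptions(K=2, n_restarts=config.n_restarts,
                                                   max_iter=config.max_iter,
                                                   rel_tol=config.rel_tol,
                                                   seed=_subseed(config.seed, "cvfit")))
        k = int(np.array(cv["k_grid"])[np.argmax(cv["mean"])])
        log["stages"].append({"cv_select_K": k})
    opts = mfmr.FitOptions(K=k, n_restarts=config.n_restarts, max_iter=config.max_iter,
                           rel_tol=config.rel_tol, seed=_subseed(config.seed, "fit"))
    params, post = mfmr.fit_mfmr(traits, cov, opts)
    log["stages"].append({"fit": {"K": k, "loglik": params.loglik_trace[-1],
                                  "converged": params.converged,
                                  "degenerate": params.degenerate}})

    bundle = {
        "config": dataclasses.asdict(config),
        "log": log,
        "sample_ids": data["sample_ids"],
        "Z": post.Z,
        "params": params,
        "traits": traits,
        "covariates": cov,
        "cv": cv,
        "tests": None,
        "scan": None,
        "varcomp": None,
        "lambda_gc": {},
    }

    if k == 1:
        log["stages"].append({"tests": "refused: no subtype variation (K=1)"})
        return bundle

    # --- step-2 fixed-effect tests -------------------------------------
    rows = []
    all_names = traits.names
    for name, mode in config.focal_covariates.items():
        if name in data["x_names"]:
            focal = x[:, data["x_names"].index(name)]
        elif data["snp_ids"] and name in data["snp_ids"]:
            focal = data["genotypes"][:, data["snp_ids"].index(name)]
        else:
            raise ValueError(f"focal covariate {name!r} not found")
        bg = np.delete(x_mat, x_cols.index(name), axis=1) if name in x_cols else x_mat
        for t, tname in enumerate(all_names):
            fam = "quantitative" if t < traits.n_quant else "binary"
            y = traits.quant[:, t] if fam == "quantitative" else traits.binary[:, t - traits.n_quant].astype(float)
            for tmode in config.test_modes:
                res = assoc.interaction_test(assoc.TestSpec(
                    y=y, family=fam, focal=focal, subtype_probs=post.Z,
                    background=bg if bg.size else None, mode=tmode))
                rows.append(dict(focal=name, trait=tname, mode=tmode, stat=res.statistic,
                                 df=res.df, p=res.p_value,
                                 **{f"beta{s+1}": res.effects[s] for s in range(k)},
                                 **{f"se{s+1}": res.ses[s] for s in range(k)}))
    if rows:
        bundle["tests"] = pd.DataFrame(rows)

    # --- genome scan ----------------------------------------------------
    if config.scan_mode and data["genotypes"] is not None:
        # scanned SNPs must not re-enter the background design
        snp_set = set(data["snp_ids"] or [])
        keep_bg = [j for j, nm in enumerate(x_cols) if nm not in snp_set]
        scan_bg = x_mat[:, keep_bg]
        scans = []
        for t, tname in enumerate(all_names):
            fam = "quantitative" if t < traits.n_quant else "binary"
            y = traits.quant[:, t] if fam == "quantitative" else traits.binary[:, t - traits.n_quant].astype(float)
            tab = assoc.genome_scan(data["genotypes"], y, fam, post.Z,
                                    background=scan_bg if scan_bg.size else None,
                                    mode=config.scan_mode, snp_ids=data["snp_ids"])
            tab.insert(0, "trait", tname)
            ok = tab["p"].dropna()
            lam = assoc.lambda_gc(ok.to_numpy()) if len(ok) else np.nan
            bundle["lambda_gc"][tname] = lam
            if np.isfinite(lam) and lam > config.lambda_gc_ceiling:
                tab["flag"] = f"lambda_gc={lam:.2f}>ceiling"
            scans.append(tab)
        bundle["scan"] = pd.concat(scans, ignore_index=True)

    # --- polygenic test -------------------------------------------------
    if config.run_gxemm and data["genotypes"] is not None:
        grm = gxemm.compute_grm(data["genotypes"], sample_ids=data["sample_ids"])
        khet = gxemm.het_kernel(grm, post.Z)
        vrows = []
        fx = np.hstack([x_mat, post.Z[:, :-1]]) if x_mat.size else post.Z[:, :-1]
        for t in range(traits.n_quant):
            fit = gxemm.fit_iid_gxemm(traits.quant[:, t], fx, grm, khet)
            tests = gxemm.test_components(fit)
            vrows.append(dict(trait=all_names[t], h2_hom=fit.h2_hom, h2_het=fit.h2_het,
                              h2_iid=fit.h2_iid, h2_greml=fit.h2_greml,
                              se_h2_iid=fit.se_h2[2], wald_p=tests["wald_p"],
                              lrt_p=tests["lrt_p"], converged=fit.converged))
        bundle["varcomp"] = pd.DataFrame(vrows)

    return bundle


def write_results(bundle: dict, outdir, force: bool = False) -> list[str]:
    """Write the bundle as TSV tables + JSON model + run manifest."""
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True / --force")
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rio.write_posterior(bundle["Z"], bundle["sample_ids"], out / "subtype_posterior.tsv")
    written.append("subtype_posterior.tsv")
    schema = {
        "trait_names": bundle["traits"].names,
        "hom_names": bundle["covariates"].hom_names,
        "het_names": bundle["covariates"].het_names,
    }
    rio.save_model(bundle["params"], schema, out / "model.json")
    written.append("model.json")

    for key, fname in (("tests", "tests.tsv"), ("scan", "scan.tsv"), ("varcomp", "varcomp.tsv")):
        df = bundle.get(key)
        if df is None:
            df = pd.DataFrame()
        df.to_csv(out / fname, sep="\t", index=False)
        written.append(fname)

    manifest = {
        "config": bundle["config"],
        "log": bundle["log"],
        "lambda_gc": {k: (None if v is None or not np.isfinite(v) else float(v))
                      for k, v in bundle["lambda_gc"].items()},
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    written.append("manifest.json")
    return written
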