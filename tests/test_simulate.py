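import numpy as np
import pytest
from scipy import stats

from rgwas.simulate import (
    AscertainmentSpec,
    SimulationConfig,
    StructureSpec,
    ascertain_case_control,
    draw_genotypes,
    draw_subtypes,
    make_scenario,
    simulate_dataset,
    synthesize_traits,
    weir_cockerham_fst,
)


class TestConfigValidation:
    def test_variance_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            SimulationConfig(h2_hom=0.5, h2_het=0.3, h2_z=0.3)

    def test_bad_rho(self):
        with pytest.raises(ValueError, match="rho_ge"):
            SimulationConfig(rho_ge=1.5)

    def test_roles_partition(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=3, snp_roles=("hom", "hom"))
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=2, snp_roles=("hom", "weird"))

    def test_bad_prevalence(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_binary=1, binary_prevalences=(1.2,))

    def test_default_roles_partition(self):
        c = SimulationConfig(n_snps=12, k_true=2)
        assert len(c.snp_roles) == 12
        assert c.snp_roles.count("null") == 4
        assert c.snp_roles.count("hom") == 4
        assert c.snp_roles.count("het") == 4


class TestDrawGenotypes:
    def test_frequencies_and_hwe(self):
        geno, mafs = draw_genotypes(4000, 12, (0.05, 0.5), rng=0)
        assert geno.shape == (4000, 12)
        assert set(np.unique(geno)) <= {0, 1, 2}
        freq = geno.mean(axis=0) / 2
        se = np.sqrt(mafs * (1 - mafs) / (2 * 4000))
        assert (np.abs(freq - mafs) < 5 * se).all()
        # HWE: heterozygote fraction close to 2pq
        het = (geno == 1).mean(axis=0)
        assert np.abs(het - 2 * mafs * (1 - mafs)).max() < 0.03

    def test_maf_half_symmetry(self):
        geno, _ = draw_genotypes(200_000, 1, (0.5, 0.5), rng=1)
        assert abs(geno.mean() - 1.0) < 0.01

    def test_bad_args(self):
        with pytest.raises(ValueError):
            draw_genotypes(0, 5)
        with pytest.raises(ValueError):
            draw_genotypes(10, 5, (0.0, 0.5))
        with pytest.raises(ValueError):
            draw_genotypes(10, 5, (0.1, 0.7))

    def test_fst_recovery(self):
        geno, _, pops = draw_genotypes(
            2000, 2000, structure=StructureSpec(fst=0.1), rng=2
        )
        fst, per_snp = weir_cockerham_fst(geno, pops)
        se = np.nanstd(per_snp) / np.sqrt(np.sum(np.isfinite(per_snp)))
        assert abs(fst - 0.1) < max(2 * se, 0.01)


class TestDrawSubtypes:
    def test_independent_when_rho_zero(self):
        rng = np.random.default_rng(0)
        score = rng.standard_normal(5000)
        z = draw_subtypes(5000, 2, (0.5, 0.5), 0.0, score, rng=rng)
        assert abs(np.corrcoef(z, score)[0, 1]) < 0.05

    def test_deterministic_when_rho_one(self):
        rng = np.random.default_rng(1)
        score = rng.standard_normal(1000)
        z1 = draw_subtypes(1000, 3, (0.3, 0.3, 0.4), 1.0, score, rng=10)
        z2 = draw_subtypes(1000, 3, (0.3, 0.3, 0.4), 1.0, score, rng=99)
        assert (z1 == z2).all()  # function of score only
        # monotone in score rank
        assert (np.diff(z1[np.argsort(score)]) >= 0).all()

    def test_k1_degenerate(self):
        assert (draw_subtypes(50, 1, (1.0,), 0.7, np.zeros(50), rng=0) == 1).all()

    def test_correlation_monotone_in_rho(self):
        rng = np.random.default_rng(3)
        score = rng.standard_normal(20000)
        r2 = []
        for rho in (0.0, 0.5, 1.0):
            z = draw_subtypes(20000, 2, (0.5, 0.5), rho, score, rng=5)
            r2.append(np.corrcoef(z, score)[0, 1] ** 2)
        assert r2[0] < r2[1] < r2[2]

    def test_errors(self):
        with pytest.raises(ValueError, match="simplex"):
            draw_subtypes(10, 2, (0.7, 0.7))
        with pytest.raises(ValueError, match="snp_score"):
            draw_subtypes(10, 2, (0.5, 0.5), rho_ge=0.5)


class TestSynthesizeTraits:
    def test_hom_variance_fraction(self):
        cfg = SimulationConfig(n_samples=10_000, k_true=1, h2_het=0, h2_z=0, seed=0)
        ds = simulate_dataset(cfg)
        # regression R2 of hom SNPs on each quant trait ~ 4%
        g = np.asarray(ds.genotypes, dtype=float)
        x = np.hstack([np.ones((10_000, 1)), g])
        r2 = []
        for t in range(ds.traits.n_quant):
            y = ds.traits.quant[:, t]
            resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
            r2.append(1 - resid.var() / y.var())
        assert abs(np.mean(r2) - 0.04) < 0.01

    def test_null_traits_uniform_p(self):
        cfg = SimulationConfig(
            n_samples=500, k_true=1, h2_hom=0, h2_het=0, h2_z=0,
            n_quant=10, n_binary=0, seed=1,
        )
        ds = simulate_dataset(cfg)
        g = np.asarray(ds.genotypes, dtype=float)
        ps = []
        for j in range(g.shape[1]):
            for t in range(10):
                r, p = stats.pearsonr(g[:, j], ds.traits.quant[:, t])
                ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_t5_noise_kurtosis(self):
        # moment oracle: excess kurtosis of t_5 is 6 / (5 - 4) = 6
        cfg = SimulationConfig(
            n_samples=60_000, k_true=1, h2_hom=0, h2_het=0, h2_z=0,
            n_quant=4, n_binary=0, noise_family="t5", noise_correlated=False, seed=2,
        )
        ds = simulate_dataset(cfg)
        kurt = stats.kurtosis(ds.traits.quant, axis=0, fisher=True)
        # sample kurtosis of t5 converges slowly; generous Monte-Carlo band
        assert (kurt > 2.0).all()
        gauss = SimulationConfig(
            n_samples=60_000, k_true=1, h2_hom=0, h2_het=0, h2_z=0,
            n_quant=4, n_binary=0, noise_family="gaussian", noise_correlated=False, seed=2,
        )
        kg = stats.kurtosis(simulate_dataset(gauss).traits.quant, axis=0)
        assert kurt.mean() > kg.mean() + 1.5

    def test_binary_prevalences(self):
        cfg = SimulationConfig(n_samples=8000, seed=3)
        ds = simulate_dataset(cfg)
        prev = ds.traits.binary.mean(axis=0)
        assert np.abs(prev - np.array([0.2, 0.35, 0.5])).max() < 0.02

    def test_conformability_errors(self):
        cfg = SimulationConfig(n_samples=100, seed=0)
        geno, _ = draw_genotypes(100, 12, rng=0)
        with pytest.raises(ValueError):
            synthesize_traits(cfg, geno[:50], np.ones(100, dtype=int))
        with pytest.raises(ValueError):
            synthesize_traits(cfg, geno[:, :5], np.ones(100, dtype=int))

    def test_main_mask_separates_components(self):
        hm = (False,) * 5
        mm = (True,) * 5
        cfg = SimulationConfig(
            n_samples=6000, n_quant=5, n_binary=0, h2_het=0.05,
            trait_het_mask=hm, trait_main_mask=mm, seed=4,
        )
        ds = simulate_dataset(cfg)
        # mains present: subtype group means differ
        d = ds.traits.quant[ds.z_true == 1].mean(0) - ds.traits.quant[ds.z_true == 2].mean(0)
        assert np.abs(d).max() > 0.2


class TestAscertainment:
    def test_fifty_fifty(self):
        ds = make_scenario("case_control", {"n_samples": 1500}, seed=5)
        frac = ds.traits.binary[:, 0].mean()
        assert ds.n_samples == 1500
        assert abs(frac - 0.5) < 1e-6

    def test_identity_when_at_target(self):
        ds = make_scenario("baseline_k2", {"n_samples": 500}, seed=6)
        prev = ds.traits.binary[:, 2].mean()
        same = ascertain_case_control(ds, trait_index=2, case_fraction=prev)
        assert same.n_samples == ds.n_samples

    def test_insufficient_cases_error(self):
        ds = make_scenario("baseline_k2", {"n_samples": 400}, seed=7)
        with pytest.raises(ValueError, match="oversample"):
            ascertain_case_control(ds, trait_index=0, case_fraction=0.5, n_target=400)

    def test_subsample_alignment(self):
        ds = make_scenario("baseline_k2", {"n_samples": 600}, seed=8)
        sub = ascertain_case_control(ds, trait_index=0, case_fraction=0.5, n_target=200)
        assert sub.n_samples == 200
        assert sub.genotypes.shape[0] == len(sub.z_true) == sub.traits.quant.shape[0]
        assert abs(sub.traits.binary[:, 0].mean() - 0.5) < 0.01


class TestScenarios:
    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("not_a_scenario")

    def test_determinism(self):
        a = make_scenario("baseline_k2", {"n_samples": 300}, seed=9)
        b = make_scenario("baseline_k2", {"n_samples": 300}, seed=9)
        assert (a.genotypes == b.genotypes).all()
        assert (a.traits.quant == b.traits.quant).all()
        assert (a.z_true == b.z_true).all()

    def test_baseline_k1_structure(self):
        ds = make_scenario("baseline_k1", {"n_samples": 200}, seed=10)
        assert (np.asarray(ds.z_true) == 1).all()
        assert all(r == "hom" for r in ds.snp_roles)

    def test_continuous_z_2x_doubles_het_effects(self):
        a = make_scenario("continuous_z", {"n_samples": 400}, seed=11)
        b = make_scenario("continuous_z_2x", {"n_samples": 400}, seed=11)
        ga = a.effect_sizes["quant"]["gamma"]
        gb = b.effect_sizes["quant"]["gamma"]
        assert np.allclose(gb, 2 * ga)

    def test_swap_scenario_moves_columns(self):
        base = make_scenario("baseline_k2", {"n_samples": 200}, seed=12)
        sw = make_scenario("swap_trait_covariate", {"n_samples": 200}, seed=12)
        assert sw.traits.n_quant == base.traits.n_quant - 1
        assert sw.covariates.n_hom == base.covariates.n_hom + 1
        sw2 = make_scenario(
            "swap_trait_covariate",
            {"n_samples": 200, "direction": "covariate_to_trait"},
            seed=12,
        )
        assert sw2.traits.n_quant == base.traits.n_quant + 1
        assert sw2.covariates.n_hom == base.covariates.n_hom - 1

    def test_population_structure_scenario(self):
        ds = make_scenario(
            "population_structure",
            {"n_samples": 300, "structure": StructureSpec(n_structure_snps=500)},
            seed=13,
        )
        assert ds.structure_snps.shape == (300, 500)
        assert ds.population_labels is not None
        assert ds.genotypes.shape[1] == 12


class TestVarianceAccounting:
    def test_realized_fractions(self):
        cfg = SimulationConfig(n_samples=10_000, k_true=2, seed=14)
        ds = simulate_dataset(cfg)
        sig = ds.effect_sizes["realized_signal_var_quant"]
        target = 0.04 + 0.004 + 0.2
        assert np.abs(sig - target).max() < 0.02
        assert np.abs(ds.traits.quant.var(axis=0) - 1.0).max() < 0.1
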