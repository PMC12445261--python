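import numpy as np
import pytest
from scipy import stats

from addom import cohort, kinship, varcomp
from addom.varcomp import (
    MixedModelSpec,
    VarCompResult,
    build_design,
    dominance_fraction,
    heritability,
    liability_transform,
    reml_fit,
)

from conftest import founder_config


def _family_fit(seed, h2=0.5, d2=0.0, n_lambs=450, m=2000, with_dominance=False):
    cfg = cohort.CohortConfig(
        n_sires=20, n_ewes=n_lambs // 3 + 2, n_lambs=n_lambs,
        n_contemporaries_ungenotyped=0, n_variants=m,
        n_qtl_additive=200, n_qtl_dominance=200 if d2 > 0 else 0,
        traits=[cohort.TraitSpec("T", "gaussian", h2=h2, d2=d2)],
        seed=seed,
    )
    ped = cohort.simulate_pedigree(cfg)
    geno = cohort.simulate_genotypes(ped, cfg)
    traits, truth = cohort.simulate_traits(ped, geno, cfg)
    lambs = traits.loc[traits["role"] == "lamb", "animal"].tolist()
    g = geno.subset_samples(lambs)
    G = kinship.grm_additive(g)
    random = [("genomic", G)]
    if with_dominance:
        random.append(("dominance", kinship.grm_dominance(g)))
    sub = traits.set_index("animal").loc[lambs].reset_index()
    X, _ = build_design(sub)
    y = sub["T"].to_numpy(float)
    return MixedModelSpec(y=y, X=X, random=random, ids=lambs), truth


class TestBuildDesign:
    def test_full_rank_and_reference_coding(self, default_cohort):
        _, _, _, traits, _ = default_cohort
        X, names = build_design(traits)
        assert np.linalg.matrix_rank(X) == X.shape[1]
        assert names[0] == "intercept"
        # sex (2 levels) -> 1 column, birth type (3) -> 2, parity (4) -> 3
        assert X.shape[1] == 1 + 1 + 2 + 3

    def test_qcovariates_appended(self, default_cohort):
        _, _, _, traits, _ = default_cohort
        t = traits.copy()
        t["PC1"] = np.arange(len(t), dtype=float)
        X, names = build_design(t, qcovariates=["PC1"])
        assert "PC1" in names


class TestRemlFit:
    def test_pure_noise_h2_near_zero(self):
        rng = np.random.default_rng(0)
        n = 300
        # block-family structure so components are separable
        Z = np.zeros((n, 30))
        Z[np.arange(n), np.repeat(np.arange(30), 10)] = 1.0
        K = Z @ Z.T
        y = rng.standard_normal(n)
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), random=[("genomic", K)])
        res = reml_fit(spec)
        h2, se = heritability(res)
        assert h2 < max(2 * se, 0.05)

    def test_balanced_anova_closed_form(self):
        # g groups x k reps; K = ZZ' block design. REML variance components
        # equal the classical ANOVA estimators on balanced data.
        rng = np.random.default_rng(3)
        g, k = 40, 5
        n = g * k
        groups = np.repeat(np.arange(g), k)
        u = rng.standard_normal(g) * np.sqrt(2.0)
        y = 1.0 + u[groups] + rng.standard_normal(n)
        Z = np.zeros((n, g))
        Z[np.arange(n), groups] = 1.0
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), random=[("between", Z @ Z.T)])
        res = reml_fit(spec, tol=1e-10)
        # ANOVA oracle
        gm = y.reshape(g, k)
        msw = ((gm - gm.mean(1, keepdims=True)) ** 2).sum() / (g * (k - 1))
        msb = k * ((gm.mean(1) - gm.mean()) ** 2).sum() / (g - 1)
        sigma_b = (msb - msw) / k
        assert res.components["residual"] == pytest.approx(msw, rel=1e-4)
        assert res.components["between"] == pytest.approx(sigma_b, rel=1e-4)

    def test_ai_and_em_same_optimum(self):
        spec, _ = _family_fit(seed=17, h2=0.5, n_lambs=240, m=1200)
        res_ai = reml_fit(spec, algorithm="ai-em")
        res_em = reml_fit(spec, algorithm="em", max_iter=2000, tol=1e-10)
        assert abs(res_ai.loglik - res_em.loglik) < 1e-4
        np.testing.assert_allclose(res_ai.estimates, res_em.estimates, atol=5e-3)

    def test_additive_recovery(self):
        hits = 0
        for seed in range(5):
            spec, _ = _family_fit(seed=100 + seed, h2=0.5, n_lambs=450, m=2000)
            res = reml_fit(spec)
            h2, se = heritability(res)
            if abs(h2 - 0.5) <= 2 * se:
                hits += 1
        assert hits >= 4

    def test_gd_model_recovery_and_misspecification(self):
        spec, truth = _family_fit(
            seed=77, h2=0.6, d2=0.15, n_lambs=600, m=2500, with_dominance=True
        )
        res = reml_fit(spec)
        h2, h2se = heritability(res)
        d2, d2se = res.ratio("dominance")
        assert abs(h2 - 0.6) <= 2 * h2se
        assert abs(d2 - 0.15) <= 2 * d2se
        # dropping D inflates the remaining components
        spec_a = MixedModelSpec(
            y=spec.y, X=spec.X, random=[spec.random[0]], ids=spec.ids
        )
        res_a = reml_fit(spec_a)
        assert (
            res_a.components["genomic"] + res_a.components["residual"]
            > res.components["genomic"] + res.components["residual"] - 1e-6
        )

    def test_nonconvergence_flagged(self):
        spec, _ = _family_fit(seed=18, n_lambs=120, m=600)
        res = reml_fit(spec, max_iter=1)
        assert not res.converged
        assert np.isfinite(res.estimates).all()

    def test_sigma_p_is_component_sum(self):
        spec, _ = _family_fit(seed=19, n_lambs=120, m=600)
        res = reml_fit(spec)
        assert res.sigma_p2 == pytest.approx(res.estimates.sum())

    def test_rank_deficient_design_rejected(self):
        n = 30
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            MixedModelSpec(y=np.random.randn(n), X=X, random=[("g", np.eye(n))])


class TestHeritability:
    def test_worked_example_high(self):
        res = VarCompResult.from_components({"genomic": 4.19, "residual": 0.76})
        assert res.sigma_p2 == pytest.approx(4.95)
        h2, _ = heritability(res)
        assert round(h2, 2) == 0.85

    def test_worked_example_moderate(self):
        res = VarCompResult.from_components({"genomic": 0.05, "residual": 0.19})
        assert res.sigma_p2 == pytest.approx(0.24)
        h2, _ = heritability(res)
        assert round(h2, 2) == 0.21

    def test_zero_additive(self):
        res = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        assert heritability(res)[0] == 0.0

    def test_zero_phenotypic_variance_rejected(self):
        res = VarCompResult.from_components({"genomic": 0.0, "residual": 0.0})
        with pytest.raises(ValueError):
            heritability(res)


class TestDominanceFraction:
    def test_worked_example(self):
        res = VarCompResult.from_components(
            {"genomic": 3.99, "dominance": 0.74, "residual": 0.22}
        )
        assert res.sigma_p2 == pytest.approx(4.95)
        assert round(dominance_fraction(res), 2) == 14.95

    def test_zero_dominance(self):
        res = VarCompResult.from_components(
            {"genomic": 1.0, "dominance": 0.0, "residual": 1.0}
        )
        assert dominance_fraction(res) == 0.0

    def test_missing_dominance_rejected(self):
        res = VarCompResult.from_components({"genomic": 1.0, "residual": 1.0})
        with pytest.raises(ValueError):
            dominance_fraction(res)


class TestLiabilityTransform:
    def test_half_prevalence_closed_form(self):
        # K = P = 0.5: factor = 0.25 / phi(0)^2 = pi/2
        got = liability_transform(0.3, 0.5, 0.5)
        assert got == pytest.approx(0.3 * np.pi / 2, rel=1e-12)

    def test_zero_h2(self):
        assert liability_transform(0.0, 0.2, 0.4) == 0.0

    def test_reduces_when_p_equals_k(self):
        for K in (0.1, 0.25, 0.4):
            z = stats.norm.pdf(stats.norm.ppf(1 - K))
            expect = 0.2 * K * (1 - K) / z**2
            assert liability_transform(0.2, K, K) == pytest.approx(expect)

    def test_factor_above_one_minimized_at_half(self):
        grid = np.linspace(0.02, 0.98, 49)
        factors = np.array([liability_transform(1.0, K, K) for K in grid])
        assert (factors > 1.0).all()
        assert grid[np.argmin(factors)] == pytest.approx(0.5)

    def test_monotone_in_h2(self):
        a = liability_transform(0.1, 0.2, 0.2)
        b = liability_transform(0.3, 0.2, 0.2)
        assert b > a

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            liability_transform(0.3, 0.0, 0.5)
        with pytest.raises(ValueError):
            liability_transform(0.3, 0.5, 1.0)

    def test_binary_fit_reports_case_proportion(self):
        cfg = founder_config(
            400, 400, seed=55, n_qtl_additive=100,
            traits=[cohort.TraitSpec("B", "binary", h2=0.4, prevalence=0.3)],
        )
        ped = cohort.simulate_pedigree(cfg)
        geno = cohort.simulate_genotypes(ped, cfg)
        traits, _ = cohort.simulate_traits(ped, geno, cfg)
        G = kinship.grm_additive(geno)
        y = traits["B"].to_numpy(float)
        spec = MixedModelSpec(
            y=y, X=np.ones((len(y), 1)), random=[("genomic", G)],
            scale="binary-observed", prevalence=0.3,
        )
        res = reml_fit(spec)
        assert res.case_proportion == pytest.approx(y.mean())
        h2, _ = heritability(res)
        h2_liab = liability_transform(h2, res.prevalence, res.case_proportion)
        assert h2_liab >= h2 * 0.9  # liability factor near prevalence 0.3 > ~1


class TestReportingStyle:
    def test_bound_component_prints_below_zero(self):
        spec, _ = _family_fit(seed=21, h2=0.0, n_lambs=150, m=500)
        res = reml_fit(spec)
        printed = res.format_components()
        if res.at_bound[0]:
            assert printed["genomic"] == "<0.00"
        assert set(printed) == {"genomic", "residual"}
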