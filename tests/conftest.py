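import numpy as np
import pytest

from addom import cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Small-variant-count instance of the default 254-lamb design."""
    cfg = cohort.CohortConfig(n_variants=400, n_qtl_additive=80, n_qtl_dominance=40, seed=42)
    ped = cohort.simulate_pedigree(cfg)
    geno = cohort.simulate_genotypes(ped, cfg)
    traits, truth = cohort.simulate_traits(ped, geno, cfg)
    return cfg, ped, geno, traits, truth


@pytest.fixture(scope="session")
def family_cohort():
    """Triplet-litter multi-sire cohort with additive+dominance trait, for
    recovery-style tests (full sibs carry the dominance information)."""
    cfg = cohort.CohortConfig(
        n_sires=20,
        n_ewes=150,
        n_lambs=450,
        n_contemporaries_ungenotyped=0,
        n_variants=2500,
        n_qtl_additive=250,
        n_qtl_dominance=250,
        traits=[cohort.TraitSpec("T", "gaussian", h2=0.6, d2=0.15, mean=0.0, sd=1.0)],
        seed=5,
    )
    ped = cohort.simulate_pedigree(cfg)
    geno = cohort.simulate_genotypes(ped, cfg)
    traits, truth = cohort.simulate_traits(ped, geno, cfg)
    return cfg, ped, geno, traits, truth


def founder_config(n, m, seed, maf=(0.05, 0.5), **kw):
    """Founders-only cohort config (independent variants, HWE)."""
    traits = kw.pop(
        "traits", [cohort.TraitSpec("T", "gaussian", h2=0.5, d2=0.0)]
    )
    return cohort.CohortConfig(
        n_sires=0,
        n_ewes=n,
        n_lambs=0,
        n_contemporaries_ungenotyped=0,
        n_variants=m,
        n_qtl_additive=min(kw.pop("n_qtl_additive", 50), m),
        n_qtl_dominance=kw.pop("n_qtl_dominance", 0),
        maf_range=maf,
        traits=traits,
        seed=seed,
        **kw,
    )


def founder_genotypes(n, m, seed, maf=(0.05, 0.5), **kw):
    cfg = founder_config(n, m, seed, maf, **kw)
    ped = cohort.simulate_pedigree(cfg)
    return cohort.simulate_genotypes(ped, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
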