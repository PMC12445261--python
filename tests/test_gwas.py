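import numpy as np
import numpy.linalg as la
import pandas as pd
import pytest

from addom import cohort, gwas, kinship, varcomp
from addom.data import GenotypeMatrix
from addom.varcomp import MixedModelSpec, VarCompResult

from conftest import founder_config, founder_genotypes


def _geno(d, chrom=None):
    d = np.asarray(d, float)
    m = d.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": (np.arange(m) + 1) * 50,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(d, variants, [f"S{i}" for i in range(d.shape[0])])


class TestThresholds:
    def test_printed_values_at_reported_meff(self):
        th = gwas.thresholds_from_meff(477627, alpha=0.05)
        bonf, sug = th.printed(2)
        assert bonf == 6.98
        assert sug == 5.67
        # p_bonf rounds to 1.05e-7 at three significant figures
        assert float(f"{th.p_bonf:.2e}") == pytest.approx(1.05e-7)

    def test_small_meff(self):
        th = gwas.thresholds_from_meff(20, alpha=0.05)
        assert th.p_bonf == pytest.approx(0.0025)
        assert th.p_sug == pytest.approx(0.05)

    def test_bonf_below_suggestive(self):
        for meff in (1, 10, 477627):
            th = gwas.thresholds_from_meff(meff)
            assert th.p_bonf < th.p_sug or meff == 1 and th.p_bonf < th.p_sug

    def test_zero_meff_rejected(self):
        with pytest.raises(ValueError):
            gwas.thresholds_from_meff(0)


class TestInflationFactor:
    def test_constant_at_median(self):
        lam = gwas.inflation_factor(np.full(100, 0.4549))
        assert lam == pytest.approx(1.0, abs=1e-3)

    def test_iid_chisquare_draws(self, rng):
        lam = gwas.inflation_factor(rng.chisquare(1, 100000))
        assert abs(lam - 1.0) < 0.02

    def test_scale_equivariance(self, rng):
        stats_ = rng.chisquare(1, 1000)
        assert gwas.inflation_factor(2 * stats_) == pytest.approx(
            2 * gwas.inflation_factor(stats_)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gwas.inflation_factor(np.array([]))

    def test_median_constant(self):
        assert round(gwas.CHI2_1_MEDIAN, 4) == 0.4549


def _ols_oracle(y, X, x, p):
    """Brute-force OLS squared t-statistics for one variant."""
    xa = x - 2 * p
    q = 1 - p
    xd = np.where(x == 0, -2 * p**2, np.where(x == 1, 2 * p * q, -2 * q**2))
    M = np.column_stack([X, xa, xd])
    if la.matrix_rank(M) < M.shape[1]:
        return None
    b, *_ = la.lstsq(M, y, rcond=None)
    r = y - M @ b
    s2 = r @ r / (len(y) - M.shape[1])
    cov = s2 * la.inv(M.T @ M)
    k = X.shape[1]
    return b[k] ** 2 / cov[k, k], b[k + 1] ** 2 / cov[k + 1, k + 1]


class TestAssocScan:
    def test_reduces_to_ols_when_no_polygenic(self, rng):
        geno = founder_genotypes(50, 8, seed=61, maf=(0.2, 0.5))
        y = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        vc = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        assoc = gwas.assoc_scan(y, X, geno, None, vc)
        checked = 0
        for j in range(geno.n_variants):
            oracle = _ols_oracle(y, X, geno.dosages[:, j], geno.allele_freq()[j])
            if oracle is None or assoc["NOTE"][j]:
                continue
            assert assoc["CHI2_A"][j] == pytest.approx(oracle[0], abs=1e-8)
            assert assoc["CHI2_D"][j] == pytest.approx(oracle[1], abs=1e-8)
            checked += 1
        assert checked >= 5

    def test_null_calibration_small(self, rng):
        n, m = 300, 2500
        geno = founder_genotypes(n, m, seed=62)
        G = kinship.grm_additive(geno)
        vals, vecs = np.linalg.eigh(G.values)
        gpoly = vecs @ (np.sqrt(np.clip(vals, 0, None) * 0.5) * rng.standard_normal(n))
        y = gpoly + np.sqrt(0.5) * rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = varcomp.reml_fit(MixedModelSpec(y=y, X=X, random=[("genomic", G)]))
        assoc = gwas.assoc_scan(y, X, geno, G, fit)
        band = 3 * np.sqrt(0.05 * 0.95 / m) + 0.01
        assert abs((assoc["P_A"] < 0.05).mean() - 0.05) < band
        assert abs((assoc["P_D"] < 0.05).mean() - 0.05) < band

    def test_allele_relabel_invariance(self, rng):
        geno = founder_genotypes(120, 20, seed=63, maf=(0.2, 0.5))
        y = rng.standard_normal(120)
        X = np.ones((120, 1))
        vc = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        a1 = gwas.assoc_scan(y, X, geno, None, vc)
        flipped = _geno(2.0 - geno.dosages)
        a2 = gwas.assoc_scan(y, X, flipped, None, vc)
        ok = (a1["NOTE"] == "") & (a2["NOTE"] == "")
        np.testing.assert_allclose(
            a1.loc[ok, "CHI2_A"], a2.loc[ok, "CHI2_A"], atol=1e-8
        )
        np.testing.assert_allclose(
            a1.loc[ok, "CHI2_D"], a2.loc[ok, "CHI2_D"], atol=1e-8
        )
        np.testing.assert_allclose(
            a1.loc[ok, "BETA_A"], -a2.loc[ok, "BETA_A"], atol=1e-10
        )

    def test_coding_orthogonality_under_hwe(self):
        geno = founder_genotypes(5000, 50, seed=64)
        p = geno.allele_freq()
        xa = geno.dosages - 2 * p
        xd = kinship.dominance_coding(geno.dosages, p)
        covs = (xa * xd).mean(axis=0) - xa.mean(0) * xd.mean(0)
        assert np.abs(covs).mean() < 0.01

    def test_overdominant_locus_found_by_dominance_scan(self, rng):
        n, m = 800, 300
        geno = founder_genotypes(n, m, seed=65, maf=(0.45, 0.5))
        j = 150
        x = geno.dosages[:, j]
        het = (x == 1).astype(float)
        y = 0.5 * (het - het.mean()) + rng.standard_normal(n)
        X = np.ones((n, 1))
        vc = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        assoc = gwas.assoc_scan(y, X, geno, None, vc)
        assert int(assoc["P_D"].idxmin()) == j
        # purely overdominant locus at p~0.5: additive test stays near null
        assert assoc["CHI2_A"][j] < 12.0

    def test_spectral_and_direct_paths_agree(self, rng):
        n, m = 150, 60
        geno = founder_genotypes(n, m, seed=66, maf=(0.2, 0.5))
        G = kinship.grm_additive(geno)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        vc = VarCompResult.from_components({"genomic": 0.4, "residual": 0.6})
        a1 = gwas.assoc_scan(y, X, geno, G, vc, method="spectral")
        a2 = gwas.assoc_scan(y, X, geno, G, vc, method="direct")
        ok = (a1["NOTE"] == "") & (a2["NOTE"] == "")
        np.testing.assert_allclose(
            a1.loc[ok, "CHI2_A"], a2.loc[ok, "CHI2_A"], atol=1e-6
        )
        np.testing.assert_allclose(
            a1.loc[ok, "CHI2_D"], a2.loc[ok, "CHI2_D"], atol=1e-6
        )

    def test_missing_genotype_class_drops_dominance(self, rng):
        # variant with only dosages {0, 2}: dominance column collinear
        d = np.column_stack([
            np.repeat([0.0, 2.0], 25),
            rng.binomial(1, 0.5, 50) + rng.binomial(1, 0.5, 50),
        ])
        geno = _geno(d)
        y = rng.standard_normal(50)
        vc = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        assoc = gwas.assoc_scan(y, np.ones((50, 1)), geno, None, vc)
        assert assoc["NOTE"][0] == "dominance collinear"
        assert np.isnan(assoc["BETA_D"][0])
        assert np.isfinite(assoc["CHI2_A"][0])

    def test_monomorphic_skipped(self, rng):
        d = np.column_stack([np.zeros(30), rng.binomial(2, 0.5, 30)])
        geno = _geno(d)
        vc = VarCompResult.from_components({"genomic": 0.0, "residual": 1.0})
        assoc = gwas.assoc_scan(
            rng.standard_normal(30), np.ones((30, 1)), geno, None, vc
        )
        assert assoc["NOTE"][0] == "monomorphic"
        assert np.isnan(assoc["CHI2_A"][0])


class TestManhattan:
    def _assoc(self):
        return pd.DataFrame(
            {
                "CHR": ["1", "1", "2"],
                "BP": [100, 200, 150],
                "ID": ["v1", "v2", "v3"],
                "FREQ": [0.3, 0.4, 0.5],
                "P_A": [1e-7, 5e-7, 0.2],
                "P_D": [0.5, 0.01, np.nan],
                "CHI2_A": [28.0, 25.0, 1.6],
                "CHI2_D": [0.4, 6.6, np.nan],
            }
        )

    def test_tier_boundaries(self):
        th = gwas.thresholds_from_meff(477627)
        out = gwas.assign_tiers(self._assoc(), th)
        # -log10(1e-7) = 7.00 > 6.98 -> bonferroni; 5e-7 -> 6.30 -> suggestive
        assert out["TIER_A"].tolist() == ["bonferroni", "suggestive", "none"]
        assert out["TIER_D"].tolist() == ["none", "none", "none"]

    def test_cumulative_coordinates_monotone_per_chrom(self, tmp_path):
        th = gwas.thresholds_from_meff(100)
        out = gwas.manhattan_export(self._assoc(), th, figure_path=tmp_path / "m.png")
        assert (tmp_path / "m.png").exists()
        c1 = out[out["CHR"] == "1"]["CUMPOS"].to_numpy()
        assert (np.diff(c1) > 0).all()
        assert out[out["CHR"] == "2"]["CUMPOS"].min() > c1.max()

    def test_empty_significant_set(self, tmp_path):
        assoc = self._assoc().assign(P_A=[0.5, 0.6, 0.7], P_D=[0.5, 0.6, 0.7])
        th = gwas.thresholds_from_meff(1000)
        out = gwas.manhattan_export(assoc, th, figure_path=tmp_path / "e.png")
        assert (out["TIER_A"] == "none").all()
        assert (tmp_path / "e.png").exists()

    def test_single_chromosome(self):
        assoc = self._assoc()
        assoc["CHR"] = "5"
        out = gwas.manhattan_export(assoc, gwas.thresholds_from_meff(10))
        assert set(out["CHR"]) == {"5"}
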